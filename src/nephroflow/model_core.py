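"""Domain types, unit conventions and compartment topology of the kidney model.

The model divides the kidney into four regions along the cortico-medullary
axis (cortex, outer medulla, inner medulla I, inner medulla II).  Each region
contains well-stirred tubular, interstitial and vascular plasma compartments.
Two nephron populations are represented: short loops turning in the outer
medulla and long loops turning in inner medulla II; all nephrons share a
single merged collecting-duct chain.

Internal unit system
--------------------
volume L, time min, amount of substance umol, pressure mmHg, dynamic
viscosity mPa.s.  All published parameter values (ml, cm/s, cm^2, mm, um)
are converted exactly once, in :func:`load_parameters`, so the rest of the
package never performs unit conversion.  Permeability-surface-area products
are stored as clearances in L/min.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "ParameterError",
    "TopologyError",
    "ParameterSet",
    "KidneyTopology",
    "ModelState",
    "REGIONS",
    "TUBULAR_COMPARTMENTS",
    "SOLUTES",
    "load_parameters",
    "serialize_parameters",
    "default_parameter_document",
    "build_topology",
    "osmolality",
]

# ---------------------------------------------------------------------------
# Naming conventions

REGIONS = ("cortex", "outer_medulla", "inner_medulla_1", "inner_medulla_2")
MEDULLARY_REGIONS = REGIONS[1:]
SOLUTES = ("sodium", "urea", "drug")
NA, UREA, DRUG = 0, 1, 2

#: ordered tubular compartments: short loop, long loop, collecting duct
TUBULAR_COMPARTMENTS = (
    "proximal_short",            # 0  cortex
    "descending_henle_short",    # 1  outer medulla
    "ascending_henle_short",     # 2  outer medulla
    "distal_short",              # 3  cortex
    "proximal_long",             # 4  cortex
    "descending_henle_long_om",  # 5  outer medulla
    "descending_henle_long_im1", # 6  inner medulla I
    "descending_henle_long_im2", # 7  inner medulla II
    "ascending_henle_long_im2",  # 8  inner medulla II
    "ascending_henle_long_im1",  # 9  inner medulla I
    "ascending_henle_long_om",   # 10 outer medulla
    "distal_long",               # 11 cortex
    "cd_cortex",                 # 12 cortex
    "cd_outer_medulla",          # 13 outer medulla
    "cd_inner_medulla_1",        # 14 inner medulla I
    "cd_inner_medulla_2",        # 15 inner medulla II
)

SHORT_CHAIN = (0, 1, 2, 3)
LONG_CHAIN = (4, 5, 6, 7, 8, 9, 10, 11)
CD_CHAIN = (12, 13, 14, 15)

#: region index (into REGIONS) of each tubular compartment
TUB_REGION = (0, 1, 1, 0, 0, 1, 2, 3, 3, 2, 1, 0, 0, 1, 2, 3)

MMHG_PA = 133.322        # 1 mmHg in Pa
IODINE_G_MOL = 126.90    # atomic mass of iodine


class ParameterError(ValueError):
    """Raised when a parameter document fails validation; names the key."""


class TopologyError(ValueError):
    """Raised when the compartment graph cannot be constructed consistently."""


# ---------------------------------------------------------------------------
# Parameter set


@dataclass(frozen=True)
class ParameterSet:
    """Unit-normalized physiological constants (see module docstring).

    ``raw`` retains the source document (published units) so that
    serialization round-trips the printed table values bit-exactly.
    """

    # nephron populations
    n_nephrons: int
    fraction_long: float
    # whole-kidney hemodynamics
    rpf: float                  # renal plasma flow, L/min
    f_peritub: float            # fraction of post-glomerular flow to peritubular caps
    gfr0: float                 # steady-state glomerular filtration rate, L/min
    # systemic boundary concentrations, umol/L
    c_na_systemic: float
    c_urea_systemic: float
    # pressure sub-model
    p_e: float                  # collecting-duct end pressure, mmHg
    r_glom: float               # effective glomerular resistance, mmHg.min/L
    p_gs: float                 # glomerular capillary pressure, short loops, mmHg
    p_gl: float                 # long loops, mmHg
    eta_water: float            # water viscosity, mPa.s
    # collecting ducts per nephron, by region
    cd_per_nephron: Mapping[str, Fraction]
    # vascular exchange clearances P*S, L/min
    ps_peritubular: float
    ps_dvr: Mapping[str, Mapping[str, float]]   # medullary region -> solute -> L/min
    ps_avr: Mapping[str, float]                 # medullary region -> L/min (all solutes)
    r_dvr: Mapping[str, float]                  # DVR water conductivity, L^2/(min.umol)
    # compartment volumes, L:  region -> structure -> L
    volumes: Mapping[str, Mapping[str, float]]
    # identified tubular transport parameters (whole-kidney aggregates)
    water_conductivity: Mapping[str, float]     # segment class -> L^2/(min.umol)
    k_active_na: Mapping[str, float]            # segment class -> L/min
    k_passive_na: Mapping[str, float]
    k_passive_urea: Mapping[str, float]
    # single-nephron segment geometry: segment class -> (radius m, length m)
    geometry: Mapping[str, tuple]
    # cellular sodium, umol/L
    c_na_cell_im2: float
    c_na_cell_elsewhere: float
    # two-compartment body
    v_plasma: float             # L
    v_extracellular: float      # L
    q_body: float               # total body plasma flow, L/min
    q_exchange: float           # plasma <-> residual extracellular clearance, L/min
    # numerics
    p_relax: float              # algebraic-relaxation time constant, min
    split_short: float          # share of a printed aggregate assigned to short loops
    split_long: float
    pair_gain: float            # calibrated allocation gain for paired segment classes
    # metadata (already folded into the volumes)
    hematocrit: Mapping[str, float]
    raw: dict = field(repr=False, default_factory=dict)

    @property
    def n_short(self) -> int:
        return self.n_nephrons - self.n_long

    @property
    def n_long(self) -> int:
        return round(self.n_nephrons * self.fraction_long)


def default_parameter_document() -> dict:
    """Return a deep copy of the packaged default parameter document."""
    text = resources.files("nephroflow.data").joinpath("parameters.json").read_text()
    return json.loads(text)


def _require(doc: Mapping, key: str, ctx: str):
    if key not in doc:
        raise ParameterError(f"missing parameter: {ctx}{key}")
    return doc[key]


def _positive(value, key: str):
    if not isinstance(value, (int, float)) or not math.isfinite(value) or value <= 0:
        raise ParameterError(f"parameter {key!r} must be a positive finite number, got {value!r}")
    return float(value)


def _fraction01(value, key: str):
    v = _positive(value, key)
    if v > 1:
        raise ParameterError(f"parameter {key!r} must lie in (0, 1], got {value!r}")
    return v


_SCHEMA_SECTIONS = {
    "nephrons", "hemodynamics", "hematocrit", "systemic",
    "collecting_ducts_per_nephron", "vascular", "volumes_ml",
    "tubular_transport", "segment_geometry", "cellular_sodium_mmol_L",
    "body", "numerics",
}


def load_parameters(document: Mapping | None = None) -> ParameterSet:
    """Validate and unit-normalize a parameter document.

    Parameters
    ----------
    document
        A mapping following the packaged ``parameters.json`` schema
        (published units: ml, ml/min, cm/s, cm^2, mm, um, mmol/L).
        ``None`` loads the packaged defaults.

    Raises
    ------
    ParameterError
        On missing keys, unknown keys, or out-of-range values; the message
        names the offending key.
    """
    doc = copy.deepcopy(dict(document)) if document is not None else default_parameter_document()
    doc.pop("_comment", None)
    unknown = set(doc) - _SCHEMA_SECTIONS
    if unknown:
        raise ParameterError(f"unknown parameter section(s): {sorted(unknown)}")
    for sec in _SCHEMA_SECTIONS:
        _require(doc, sec, "section ")

    neph = doc["nephrons"]
    n_nephrons = int(_positive(_require(neph, "total_count", "nephrons."), "nephrons.total_count"))
    fraction_long = _fraction01(_require(neph, "fraction_long_loops", "nephrons."),
                                "nephrons.fraction_long_loops")

    hemo = doc["hemodynamics"]
    rpf = _positive(hemo["renal_plasma_flow_ml_min"], "renal_plasma_flow_ml_min") * 1e-3
    f_peritub = _fraction01(hemo["fraction_peritubular_plasma_flow"],
                            "fraction_peritubular_plasma_flow")
    gfr0 = _positive(hemo["gfr0_ml_min"], "gfr0_ml_min") * 1e-3
    if gfr0 >= rpf:
        raise ParameterError("gfr0_ml_min must be smaller than renal_plasma_flow_ml_min")
    p_e = _positive(hemo["collecting_duct_end_pressure_mmHg"], "collecting_duct_end_pressure_mmHg")
    r_glom = _positive(hemo["glomerular_resistance_mmHg_min_L"], "glomerular_resistance_mmHg_min_L")
    p_gs = _positive(hemo["glomerular_pressure_short_mmHg"], "glomerular_pressure_short_mmHg")
    p_gl = _positive(hemo["glomerular_pressure_long_mmHg"], "glomerular_pressure_long_mmHg")
    eta_water = _positive(hemo["water_viscosity_mPa_s"], "water_viscosity_mPa_s")

    sys_ = doc["systemic"]
    c_na = _positive(sys_["sodium_mmol_L"], "systemic.sodium_mmol_L") * 1e3
    c_urea = _positive(sys_["urea_mmol_L"], "systemic.urea_mmol_L") * 1e3

    cd_doc = doc["collecting_ducts_per_nephron"]
    cd_per_nephron = {}
    for region in REGIONS:
        v = _require(cd_doc, region, "collecting_ducts_per_nephron.")
        frac = Fraction(v) if isinstance(v, str) else Fraction(v).limit_denominator(10**6)
        if not 0 < frac <= 1:
            raise ParameterError(f"collecting_ducts_per_nephron.{region} must lie in (0, 1]")
        cd_per_nephron[region] = frac

    vas = doc["vascular"]
    cm_s_to_cm_min = 60.0
    cm3_to_L = 1e-3
    p_avr = _positive(vas["avr_permeability_cm_s"], "avr_permeability_cm_s") * cm_s_to_cm_min
    p_dvr = _positive(vas["dvr_permeability_cm_s"], "dvr_permeability_cm_s") * cm_s_to_cm_min
    p_dvr_urea_om = _positive(vas["dvr_urea_permeability_outer_medulla_cm_s"],
                              "dvr_urea_permeability_outer_medulla_cm_s") * cm_s_to_cm_min
    ps_peritub = (_positive(vas["peritubular_permeability_cm_s"], "peritubular_permeability_cm_s")
                  * cm_s_to_cm_min
                  * _positive(vas["peritubular_surface_cm2"], "peritubular_surface_cm2")
                  * cm3_to_L)
    ps_dvr, ps_avr, r_dvr = {}, {}, {}
    for region in MEDULLARY_REGIONS:
        s_dvr = _positive(vas["dvr_surface_cm2"][region], f"dvr_surface_cm2.{region}")
        s_avr = 2.0 * s_dvr  # AVR/DVR number ratio of two
        p_dvr_urea = p_dvr_urea_om if region == "outer_medulla" else p_dvr
        ps_dvr[region] = {
            "sodium": p_dvr * s_dvr * cm3_to_L,
            "urea": p_dvr_urea * s_dvr * cm3_to_L,
            "drug": p_dvr * s_dvr * cm3_to_L,
        }
        ps_avr[region] = p_avr * s_avr * cm3_to_L
        r_dvr[region] = _positive(vas["dvr_water_conductivity_L2_min_umol"][region],
                                  f"dvr_water_conductivity_L2_min_umol.{region}")

    volumes = {}
    for region in REGIONS:
        vols = _require(doc["volumes_ml"], region, "volumes_ml.")
        volumes[region] = {name: _positive(v, f"volumes_ml.{region}.{name}") * 1e-3
                           for name, v in vols.items()}

    tt = doc["tubular_transport"]
    water_conductivity = {k: _positive(v, f"water_conductivity.{k}")
                          for k, v in tt["water_conductivity_L2_min_umol"].items()}
    k_active_na = {k: _positive(v, f"sodium_active.{k}") for k, v in tt["sodium_active_L_min"].items()}
    k_passive_na = {k: _positive(v, f"sodium_passive.{k}") for k, v in tt["sodium_passive_L_min"].items()}
    k_passive_urea = {k: _positive(v, f"urea_passive.{k}") for k, v in tt["urea_passive_L_min"].items()}

    geometry = {}
    for seg, g in doc["segment_geometry"].items():
        r_m = _positive(g["radius_um"], f"segment_geometry.{seg}.radius_um") * 1e-6
        l_m = _positive(g["length_mm"], f"segment_geometry.{seg}.length_mm") * 1e-3
        geometry[seg] = (r_m, l_m)

    cell = doc["cellular_sodium_mmol_L"]
    c_na_cell_im2 = _positive(cell["inner_medulla_2"], "cellular_sodium_mmol_L.inner_medulla_2") * 1e3
    c_na_cell_else = _positive(cell["elsewhere"], "cellular_sodium_mmol_L.elsewhere") * 1e3

    body = doc["body"]
    v_plasma = _positive(body["plasma_volume_ml"], "body.plasma_volume_ml") * 1e-3
    v_ec = _positive(body["residual_extracellular_volume_ml"], "body.residual_extracellular_volume_ml") * 1e-3
    q_body = _positive(body["total_plasma_flow_L_min"], "body.total_plasma_flow_L_min")
    q_ex = body.get("exchange_clearance_L_min")
    if q_ex is None:
        q_ex = q_body - rpf  # flow-limited distribution into the extracellular space
        if q_ex <= 0:
            raise ParameterError("total_plasma_flow_L_min must exceed renal plasma flow")
    else:
        q_ex = _positive(q_ex, "body.exchange_clearance_L_min")

    num = doc["numerics"]
    p_relax = _positive(num["relaxation_time_min"], "numerics.relaxation_time_min")
    split_short = _fraction01(num["short_loop_split"], "numerics.short_loop_split")
    split_long = _fraction01(num["long_loop_split"], "numerics.long_loop_split")
    if abs(split_short + split_long - 1.0) > 1e-12:
        raise ParameterError("short_loop_split and long_loop_split must sum to 1")
    pair_gain = _positive(num["pair_allocation_gain"], "numerics.pair_allocation_gain")

    hct = {k: _fraction01(v, f"hematocrit.{k}") for k, v in doc["hematocrit"].items()}

    return ParameterSet(
        n_nephrons=n_nephrons, fraction_long=fraction_long,
        rpf=rpf, f_peritub=f_peritub, gfr0=gfr0,
        c_na_systemic=c_na, c_urea_systemic=c_urea,
        p_e=p_e, r_glom=r_glom, p_gs=p_gs, p_gl=p_gl, eta_water=eta_water,
        cd_per_nephron=cd_per_nephron,
        ps_peritubular=ps_peritub, ps_dvr=ps_dvr, ps_avr=ps_avr, r_dvr=r_dvr,
        volumes=volumes,
        water_conductivity=water_conductivity, k_active_na=k_active_na,
        k_passive_na=k_passive_na, k_passive_urea=k_passive_urea,
        geometry=geometry,
        c_na_cell_im2=c_na_cell_im2, c_na_cell_elsewhere=c_na_cell_else,
        v_plasma=v_plasma, v_extracellular=v_ec, q_body=q_body, q_exchange=q_ex,
        p_relax=p_relax, split_short=split_short, split_long=split_long,
        pair_gain=pair_gain,
        hematocrit=hct, raw=doc,
    )


def serialize_parameters(params: ParameterSet) -> dict:
    """Return the parameter document (published units) of a ParameterSet.

    ``load_parameters(serialize_parameters(p))`` is an identity, and the
    document reproduces the published table values on their printed scale.
    """
    return copy.deepcopy(params.raw)


# ---------------------------------------------------------------------------
# Topology


@dataclass(frozen=True)
class KidneyTopology:
    """The ordered compartment graph with per-compartment transport data.

    Tubular arrays are indexed by :data:`TUBULAR_COMPARTMENTS`.  Whole-kidney
    transport aggregates for segment classes present in both nephron
    populations (proximal, distal, outer-medullary limbs) are split between
    the short- and long-loop compartments in proportion to the nephron-count
    fractions, preserving the whole-kidney aggregate.
    """

    names: tuple
    region: np.ndarray          # (16,) region index 0..3
    v_tub: np.ndarray           # (16,) L
    r_water: np.ndarray         # (16,) L^2/(min.umol); 0 = water-impermeable
    k_active_na: np.ndarray     # (16,) L/min
    k_passive_na: np.ndarray    # (16,) L/min
    k_passive_urea: np.ndarray  # (16,) L/min
    radius: np.ndarray          # (16,) m, single-nephron geometry
    length: np.ndarray          # (16,) m
    n_tubes: np.ndarray         # (16,) parallel tubes represented by the compartment
    v_int: np.ndarray           # (4,) interstitial volumes, L
    v_cell: np.ndarray          # (4,) cellular volumes, L
    v_peritub: float            # L
    v_glom: float               # glomerular plasma, metadata volume, L
    v_dvr: np.ndarray           # (3,) OM, IM-I, IM-II, L
    v_avr: np.ndarray           # (3,) L
    ps_dvr: np.ndarray          # (3, 3) region x solute clearance, L/min
    ps_avr: np.ndarray          # (3,) L/min (solute-independent)
    r_dvr: np.ndarray           # (3,) L^2/(min.umol)

    @property
    def water_sites(self):
        return tuple(self.names[i] for i in range(16) if self.r_water[i] > 0)

    @property
    def active_na_sites(self):
        return tuple(self.names[i] for i in range(16) if self.k_active_na[i] > 0)

    def region_volume(self, region: str) -> float:
        """Total anatomical volume of a region (all compartments, L)."""
        j = REGIONS.index(region)
        total = float(self.v_tub[self.region == j].sum()) + self.v_int[j] + self.v_cell[j]
        if j == 0:
            total += self.v_peritub + self.v_glom
        else:
            total += self.v_dvr[j - 1] + self.v_avr[j - 1]
        return total


# (segment class, applies to) mapping of the identified transport parameters;
# "split" entries exist once per printed table row but twice in the topology.
_SEGMENT_CLASS = {
    "proximal_tubule": {"short": 0, "long": 4},
    "descending_henle_outer_medulla": {"short": 1, "long": 5},
    "ascending_henle_outer_medulla": {"short": 2, "long": 10},
    "distal_tubule": {"short": 3, "long": 11},
    "descending_henle_inner_medulla_1": {"long": 6},
    "descending_henle_inner_medulla_2": {"long": 7},
    "ascending_henle_inner_medulla_2": {"long": 8},
    "ascending_henle_inner_medulla_1": {"long": 9},
    "collecting_duct_cortex": {"shared": 12},
    "collecting_duct_outer_medulla": {"shared": 13},
    "collecting_duct_inner_medulla_1": {"shared": 14},
    "collecting_duct_inner_medulla_2": {"shared": 15},
}

_VOLUME_KEYS = (
    ("cortex", "proximal_tubule_short", 0),
    ("outer_medulla", "descending_henle_short", 1),
    ("outer_medulla", "ascending_henle_short", 2),
    ("cortex", "distal_tubule_short", 3),
    ("cortex", "proximal_tubule_long", 4),
    ("outer_medulla", "descending_henle_long", 5),
    ("inner_medulla_1", "descending_henle", 6),
    ("inner_medulla_2", "descending_henle", 7),
    ("inner_medulla_2", "ascending_henle", 8),
    ("inner_medulla_1", "ascending_henle", 9),
    ("outer_medulla", "ascending_henle_long", 10),
    ("cortex", "distal_tubule_long", 11),
    ("cortex", "collecting_duct", 12),
    ("outer_medulla", "collecting_duct", 13),
    ("inner_medulla_1", "collecting_duct", 14),
    ("inner_medulla_2", "collecting_duct", 15),
)


def _distribute(params: ParameterSet, table: Mapping[str, float], out: np.ndarray):
    """Attach one printed aggregate per segment class to topology compartments."""
    for seg_class, value in table.items():
        sites = _SEGMENT_CLASS.get(seg_class)
        if sites is None:
            raise TopologyError(f"transport parameter for unknown segment class {seg_class!r}")
        if "shared" in sites:
            out[sites["shared"]] += value
        elif "long" in sites and "short" in sites:
            # nephron-count-proportional allocation, scaled by the pair
            # allocation gain calibrated to the drug-free urine flow (the
            # published tables leave the short/long mapping unstated)
            gain = params.pair_gain
            out[sites["short"]] += params.split_short * gain * value
            out[sites["long"]] += params.split_long * gain * value
        else:
            out[sites["long"]] += value


def build_topology(params: ParameterSet) -> KidneyTopology:
    """Construct the compartment graph of the kidney from a ParameterSet."""
    v_tub = np.zeros(16)
    for region, key, idx in _VOLUME_KEYS:
        v_tub[idx] = params.volumes[region][key]

    r_water = np.zeros(16)
    k_act = np.zeros(16)
    k_pas_na = np.zeros(16)
    k_pas_urea = np.zeros(16)
    _distribute(params, params.water_conductivity, r_water)
    _distribute(params, params.k_active_na, k_act)
    _distribute(params, params.k_passive_na, k_pas_na)
    _distribute(params, params.k_passive_urea, k_pas_urea)

    # ascending limbs are water-impermeable by construction
    for i in (2, 8, 9, 10):
        if r_water[i] != 0.0:
            raise TopologyError(f"ascending limb {TUBULAR_COMPARTMENTS[i]!r} must be water-impermeable")

    radius = np.zeros(16)
    length = np.zeros(16)
    geom_class = {
        0: "proximal_tubule", 4: "proximal_tubule",
        1: "descending_henle_outer_medulla", 5: "descending_henle_outer_medulla",
        6: "descending_henle_inner_medulla_1", 7: "descending_henle_inner_medulla_2",
        8: "ascending_henle_inner_medulla_2", 9: "ascending_henle_inner_medulla_1",
        2: "ascending_henle_outer_medulla", 10: "ascending_henle_outer_medulla",
        3: "distal_tubule", 11: "distal_tubule",
        12: "collecting_duct_cortex", 13: "collecting_duct_outer_medulla",
        14: "collecting_duct_inner_medulla_1", 15: "collecting_duct_inner_medulla_2",
    }
    for idx, seg in geom_class.items():
        if seg not in params.geometry:
            raise TopologyError(f"missing segment geometry for {seg!r}")
        radius[idx], length[idx] = params.geometry[seg]

    n_short, n_long, n_tot = params.n_short, params.n_long, params.n_nephrons
    n_tubes = np.zeros(16)
    n_tubes[list(SHORT_CHAIN)] = n_short
    n_tubes[list(LONG_CHAIN)] = n_long
    for idx, region in zip(CD_CHAIN, REGIONS):
        n_tubes[idx] = n_tot * float(params.cd_per_nephron[region])

    v_int = np.array([params.volumes[r]["interstitial_space"] for r in REGIONS])
    v_cell = np.array([params.volumes[r]["cellular_space"] for r in REGIONS])
    v_dvr = np.array([params.volumes[r]["vasa_descendens"] for r in MEDULLARY_REGIONS])
    v_avr = np.array([params.volumes[r]["vasa_ascendens"] for r in MEDULLARY_REGIONS])
    ps_dvr = np.array([[params.ps_dvr[r][s] for s in SOLUTES] for r in MEDULLARY_REGIONS])
    ps_avr = np.array([params.ps_avr[r] for r in MEDULLARY_REGIONS])
    r_dvr = np.array([params.r_dvr[r] for r in MEDULLARY_REGIONS])

    topo = KidneyTopology(
        names=TUBULAR_COMPARTMENTS, region=np.array(TUB_REGION),
        v_tub=v_tub, r_water=r_water, k_active_na=k_act,
        k_passive_na=k_pas_na, k_passive_urea=k_pas_urea,
        radius=radius, length=length, n_tubes=n_tubes,
        v_int=v_int, v_cell=v_cell,
        v_peritub=params.volumes["cortex"]["peritubular_capillaries"],
        v_glom=params.volumes["cortex"]["glomerular_plasma"],
        v_dvr=v_dvr, v_avr=v_avr,
        ps_dvr=ps_dvr, ps_avr=ps_avr, r_dvr=r_dvr,
    )
    # every water-reabsorbing compartment must carry a conductivity; the
    # complement (ascending limbs) was checked above
    if np.any(v_tub <= 0) or np.any(n_tubes <= 0):
        raise TopologyError("all tubular volumes and tube counts must be positive")
    return topo


# ---------------------------------------------------------------------------
# Model state


@dataclass
class ModelState:
    """Concentrations (umol/L), body drug amounts (umol) and relaxed SNGFR.

    Array shapes: ``c_tub (16, 3)``, ``c_int (4, 3)``, ``c_peritub (3,)``,
    ``c_dvr (3, 3)``, ``c_avr (3, 3)`` with solute order (sodium, urea, drug)
    and medullary vascular order (OM, IM-I, IM-II).
    """

    c_tub: np.ndarray
    c_int: np.ndarray
    c_peritub: np.ndarray
    c_dvr: np.ndarray
    c_avr: np.ndarray
    a_plasma: float = 0.0       # body plasma drug amount, umol
    a_extracellular: float = 0.0
    sngfr_s: float = 0.0        # relaxed single-nephron GFR, L/min
    sngfr_l: float = 0.0
    v_urine: float = 0.0        # cumulative urine volume, L
    a_urine: float = 0.0        # cumulative excreted drug, umol

    NVEC = 87

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.c_tub.ravel(), self.c_int.ravel(), self.c_peritub,
            self.c_dvr.ravel(), self.c_avr.ravel(),
            [self.a_plasma, self.a_extracellular,
             self.sngfr_s, self.sngfr_l, self.v_urine, self.a_urine],
        ])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        return cls(
            c_tub=y[0:48].reshape(16, 3).copy(),
            c_int=y[48:60].reshape(4, 3).copy(),
            c_peritub=y[60:63].copy(),
            c_dvr=y[63:72].reshape(3, 3).copy(),
            c_avr=y[72:81].reshape(3, 3).copy(),
            a_plasma=float(y[81]), a_extracellular=float(y[82]),
            sngfr_s=float(y[83]), sngfr_l=float(y[84]),
            v_urine=float(y[85]), a_urine=float(y[86]),
        )

    @classmethod
    def uniform(cls, params: ParameterSet, sngfr0: float | None = None) -> "ModelState":
        """All compartments at systemic concentrations; SNGFR at its
        GFR_0-derived start value."""
        base = np.array([params.c_na_systemic, params.c_urea_systemic, 0.0])
        s0 = params.gfr0 / params.n_nephrons if sngfr0 is None else sngfr0
        return cls(
            c_tub=np.tile(base, (16, 1)), c_int=np.tile(base, (4, 1)),
            c_peritub=base.copy(), c_dvr=np.tile(base, (3, 1)),
            c_avr=np.tile(base, (3, 1)),
            sngfr_s=s0, sngfr_l=s0,
        )


# ---------------------------------------------------------------------------


def osmolality(c_na: float, c_urea: float, c_drug: float = 0.0, n: float = 1.0):
    """Osmotically active concentration, umol/L.

    Sodium counts twice, for its accompanying anions; the administered agent
    counts ``n`` times (1 non-ionic, 2 ionic).
    """
    return 2.0 * c_na + c_urea + n * c_drug
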