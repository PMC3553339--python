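"""Administered agents: contrast media and osmotic diuretics.

A substance is characterized by the number of osmotically active particles
per molecule (1 non-ionic, 2 ionic), its iodine content, its molar mass and
a viscosity exponent b such that fluid viscosity is eta_w * exp(b*C) at
molar concentration C.  Exponents are fit from (iodine concentration,
viscosity) points taken from vendor brochures; the packaged library ships
the six agents used in the model comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

from .model_core import IODINE_G_MOL
from .hemodynamics import fit_viscosity_exponent

__all__ = ["SubstanceSpec", "load_substance_library", "mg_iodine_per_ml_to_umol_L"]


def mg_iodine_per_ml_to_umol_L(c_mgI_ml: float, iodine_atoms: int) -> float:
    """Convert an iodine mass concentration to molar substance concentration."""
    if iodine_atoms <= 0:
        raise ValueError("substance carries no iodine")
    return c_mgI_ml / (iodine_atoms * IODINE_G_MOL) * 1e6


@dataclass(frozen=True)
class SubstanceSpec:
    """An administered hydrophilic agent."""

    name: str
    n_osmotic: int                 # osmotically active particles per molecule
    iodine_atoms: int
    molar_mass: float              # g/mol
    viscosity_exponent: float      # b, L/umol
    formulation_mg_iodine_ml: float | None = None

    def __post_init__(self):
        if self.n_osmotic not in (1, 2):
            raise ValueError("n_osmotic must be 1 (non-ionic) or 2 (ionic)")
        if self.viscosity_exponent < 0:
            raise ValueError("viscosity exponent must be non-negative")

    # ---- dose conversions ------------------------------------------------
    def dose_ml_to_umol(self, volume_ml: float) -> float:
        if self.formulation_mg_iodine_ml is None:
            raise ValueError(f"{self.name} has no iodine formulation concentration")
        mg_iodine = volume_ml * self.formulation_mg_iodine_ml
        return self.dose_mg_iodine_to_umol(mg_iodine)

    def dose_mg_iodine_to_umol(self, mg_iodine: float) -> float:
        return mg_iodine / (self.iodine_atoms * IODINE_G_MOL) * 1e3

    def dose_g_to_umol(self, grams: float) -> float:
        return grams / self.molar_mass * 1e6

    def dose_mosm_to_umol(self, mosm: float) -> float:
        """mOsmol of osmotically active particles -> umol of molecules."""
        return mosm / self.n_osmotic * 1e3

    def umol_to_mg_iodine(self, umol: float) -> float:
        return umol * self.iodine_atoms * IODINE_G_MOL * 1e-3

    def umol_to_mosm(self, umol: float) -> float:
        return umol * self.n_osmotic * 1e-3


def _spec_from_entry(name: str, entry: dict, eta_water: float,
                     library: dict) -> SubstanceSpec:
    b = entry.get("viscosity_exponent_L_umol")
    if b is None and "viscosity_iodine_curve_from" in entry:
        # same viscosity vs *iodine* concentration curve as the referenced
        # agent: b scales with the iodine atoms per molecule
        ref_name = entry["viscosity_iodine_curve_from"]
        ref = _spec_from_entry(ref_name, library[ref_name], eta_water, library)
        b = ref.viscosity_exponent * entry["iodine_atoms"] / ref.iodine_atoms
    if b is None:
        pts = entry["viscosity_points_mgI_ml_mPa_s"]
        conc = [mg_iodine_per_ml_to_umol_L(c, entry["iodine_atoms"]) for c, _ in pts]
        b = fit_viscosity_exponent(conc, [eta for _, eta in pts], eta_water)
    return SubstanceSpec(
        name=name,
        n_osmotic=entry["n_osmotic"],
        iodine_atoms=entry["iodine_atoms"],
        molar_mass=entry["molar_mass_g_mol"],
        viscosity_exponent=b,
        formulation_mg_iodine_ml=entry.get("formulation_mg_iodine_ml"),
    )


def load_substance_library(eta_water: float = 0.6913, document: dict | None = None) -> dict:
    """Load the packaged substance library (or a user document).

    Viscosity exponents are (re)fit at load time from the stored brochure
    points, on molar substance concentration.
    """
    if document is None:
        text = resources.files("nephroflow.data").joinpath("substances.json").read_text()
        document = json.loads(text)
    document = {k: v for k, v in document.items() if not k.startswith("_")}
    return {name: _spec_from_entry(name, entry, eta_water, document)
            for name, entry in document.items()}
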