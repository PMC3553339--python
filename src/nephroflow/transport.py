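"""Solute and water flux operators.

Each tubular compartment obeys a mass balance

    V_i dC_i/dt = q_in C_upstream - q_out C_i - k_active C_i
                  - k_passive (C_i - C_int),

with water reabsorption flows driven by the osmotic gradient between the
tubular fluid and the surrounding interstitium.  Interstitial, peritubular
and vasa-recta compartments exchange solute by permeability-surface-area
clearances and take up the reabsorbed water convectively.  Every exchange
term is antisymmetric between the two compartments it couples, so solute
mass is conserved up to the systemic boundaries (arterial inflow, venous
return, urine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    CD_CHAIN, DRUG, LONG_CHAIN, NA, SHORT_CHAIN, UREA,
    KidneyTopology, ModelState, ParameterSet, TUBULAR_COMPARTMENTS, osmolality,
)

__all__ = [
    "SimulationFault",
    "FlowField",
    "water_reabsorption",
    "compute_flows",
    "tubular_rhs",
    "interstitial_rhs",
    "peritubular_rhs",
    "vasa_recta_rhs",
    "body_rhs",
    "solute_derivatives",
]


class SimulationFault(RuntimeError):
    """Nonphysical flow state (e.g. filtration exceeding plasma flow)."""


@dataclass
class FlowField:
    """All water flows of one right-hand-side evaluation, L/min."""

    q_in: np.ndarray        # (16,) tubular inflow
    q_reabs: np.ndarray     # (16,) water reabsorption, clamped to [0, q_in]
    q_out: np.ndarray       # (16,) tubular outflow
    u_in_peritub: float
    u_out_peritub: float
    u_dvr_in: np.ndarray    # (3,) OM, IM-I, IM-II
    u_dvr_reabs: np.ndarray # (3,) unclamped, may be negative
    u_dvr_out: np.ndarray
    u_avr_in: np.ndarray    # (3,) same region order; flow direction IM-II -> OM
    u_avr_out: np.ndarray
    gfr_short: float
    gfr_long: float

    @property
    def urine_flow(self) -> float:
        """Flow leaving the terminal inner-medullary collecting duct."""
        return float(self.q_out[15])


def water_reabsorption(r_i: float, osm_int: float, osm_tub: float, q_in: float) -> float:
    """Osmotically driven water reabsorption from one tubular compartment.

    ``R_i (osm_int - osm_tub)`` clamped to ``[0, q_in]``: water never moves
    into the tubule, and no more can leave than flows in.
    """
    return min(max(r_i * (osm_int - osm_tub), 0.0), q_in)


def compute_flows(state: ModelState, params: ParameterSet, topo: KidneyTopology,
                  n_osmotic: float = 1.0) -> FlowField:
    """Evaluate every water flow from the current state.

    SNGFR values are read from the relaxed state variables; tubular chains
    are walked in flow order applying the reabsorption clamp.
    """
    sngfr_s = max(state.sngfr_s, 0.0)
    sngfr_l = max(state.sngfr_l, 0.0)
    gfr_s = params.n_short * sngfr_s
    gfr_l = params.n_long * sngfr_l
    if gfr_s + gfr_l >= params.rpf:
        raise SimulationFault(
            f"total GFR {gfr_s + gfr_l:.3e} L/min reached renal plasma flow {params.rpf:.3e}")

    osm_tub = osmolality(state.c_tub[:, NA], state.c_tub[:, UREA], state.c_tub[:, DRUG], n_osmotic)
    osm_int = osmolality(state.c_int[:, NA], state.c_int[:, UREA], state.c_int[:, DRUG], n_osmotic)
    osm_int_of_tub = osm_int[topo.region]

    q_in = np.zeros(16)
    q_reabs = np.zeros(16)
    q_out = np.zeros(16)

    def walk(chain, inflow):
        q = inflow
        for i in chain:
            q_in[i] = q
            q_reabs[i] = water_reabsorption(topo.r_water[i], osm_int_of_tub[i], osm_tub[i], q)
            q = q - q_reabs[i]
            q_out[i] = q
        return q

    walk(SHORT_CHAIN, gfr_s)
    walk(LONG_CHAIN, gfr_l)
    walk(CD_CHAIN, q_out[SHORT_CHAIN[-1]] + q_out[LONG_CHAIN[-1]])

    cortex_reabs = float(q_reabs[topo.region == 0].sum())
    u_in_peritub = params.f_peritub * (params.rpf - gfr_s - gfr_l)
    u_out_peritub = u_in_peritub + cortex_reabs

    # DVR chain: OM -> IM-I -> IM-II; reabsorption is bidirectional.  The
    # osmotic law is limited only by water availability: a DVR segment can
    # neither lose more water than flows into it nor draw more water back
    # than the ascending side can supply.  The availability bounds couple
    # the two chains, so they are resolved by a short fixed-point sweep;
    # away from the bounds a single pass is exact.
    osm_dvr = osmolality(state.c_dvr[:, NA], state.c_dvr[:, UREA], state.c_dvr[:, DRUG], n_osmotic)
    raw_reabs = topo.r_dvr * (osm_int[1:] - osm_dvr)
    med_reabs = np.array([float(q_reabs[topo.region == j].sum()) for j in (1, 2, 3)])
    u_dvr_inflow = (1.0 - params.f_peritub) * (params.rpf - gfr_s - gfr_l)

    u_dvr_in = np.zeros(3)
    u_dvr_reabs = np.zeros(3)
    u_dvr_out = np.zeros(3)
    u_avr_in = np.zeros(3)
    u_avr_out = np.zeros(3)
    lower = np.full(3, -np.inf)
    for _ in range(40):
        u = u_dvr_inflow
        for m in range(3):
            u_dvr_in[m] = u
            u_dvr_reabs[m] = min(max(raw_reabs[m], lower[m]), u)
            u = u - u_dvr_reabs[m]
            u_dvr_out[m] = u
        # AVR chain runs IM-II -> IM-I -> OM; arrays stay in region order
        u = u_dvr_out[2]  # deepest AVR inflow = deepest DVR outflow
        deficit = None
        for m in (2, 1, 0):
            u_avr_in[m] = u
            u = u + u_dvr_reabs[m] + med_reabs[m]
            u_avr_out[m] = u
            if u < -1e-18 and deficit is None:
                deficit = m
        if deficit is None:
            break
        lower[deficit] = u_dvr_reabs[deficit] - u_avr_out[deficit]
    else:
        raise SimulationFault("vasa recta water balance did not stabilize")

    return FlowField(
        q_in=q_in, q_reabs=q_reabs, q_out=q_out,
        u_in_peritub=u_in_peritub, u_out_peritub=u_out_peritub,
        u_dvr_in=u_dvr_in, u_dvr_reabs=u_dvr_reabs, u_dvr_out=u_dvr_out,
        u_avr_in=u_avr_in, u_avr_out=u_avr_out,
        gfr_short=gfr_s, gfr_long=gfr_l,
    )


# ---------------------------------------------------------------------------
# Right-hand sides (all return dC/dt, umol/L/min)

_UPSTREAM = {}
for chain in (SHORT_CHAIN, LONG_CHAIN, CD_CHAIN):
    for a, b in zip(chain[:-1], chain[1:]):
        _UPSTREAM[b] = a


def _arterial(state: ModelState, params: ParameterSet) -> np.ndarray:
    """Arterial concentrations feeding glomeruli, peritubular caps and DVR."""
    return np.array([params.c_na_systemic, params.c_urea_systemic,
                     state.a_plasma / params.v_plasma])


def solute_derivatives(state: ModelState, flows: FlowField, params: ParameterSet,
                       topo: KidneyTopology):
    """dC/dt for every kidney compartment and solute.

    Returns ``(dc_tub (16,3), dc_int (4,3), dc_peritub (3,), dc_dvr (3,3),
    dc_avr (3,3))``.
    """
    c_art = _arterial(state, params)
    c_tub, c_int = state.c_tub, state.c_int
    c_int_of_tub = c_int[topo.region]

    # --- tubular compartments -------------------------------------------
    influx = np.empty((16, 3))
    influx[0] = flows.q_in[0] * c_art
    influx[4] = flows.q_in[4] * c_art
    for i in range(16):
        up = _UPSTREAM.get(i)
        if up is not None:
            influx[i] = flows.q_out[up] * c_tub[up]
    influx[12] = flows.q_out[3] * c_tub[3] + flows.q_out[11] * c_tub[11]

    k_act = np.zeros((16, 3))
    k_act[:, NA] = topo.k_active_na
    k_pas = np.zeros((16, 3))
    k_pas[:, NA] = topo.k_passive_na
    k_pas[:, UREA] = topo.k_passive_urea

    dc_tub = (influx - flows.q_out[:, None] * c_tub
              - k_act * c_tub - k_pas * (c_tub - c_int_of_tub)) / topo.v_tub[:, None]

    # --- interstitial regions -------------------------------------------
    dc_int = np.zeros((4, 3))
    active_in = np.zeros((4, 3))
    passive_in = np.zeros((4, 3))
    reabs_out = np.zeros(4)
    np.add.at(active_in, topo.region, k_act * c_tub)
    np.add.at(passive_in, topo.region, k_pas * (c_tub - c_int_of_tub))
    np.add.at(reabs_out, topo.region, flows.q_reabs)

    dc_int += active_in + passive_in - reabs_out[:, None] * c_int
    # vascular exchange: cortex <-> peritubular; medulla <-> DVR + AVR
    dc_int[0] -= params.ps_peritubular * (c_int[0] - state.c_peritub)
    dc_int[1:] -= topo.ps_dvr * (c_int[1:] - state.c_dvr)
    dc_int[1:] -= topo.ps_avr[:, None] * (c_int[1:] - state.c_avr)
    dc_int /= topo.v_int[:, None]

    # --- peritubular plasma ---------------------------------------------
    dc_peritub = (flows.u_in_peritub * c_art - flows.u_out_peritub * state.c_peritub
                  + reabs_out[0] * c_int[0]
                  + params.ps_peritubular * (c_int[0] - state.c_peritub)) / topo.v_peritub

    # --- vasa recta ------------------------------------------------------
    dc_dvr = np.zeros((3, 3))
    up_dvr = [c_art, state.c_dvr[0], state.c_dvr[1]]
    for m in range(3):
        dc_dvr[m] = (flows.u_dvr_in[m] * up_dvr[m] - flows.u_dvr_out[m] * state.c_dvr[m]
                     + topo.ps_dvr[m] * (c_int[m + 1] - state.c_dvr[m])) / topo.v_dvr[m]

    dc_avr = np.zeros((3, 3))
    med_reabs = reabs_out[1:]
    up_avr = [state.c_avr[1], state.c_avr[2], state.c_dvr[2]]  # region order OM, IM-I, IM-II
    for m in range(3):
        dc_avr[m] = (flows.u_avr_in[m] * up_avr[m] - flows.u_avr_out[m] * state.c_avr[m]
                     + med_reabs[m] * c_int[m + 1]
                     + topo.ps_avr[m] * (c_int[m + 1] - state.c_avr[m])) / topo.v_avr[m]

    return dc_tub, dc_int, dc_peritub, dc_dvr, dc_avr


def flux_terms(compartment: str, state: ModelState, flows: FlowField,
               params: ParameterSet, topo: KidneyTopology) -> dict:
    """Named flux terms (umol/min) of one tubular compartment, per solute.

    Term-level introspection for testing: advection_in, advection_out,
    active, passive.  ``V dC/dt = advection_in - advection_out - active -
    passive``.
    """
    i = TUBULAR_COMPARTMENTS.index(compartment)
    c_art = _arterial(state, params)
    if i in (0, 4):
        adv_in = flows.q_in[i] * c_art
    elif i == 12:
        adv_in = flows.q_out[3] * state.c_tub[3] + flows.q_out[11] * state.c_tub[11]
    else:
        up = _UPSTREAM[i]
        adv_in = flows.q_out[up] * state.c_tub[up]
    k_act = np.array([topo.k_active_na[i], 0.0, 0.0])
    k_pas = np.array([topo.k_passive_na[i], topo.k_passive_urea[i], 0.0])
    return {
        "advection_in": adv_in,
        "advection_out": flows.q_out[i] * state.c_tub[i],
        "active": k_act * state.c_tub[i],
        "passive": k_pas * (state.c_tub[i] - state.c_int[topo.region[i]]),
    }


def tubular_rhs(compartment: str, state: ModelState, flows: FlowField,
                params: ParameterSet, topo: KidneyTopology) -> np.ndarray:
    """dC/dt (umol/L/min) of one tubular compartment, per solute."""
    i = TUBULAR_COMPARTMENTS.index(compartment)
    return solute_derivatives(state, flows, params, topo)[0][i]


def interstitial_rhs(region: str, state: ModelState, flows: FlowField,
                     params: ParameterSet, topo: KidneyTopology) -> np.ndarray:
    from .model_core import REGIONS
    j = REGIONS.index(region)
    return solute_derivatives(state, flows, params, topo)[1][j]


def peritubular_rhs(state: ModelState, flows: FlowField,
                    params: ParameterSet, topo: KidneyTopology) -> np.ndarray:
    return solute_derivatives(state, flows, params, topo)[2]


def vasa_recta_rhs(segment: str, state: ModelState, flows: FlowField,
                   params: ParameterSet, topo: KidneyTopology) -> np.ndarray:
    """dC/dt of one vasa recta segment, e.g. ``"dvr_outer_medulla"``,
    ``"avr_inner_medulla_2"``."""
    kind, _, region = segment.partition("_")
    from .model_core import MEDULLARY_REGIONS
    m = MEDULLARY_REGIONS.index(region)
    _, _, _, dc_dvr, dc_avr = solute_derivatives(state, flows, params, topo)
    if kind == "dvr":
        return dc_dvr[m]
    if kind == "avr":
        return dc_avr[m]
    raise ValueError(f"unknown vasa recta segment {segment!r}")


def body_rhs(state: ModelState, flows: FlowField, dose_rate: float,
             params: ParameterSet) -> tuple:
    """Drug amount derivatives (umol/min) of the two body compartments.

    The plasma compartment receives the dosing rate and the renal venous
    return (peritubular + outer-medullary AVR outflow), delivers drug to the
    kidney by the renal plasma flow, and exchanges with the residual
    extracellular space by a first-order clearance.
    """
    c_plasma = state.a_plasma / params.v_plasma
    c_ec = state.a_extracellular / params.v_extracellular
    venous = (flows.u_out_peritub * state.c_peritub[DRUG]
              + flows.u_avr_out[0] * state.c_avr[0, DRUG])
    exchange = params.q_exchange * (c_plasma - c_ec)
    da_plasma = dose_rate + venous - params.rpf * c_plasma - exchange
    da_ec = exchange
    return da_plasma, da_ec
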