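"""Viscosity model, single-nephron pressure recursion and SNGFR.

Tubular fluid viscosity rises exponentially with contrast-medium
concentration, eta(C) = eta_w * exp(b*C).  Hydrostatic pressures along a
single short-loop nephron, a single long-loop nephron, and the merging
collecting-duct chain are obtained by walking upstream from the fixed
pelvic pressure P_e with Hagen-Poiseuille type pressure drops; segments
with fluid reabsorption use the flow profile of exponentially decaying
flow.  The single-nephron glomerular filtration rate follows from the
pressure difference between the glomerular capillaries and the proximal
tubule inlet across an effective glomerular resistance.  Because SNGFR
feeds back into the flows that set the pressures, the algebraic loop is
closed by relaxing SNGFR as a stiff ODE state with time constant p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import (
    CD_CHAIN, LONG_CHAIN, MMHG_PA, SHORT_CHAIN,
    KidneyTopology, ParameterSet,
)
from .transport import FlowField, SimulationFault

__all__ = [
    "PressureProfile",
    "viscosity",
    "fit_viscosity_exponent",
    "segment_pressure_drop",
    "pressure_recursion",
    "sngfr",
    "relax_algebraic",
]

_EXP_CAP = 50.0  # caps eta/eta_w at e^50; far beyond any physical regime


def viscosity(c_drug, b: float, eta_water: float):
    """Dynamic viscosity of tubular fluid, mPa.s.

    ``b`` is the substance's viscosity exponent in L/umol (0 for mannitol,
    which is assumed not to alter viscosity).
    """
    c = np.maximum(c_drug, 0.0)
    return eta_water * np.exp(np.minimum(b * c, _EXP_CAP))


def fit_viscosity_exponent(concentrations_umol_L, viscosities_mPa_s,
                           eta_water: float) -> float:
    """Least-squares fit of the exponent b through the origin.

    Fits ``log(eta/eta_w) = b * C`` to (molar concentration, viscosity)
    pairs.  With a single point this reduces to ``b = ln(eta0/eta_w)/C0``.
    """
    c = np.asarray(concentrations_umol_L, dtype=float)
    eta = np.asarray(viscosities_mPa_s, dtype=float)
    if c.size == 0 or np.all(eta <= eta_water):
        raise ValueError("need at least one point with viscosity above that of water")
    y = np.log(eta / eta_water)
    return float(np.dot(c, y) / np.dot(c, c))


def segment_pressure_drop(eta: float, length: float, radius: float,
                          qsn_in: float, qsn_reabs: float = 0.0) -> float:
    """Pressure drop over one single-nephron tubular segment, mmHg.

    Parameters are in internal units: eta mPa.s, length/radius m, flows
    L/min.  Without reabsorption this is the Hagen-Poiseuille drop
    ``8 eta L q / (pi r^4)``; with reabsorption (assumed proportional to
    local flow) the drop is reduced by the factor ``x / (-ln(1-x))`` with
    ``x = qsn_reabs/qsn_in``.
    """
    if qsn_in <= 0.0:
        return 0.0
    if qsn_reabs < 0.0 or qsn_reabs > qsn_in:
        raise ValueError("reabsorbed flow must lie in [0, qsn_in]")
    # mPa.s -> Pa.s (1e-3), L/min -> m^3/s (1e-3/60); result Pa -> mmHg
    q_si = qsn_in * 1e-3 / 60.0
    dp_pa = 8.0 * (eta * 1e-3) * length * q_si / (math.pi * radius ** 4)
    x = qsn_reabs / qsn_in
    if x > 1e-12:
        x = min(x, 1.0 - 1e-12)
        dp_pa *= x / (-math.log1p(-x))
    return dp_pa / MMHG_PA


@dataclass
class PressureProfile:
    """Hydrostatic pressures and single-nephron flows along the nephron paths."""

    p_in: np.ndarray        # (16,) pressure at the inlet of each segment, mmHg
    p_out: np.ndarray       # (16,) pressure at the outlet, mmHg
    eta: np.ndarray         # (16,) per-segment viscosity, mPa.s
    qsn_in: np.ndarray      # (16,) per-tube inflow, L/min
    qsn_reabs: np.ndarray   # (16,)

    @property
    def p_1s(self) -> float:
        """Pressure at the proximal tubule inlet, short loop (PTHP)."""
        return float(self.p_in[0])

    @property
    def p_1l(self) -> float:
        return float(self.p_in[4])

    @property
    def dthp(self) -> float:
        """Pressure at the distal tubule inlet of the short-loop path."""
        return float(self.p_in[3])


def pressure_recursion(flows: FlowField, c_drug_tub, b: float,
                       params: ParameterSet, topo: KidneyTopology) -> PressureProfile:
    """Walk the pressure profile upstream from the collecting-duct end.

    Whole-kidney flows are converted to per-tube flows by dividing by the
    number of parallel tubes each compartment represents (nephron counts;
    for collecting ducts the duct counts, which fall towards the papilla as
    ducts merge).
    """
    eta = viscosity(np.asarray(c_drug_tub, dtype=float), b, params.eta_water)
    qsn_in = flows.q_in / topo.n_tubes
    qsn_reabs = flows.q_reabs / topo.n_tubes
    if np.any(qsn_in < -1e-30):
        raise SimulationFault("negative tubular flow in pressure recursion")

    p_in = np.zeros(16)
    p_out = np.zeros(16)

    def walk_up(chain, p_end):
        p = p_end
        for i in reversed(chain):
            p_out[i] = p
            p = p + segment_pressure_drop(eta[i], topo.length[i], topo.radius[i],
                                          qsn_in[i], qsn_reabs[i])
            p_in[i] = p
        return p

    p_junction = walk_up(CD_CHAIN, params.p_e)
    walk_up(SHORT_CHAIN, p_junction)
    walk_up(LONG_CHAIN, p_junction)
    return PressureProfile(p_in=p_in, p_out=p_out, eta=eta,
                           qsn_in=qsn_in, qsn_reabs=qsn_reabs)


def sngfr(p_g: float, p_1: float, r_glom: float) -> float:
    """Single-nephron GFR from the glomerular pressure difference, L/min.

    ``(P_g - P_1)/R_glom``, floored at zero (no reverse filtration).
    """
    return max((p_g - p_1) / r_glom, 0.0)


def relax_algebraic(y: float, target: float, p: float) -> float:
    """Stiff-ODE relaxation of an algebraic condition: dy/dt = (-y + F)/p."""
    return (-y + target) / p
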