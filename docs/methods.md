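# Methods

## Model structure and assumptions

The kidney is discretized into four regions along the cortico-medullary
axis; each region holds well-stirred compartments for tubular lumina
(separately for short- and long-loop nephrons plus a merged collecting-duct
chain), interstitial space, and vascular plasma (peritubular capillaries in
the cortex; descending and ascending vasa recta, DVR/AVR, in the medulla).
Compartment volumes are fixed: there is no dynamic swelling of tubules or
interstitium, and tubules are non-compliant (constant radii). The cellular
space is not a dynamic compartment; it enters only the tissue-concentration
observable with fixed sodium (25 mM in inner medulla II, 15 mM elsewhere),
urea equal to the local interstitial value, and no drug.

Species: sodium (osmotic coefficient 2, for its accompanying anions), urea,
and one administered agent with `n` osmotically active particles per
molecule (1 non-ionic, 2 ionic). Systemic sodium and urea are constant
boundary conditions (150 mM, 6 mM); the agent distributes over a
two-compartment body (plasma 2.41 ml, residual extracellular space 44.6 ml)
and reaches the kidney with the renal plasma flow. Hydrophilic agents are
freely filtered (no protein binding, sieving 1) and neither secreted nor
reabsorbed across the epithelium; they cross only the vascular walls, by
permeability–surface-area clearances.

Water reabsorption from each water-permeable tubular segment is
`R_i (osm_int − osm_tub)`, clamped to `[0, q_in]`. The clamp is hard; the
solver (BDF) handles the kinks. Reabsorbed water is solute-free across the
epithelium, dilutes the interstitium, and is swept into the local
capillaries (peritubular in the cortex, AVR in the medulla) carrying the
interstitial concentration, so all exchange terms are antisymmetric and
solute mass is conserved exactly up to the boundaries (arterial inflow,
venous return, urine).

DVR water flux uses the same osmotic law without the lower clamp
(bidirectional). It is, however, bounded by water availability: a DVR
segment can neither lose more water than flows into it nor draw back more
than the ascending side can supply. The bounds couple the descending and
ascending chains and are resolved by a short fixed-point sweep; away from
the bounds (in particular at every converged steady state we report) a
single pass is exact and the published flux law holds unmodified. Without
the bounds the uniform-start transient reaches negative vascular flows and
the integration cannot proceed.

The vascular chain inflows split the post-glomerular plasma flow
`RPF − GFR` into a peritubular fraction `f_peritub = 0.85` and the DVR
complement `0.15`; the deepest AVR segment takes the deepest DVR outflow,
and the outer-medullary AVR outflow returns venously to the body plasma
compartment directly (whether it first traverses the cortex is unspecified
anatomically; the direct route was chosen). The arterial concentration
feeding glomeruli, peritubular capillaries and DVR is the body plasma
concentration — arterial and venous plasma are not distinguished.

## Pressure sub-model and filtration

Hydrostatic pressures are evaluated on a single-nephron representation:
whole-kidney flows divided by nephron counts (53,200 short, 22,800 long),
and collecting-duct flows divided by duct counts, which fall from 1 duct
per 4 nephrons in the cortex to 1 per 310 in inner medulla II as ducts
merge. Starting from the fixed pelvic pressure P_e = 3 mmHg at the end of
the papillary collecting duct, pressures are walked upstream segment by
segment with Hagen–Poiseuille-type drops; segments with fluid reabsorption
use the closed form for exponentially decaying flow,
`ΔP = 8ηLq_reabs/(πr⁴ ln[q_in/(q_in−q_reabs)])`, which analytically reduces
to the plain Poiseuille drop as reabsorption vanishes. Per-segment
viscosity is `η_w exp(b C_drug)` with that compartment's current drug
concentration; mannitol is assigned b = 0 (water viscosity throughout).
Unit conversions (mPa·s, m, L/min → mmHg) happen only inside the
pressure-drop routine, with 1 mmHg = 133.322 Pa.

SNGFR = (P_g − P_1)/R_glom, floored at zero, with fixed glomerular
pressures (44.2 / 47.2 mmHg short/long) and resistance 2.205×10⁹
mmHg·min/L. Since SNGFR sets the flows that set the pressures that set
SNGFR, the two SNGFR values are the only relaxed algebraic states,
`dy/dt = (−y + F)/p` with p = 0.1 min; pressures themselves are recomputed
explicitly at every right-hand-side evaluation. No tubuloglomerular
feedback, renin–angiotensin–aldosterone regulation, or medullary blood-flow
autoregulation is represented.

## Parameters

All published table values ship verbatim (on their printed scale) in
`src/nephroflow/data/parameters.json` and are unit-normalized exactly once
at load into the internal system (L, min, μmol, mmHg, mPa·s); permeabilities
in cm/s become clearances P·S in L/min; the AVR surface is constructed as
twice the DVR surface per region. Serialization reproduces the printed
values bit-exactly.

One structural convention is not determined by the tables: transport
parameters are listed once per segment class (e.g. "proximal tubule"), but
the proximal, distal and outer-medullary limb classes exist as two
compartments, one per nephron population. The allocation is parameterized
as nephron-count-proportional weights (0.7/0.3) times a single
pair-allocation gain. The gain is the one free constant of the model and is
calibrated by bisection so that the drug-free steady state reproduces the
5.6 μL/min urine flow of the normally hydrated rat — the datum the
transport tables were themselves identified against. The packaged value is
3.35 (`nephroflow.simulation.calibrate_pair_allocation` re-derives it);
with it the steady state also reproduces the whole-animal GFR
(1.313 vs 1.31 ml/min) without any further adjustment. Collecting-duct and
inner-medullary entries, which map to single compartments, are used exactly
as printed. Note 0.3 × 3.35 ≈ 1.0: the calibrated convention is equivalent
to assigning each long-loop compartment the printed value and scaling the
short-loop compartment by the population ratio.

Other conventions chosen where the published description is silent:

- Water viscosity η_w = 0.6913 mPa·s (water at 37 °C), configurable.
- Body–extracellular exchange is flow-limited: clearance = total body
  plasma flow − RPF = 0.01859 L/min, configurable.
- Boluses are 1-min infusions by default (configurable per dose event).
- Contrast-media viscosity exponents are fit on molar concentration from
  vendor-brochure (iodine concentration, viscosity) points at 37 °C stored
  in the substance library; a single point gives b = ln(η/η_w)/C exactly.
  The "perfect dimer" shares iopromide's viscosity-vs-iodine-concentration
  curve, hence twice iopromide's molar exponent, with iodixanol's molar
  mass and six iodine atoms.
- Kidney exposure is the 0–3 h AUC of the volume-weighted whole-kidney
  concentration divided by the dose, with concentration and dose on
  matching bases (iodine mass for contrast media, moles for mannitol; the
  two give identical numbers). The glomerular plasma volume, which is not a
  dynamic compartment, contributes to tissue concentrations at the arterial
  concentration but is excluded from the mass-balance bookkeeping.
- PTHP is reported as the pressure at the proximal-tubule inlet of the
  short-loop path (P_1s), DTHP at the distal-tubule inlet.

## Numerics

The coupled system has 87 states (81 concentrations, 2 body amounts, 2
relaxed SNGFR states, cumulative urine volume and excreted amount). It is
stiff (fast modes ~ms from small-volume compartments and the relaxation
states) and integrated with scipy's BDF at rtol 1e-8 (1e-10 for
steady-state searches) and per-block absolute tolerances. The drug-free
steady state is found by long-horizon integration from a uniform start (all
compartments at systemic concentrations, SNGFR at its GFR₀-derived start
value) in growing chunks until the scaled right-hand-side norm, excluding
the cumulative outputs, falls below 1e-8 per minute — integration rather
than root finding so the reabsorption clamps are respected; the steady
state is a unique attractor under the packaged parameters (seeded-gradient
starts converge to the same state). Dosing discontinuities are integration
breakpoints, so each segment sees a smooth constant-rate source. The
viscosity exponent is capped at e⁵⁰ to keep transient overshoots finite.

Scenario problem sizes used by the test suite and the acceptance script:
the full 87-state system over 180 min for bolus panels, 451 min for the
mannitol protocol, 90–120 min for dose sweeps; observables on a 1–2 min
output grid. Peak observables change by <0.5 % on grid refinement.

## What the packaged scenarios do and do not show

The packaged scenarios are forward simulations of the published study
designs (mannitol priming + infusion; 1.5-ml contrast boluses; dose grids
in mOsm and mg iodine). They demonstrate the mechanistic couplings —
osmotic diuresis, urea-gradient breakdown, viscosity-driven pressure rise
and filtration drop, osmolality-driven kidney retention — as qualitative
orderings and conserved-mass properties. They are not re-identifications of
the transport parameters: the original calibration targets (tissue-gradient
and reabsorption profiles) exist only as figures and are not reproduced
numerically. Real-data features outside the model include tubular
compliance, tubuloglomerular feedback, ureter transit lag, cellular uptake
by vacuolization, and nephron-length distributions; predictions for urine
viscosity in particular inherit the exponential sensitivity of η(C) to
concentration errors.
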