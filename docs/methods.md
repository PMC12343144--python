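# Methods

## Model

The package implements a deterministic compartmental model of the cell
populations interacting in peritoneal fluid during early superficial
peritoneal endometriosis lesion onset. Eight state variables
(cells·ml⁻¹): resting/pro-inflammatory/pro-repair macrophages (M0, M1,
M2), resting/activated NK cells (K0, KA), and eutopic/in-fluid/attached
endometrial cells (E0, EF, EA). Transitions follow mass-action or Hill
kinetics; proliferation and production are logistic. The full term
structure is documented in `endoimmune.model_core.rhs` and mirrored by an
independent term-by-term oracle in the test suite.

Assumptions worth making explicit:

* macrophage activation is binary (M1/M2), standing in for a continuous
  activation spectrum; M1 is strictly anti-lesion, M2 strictly pro-lesion;
* NK activation requires M1 (via pro-inflammatory cytokines), and
  activated NK cells are the dominant clearance effectors (`gamma`, the
  NK share of clearance, defaults to 0.95);
* NK exhaustion is proportional to encounters with ectopic cells
  (`sigma·(EF+EA)·KA`) — this is the positive feedback that makes the
  diseased state self-sustaining: a large attached population exhausts
  the NK pool, which removes the clearance pressure on itself;
* endometrial transitions are strictly sequential (E0 → EF → EA, no
  detachment); E0 is forced, not regulated, so its equation is linear.

Menstrual forcing: `mu_E(t) = a_E·|sin(pi·(t+d_E)/cycle_length)|^b_E` —
non-negative and 28-day periodic for any real `b_E ≥ 1`, with one
menstrual peak per cycle. The *surrogate model* replaces `mu_E(t)` by its
cycle average (computed by adaptive quadrature, relative tolerance
1e-12), making the system autonomous so that steady states, eigenvalues
and bifurcations are well-defined.

## Parameters

All 33 constants plus the cycle length live in a single flat
`ParameterSet` (units: days, cells·ml⁻¹; bimolecular rates in
cells⁻¹·ml·day⁻¹). The values printed in the primary description of the
model are kept verbatim: detection β₁ = 10⁻⁶ cells⁻¹·ml·day⁻¹, clearance
ω = 10⁻⁵ cells⁻¹·ml·day⁻¹, retrograde fraction ρ₀ spanning 0.005–0.1,
cycle length 28 d, attachment threshold ε = 1 cell·ml⁻¹. The remaining
constants are a **calibrated set**: they were chosen once, as a package
design decision, so that the model reproduces the documented qualitative
regimes, and are shipped frozen in `endoimmune.fixtures.DEFAULTS`:

* the baseline cyclic run clears all ectopic cells (EF, EA) before each
  cycle end and reaches a periodic attractor within ten cycles;
* (β₁ = 10⁻⁶, ω = 10⁻⁵, ρ₀ = 0.1) lies inside a bistable window of the
  surrogate model (folds at ω ≈ 4.9·10⁻⁶ and ≈ 1.1·10⁻⁵);
* raising ρ₀ raises mean M1 fraction and mean activated-NK concentration
  monotonically while leaving the M2 fraction nearly unchanged (<5%
  relative spread), and does not produce sustained attachment;
* reducing ω to 3·10⁻⁶ produces sustained attachment (diseased regime).

Magnitudes follow peritoneal-fluid scales: macrophage capacity 10⁵
cells·ml⁻¹, NK capacity 2·10⁴ cells·ml⁻¹, lesion carrying capacity 10⁶
cells·ml⁻¹; turnover times of days to weeks. The influx shape b_E = 20,
d_E = 9 d gives a ≈5-day menstrual pulse early in the cycle with
negligible influx at cycle boundaries. The attachment rate ρ_F = 10⁻⁶
day⁻¹ keeps the disease-free equilibrium's attached population well below
the ε = 1 cell·ml⁻¹ threshold throughout the low-attachment region; the
`transient` fixture raises it 150-fold to realize the
transient-attachment regime.

Named fixtures (`reference`, `low_influx`, `transient`, `bistable`,
`diseased`) pin these regimes and are behaviourally verified by the test
suite.

## Numerical choices

* **Integration** — `scipy.integrate.solve_ivp` with LSODA (stiff-capable,
  variable step), rel_tol 1e-8 / abs_tol 1e-10, sampled on a uniform
  0.1-day output grid. End-of-cycle values are taken at exact multiples
  of the cycle length (the grid contains them; interpolation is used for
  off-grid queries). Solvers may step slightly negative: saturating and
  mass-action terms evaluate a state clamped at zero while linear
  turnover uses the raw value, so excursions decay back; any excursion
  beyond −10⁻⁶ cells·ml⁻¹ aborts with a diagnostic.
* **Two-stage initialization** — every cyclic study starts from the
  surrogate-model steady state, obtained by ≥4000 days of constant-influx
  integration from a documented guess (1 cell·ml⁻¹ in each immune
  compartment, endometrial compartments empty) followed by Newton
  polishing with the analytic Jacobian to residual ≤ 10⁻⁸
  cells·ml⁻¹·day⁻¹. Oscillatory non-convergence returns the cycle-mean
  state with a limit-cycle flag.
* **Equilibria** — multi-start root finding (seeded log-uniform starts
  per compartment plus two deterministic starts), deduplicated at
  relative distance 10⁻⁶, restricted to the non-negative orthant, and
  classified by the eigenvalues of the analytic Jacobian (marginal when
  |max Re λ| ≤ 10⁻⁶ day⁻¹). An equilibrium counts as disease-free when
  EA ≤ 10⁻³ cells·ml⁻¹ — exact zero is unattainable because the
  attachment source ρ_F·EF is always positive.
* **Continuation** — pseudo-arclength with a secant predictor and a
  Newton corrector on the bordered system, in log₁₀ of the continued
  parameter with per-compartment state scaling. Folds are detected by
  sign change of the parameter tangent and refined by shrinking the
  arclength step until the bracketing parameters agree to 10⁻⁴ relative.
  Unstable segments with a complex leading pair are reported as
  limit-cycle candidates.
* **Limit cycles** — detected by long constant-influx simulation from a
  perturbed state and peak-train regularity (relative period jitter
  < 10⁻³), characterized by the period and the median EA over one period;
  region labels use that median. Under the shipped calibration no
  oscillatory (complex-unstable) equilibria arise anywhere in the scanned
  (β₁, ω) region, so region maps contain no reclassified cells; the
  reclassification rule is exercised in the test suite through its
  contract.
* **Classification ties** — the attachment labels use strict inequalities
  (EA identically equal to ε is *low*); trajectories whose end-of-cycle
  values straddle ε after the transient are labelled by the final cycle
  and flagged non-converged (this occurs transiently near bifurcation
  boundaries).
* **Transient** — τ defaults to 5 cycles (140 d); studies default to 10
  cycles so at least five post-transient cycles inform every metric.

## Experiment scales

Desk-scale defaults keep every pipeline in seconds-to-minutes on one
core: dysfunction heatmaps default to 30×30 (β₁, ω) grids (the validation
suite uses 15×15), transition maps to 25-point ω grids, hysteresis sweeps
to 15–25 quasi-static steps of ≥2500 settle-days each. The quantities of
interest (fold locations, labels, monotone trends) are grid-converged at
these sizes; halving the sampling interval changes no label in the
shipped regimes.

## What the synthetic regimes do and do not show

The fixtures emulate the *qualitative* physiology: pulsed menstrual
influx, a macrophage/NK response with realistic concentration scales, and
a clearance-vs-proliferation contest near its tipping point. They do not
carry patient-calibrated rate constants, hormonal regulation, cytokine
intermediates, adaptive immunity, stochastic cell-number effects, or
cycle-length variability. Passing tests therefore demonstrate the
mechanisms — inflammation rising with retrograde influx without disease,
clearance loss as the dominant disease driver, fold-bounded hysteresis of
onset and recovery — not quantitative predictions for real patients.

## Known limitations

* The calibrated constants are a stand-in for an unavailable reference
  parameterization; quantitative outputs (fold positions, equilibrium
  concentrations) are calibration-dependent even where the qualitative
  structure is robust.
* The bistable window is reported for the surrogate model; under cyclic
  forcing the basin boundaries shift slightly within the window.
* No Hopf bifurcations occur under the shipped calibration, so the
  limit-cycle reclassification path is dormant in the default maps.
* Continuation handles one parameter at a time; the co-dimension-2 map is
  grid-based rather than a continued fold curve.
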