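"""Equilibrium continuation, fold detection, limit cycles and region maps.

The surrogate (constant-influx) system is bistable in parts of the
(detection, clearance) = (``beta_1``, ``omega``) plane: a low-attachment
and a high-attachment stable equilibrium coexist, separated by an unstable
saddle branch.  The branch is traced by pseudo-arclength continuation
(secant predictor, damped Newton corrector on a bordered system); folds
(saddle-nodes) appear as turning points of the continuation parameter and
bound the hysteresis window.

Attractors that are limit cycles rather than equilibria are characterized
by long simulation and peak detection, and region labels are assigned from
the median attached-cell concentration over one period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .classify import DEFAULT_EPSILON
from .equilibria import (
    EPS_EQ,
    Equilibrium,
    _classify,
    find_equilibria,
    jacobian,
)
from .model_core import InfluxMode, ParameterSet, SystemState, rhs

__all__ = [
    "Branch",
    "BranchPoint",
    "LimitCycleInfo",
    "RegionMap",
    "StepControl",
    "continue_branch",
    "characterize_limit_cycle",
    "classify_region",
    "codim2_region_map",
    "hysteresis_sweep",
]

VARYABLE = ("omega", "beta_1")

# per-compartment scales used to non-dimensionalize the arclength metric
def _state_scales(params: ParameterSet) -> np.ndarray:
    return np.array([
        params.M_C, params.M_C, params.M_C,
        params.K_C, params.K_C,
        max(params.a_E / max(params.delta_E0, 1e-12), 1.0),
        params.E_C * 1e-2, params.E_C,
    ]) * 0.1


def _dF_dparam(x: np.ndarray, params: ParameterSet, vary: str) -> np.ndarray:
    """Analytic derivative of the constant-mode RHS w.r.t. omega or beta_1."""
    M0, M1, M2, K0, KA, E0, EF, EA = np.maximum(x, 0.0)
    out = np.zeros(8)
    if vary == "omega":
        immune = params.gamma * KA + (1.0 - params.gamma) * M1
        out[6] = -immune * EF
        out[7] = -immune * EA
    elif vary == "beta_1":
        E = EF + EA
        out[0] = -E * M0
        out[1] = E * M0
    else:
        raise ValueError(f"vary must be one of {VARYABLE}, got {vary!r}")
    return out


@dataclass(frozen=True)
class StepControl:
    """Arclength step control for continuation (steps in the scaled
    (state, log10-parameter) metric)."""

    h0: float = 0.02
    h_min: float = 1e-7
    h_max: float = 0.2
    max_points: int = 2000
    newton_tol: float = 1e-10
    newton_maxit: int = 25
    fold_rtol: float = 1e-4


@dataclass
class BranchPoint:
    param: float
    eq: Equilibrium


@dataclass
class Branch:
    vary: str
    points: list[BranchPoint] = field(default_factory=list)
    folds: list[float] = field(default_factory=list)
    oscillatory_segments: list[tuple[float, float]] = field(default_factory=list)
    message: str = ""

    @property
    def params_values(self) -> np.ndarray:
        return np.array([pt.param for pt in self.points])

    def to_frame(self):
        import pandas as pd

        rows = []
        for pt in self.points:
            row = {"param_value": pt.param}
            row.update(pt.eq.state.to_dict())
            row["max_re_eig"] = pt.eq.max_re
            row["stability"] = pt.eq.stability
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class LimitCycleInfo:
    period: float            # days
    median_EA: float         # median of EA over one period
    amplitude_EA: float      # peak-to-trough EA over one period
    min_EA: float = 0.0
    max_EA: float = 0.0
    cycle_found: bool = True
    message: str = ""


def _corrector(x_guess, s_guess, params, vary, tangent, u_prev, h, scales, ctl):
    """Damped Newton on the bordered system [rhs; arclength constraint]."""
    mode_cache: dict[float, InfluxMode] = {}

    def make_params(s):
        return params.replace(**{vary: 10.0 ** s})

    x, s = x_guess.copy(), s_guess
    for _ in range(ctl.newton_maxit):
        if not np.isfinite(s) or abs(s - s_guess) > 2.0:
            return None
        p = make_params(s)
        if s not in mode_cache:
            mode_cache[s] = InfluxMode.constant(p)
        mode = mode_cache[s]
        F = rhs(0.0, x, p, mode)
        u = np.concatenate([x / scales, [s]])
        g = tangent @ (u - u_prev) - h
        if np.max(np.abs(F)) < ctl.newton_tol and abs(g) < 1e-12:
            return x, s, float(np.max(np.abs(F)))
        J = jacobian(np.maximum(x, 0.0), p)
        dFds = _dF_dparam(x, p, vary) * (10.0 ** s) * np.log(10.0)
        # row-scale the model equations so they are commensurate with the
        # O(1) arclength constraint row
        A = np.zeros((9, 9))
        A[:8, :8] = J / scales[:, None]
        A[:8, 8] = dFds / scales
        A[8, :8] = tangent[:8] / scales
        A[8, 8] = tangent[8]
        res = np.concatenate([F / scales, [g]])
        try:
            delta = np.linalg.solve(A, -res)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(delta)):
            return None
        # clip overlong Newton steps (in the scaled metric)
        size = max(abs(delta[8]) / 0.25, np.max(np.abs(delta[:8] / scales)))
        if size > 1.0:
            delta = delta / size
        x = x + delta[:8]
        s = s + delta[8]
    p = make_params(s)
    F = rhs(0.0, x, p, InfluxMode.constant(p))
    if np.max(np.abs(F)) < 1e-8:
        return x, s, float(np.max(np.abs(F)))
    return None


def continue_branch(
    params: ParameterSet,
    vary: str,
    p_range: tuple[float, float],
    init_eq: Equilibrium,
    step: StepControl | None = None,
) -> Branch:
    """Trace an equilibrium branch of the surrogate model in *vary*.

    Starts from *init_eq* (valid at ``params``, whose *vary* value must lie
    inside *p_range*) and follows the branch by pseudo-arclength
    continuation in both directions until the parameter range is covered or
    the corrector fails.  Fold locations are refined to relative accuracy
    ``step.fold_rtol`` by bisecting the arclength step across each turning
    point; eigenvalues are tracked along the branch and unstable segments
    with a complex leading pair are reported as limit-cycle candidates.
    """
    if vary not in VARYABLE:
        raise ValueError(f"vary must be one of {VARYABLE}, got {vary!r}")
    ctl = step or StepControl()
    lo, hi = sorted(float(v) for v in p_range)
    if not (lo > 0):
        raise ValueError("parameter range must be positive (log-scale continuation)")
    s_lo, s_hi = np.log10(lo), np.log10(hi)
    scales = _state_scales(params)

    p0 = float(getattr(params, vary))
    x0 = init_eq.state.to_array()
    s0 = np.log10(p0)

    def classify_point(x, s, rnorm):
        p = params.replace(**{vary: 10.0 ** s})
        return BranchPoint(param=10.0 ** s, eq=_classify(x, p, rnorm))

    half_branches = []
    for direction in (+1.0, -1.0):
        pts: list[tuple[np.ndarray, float]] = [(x0, s0)]
        folds: list[float] = []
        # initial tangent: pure parameter direction
        u_prev = np.concatenate([x0 / scales, [s0]])
        tangent = np.zeros(9)
        tangent[8] = direction
        h = ctl.h0
        msg = ""
        refining = 0
        last_dp_sign = direction
        while len(pts) < ctl.max_points:
            x_prev, s_prev = pts[-1]
            u_prev = np.concatenate([x_prev / scales, [s_prev]])
            guess = u_prev + h * tangent
            res = _corrector(guess[:8] * scales, guess[8], params, vary,
                             tangent, u_prev, h, scales, ctl)
            if res is None:
                if h > ctl.h_min:
                    h = max(h * 0.3, ctl.h_min)
                    continue
                msg = "corrector divergence: branch truncated"
                break
            x_new, s_new, rnorm = res
            u_new = np.concatenate([x_new / scales, [s_new]])
            # secant tangent for next step
            t_new = u_new - u_prev
            norm = np.linalg.norm(t_new)
            if norm == 0:
                msg = "stagnated"
                break
            t_new /= norm
            dp_sign = np.sign(t_new[8]) or last_dp_sign
            if dp_sign != last_dp_sign:
                # turning point crossed between the last two points
                if h > ctl.h_min and abs(10.0 ** s_new - 10.0 ** s_prev) \
                        > ctl.fold_rtol * 10.0 ** s_prev:
                    h = max(h * 0.25, ctl.h_min)
                    refining += 1
                    if refining < 60:
                        continue
                folds.append(float(10.0 ** max(s_new, s_prev)
                                   if direction > 0 else 10.0 ** min(s_new, s_prev)))
                # record the more extreme of the bracketing parameters
                folds[-1] = float(10.0 ** (s_new if
                                  (s_new - s_prev) * last_dp_sign > 0 else s_prev))
                last_dp_sign = dp_sign
                refining = 0
            pts.append((x_new, s_new))
            tangent = t_new
            h = min(h * 1.4, ctl.h_max)
            if not (s_lo - 1e-9 <= s_new <= s_hi + 1e-9):
                break
            if x_new[7] < -1.0 or np.abs(x_new).max() > 1e12:
                msg = "left admissible region"
                break
        half_branches.append((direction, pts[1:], folds, msg))

    branch = Branch(vary=vary)
    # assemble: backward half reversed, then the seed, then forward half
    bwd = next(hb for hb in half_branches if hb[0] < 0)
    fwd = next(hb for hb in half_branches if hb[0] > 0)
    seq: list[tuple[np.ndarray, float]] = list(reversed(bwd[1])) + [(x0, s0)] + fwd[1]
    for x, s in seq:
        p = params.replace(**{vary: 10.0 ** s})
        F = rhs(0.0, x, p, InfluxMode.constant(p))
        branch.points.append(classify_point(x, s, float(np.max(np.abs(F)))))
    branch.folds = sorted(set(round(f, 14) for f in bwd[2] + fwd[2]))
    branch.message = "; ".join(m for m in (bwd[3], fwd[3]) if m)

    # oscillatory segments: maximal runs of unstable points with complex
    # leading eigenvalue pair
    segs: list[tuple[float, float]] = []
    run: list[float] = []
    for pt in branch.points:
        eig = pt.eq.eigenvalues
        lead = eig[np.argmax(eig.real)]
        osc = pt.eq.stability == "unstable" and abs(lead.imag) > 1e-10
        if osc:
            run.append(pt.param)
        elif run:
            segs.append((min(run), max(run)))
            run = []
    if run:
        segs.append((min(run), max(run)))
    branch.oscillatory_segments = segs
    return branch


def characterize_limit_cycle(
    params: ParameterSet,
    near_eq: Equilibrium,
    *,
    n_periods: float = 40.0,
    perturbation: float = 0.01,
    jitter_tol: float = 1e-3,
    seed_direction: int = 0,
) -> LimitCycleInfo:
    """Detect and characterize a limit cycle near an unstable focus.

    Integrates the constant-influx dynamics from a slightly perturbed state
    for many putative periods (estimated from the imaginary part of the
    leading eigenvalue pair), discards the transient half, and detects
    periodicity from the regularity of successive EA peaks.  Returns the
    period and the median/extremes of EA over one period, or a
    ``cycle_found=False`` outcome when the trajectory converges to an
    equilibrium instead.
    """
    eig = near_eq.eigenvalues
    lead = eig[np.argmax(eig.real)]
    if near_eq.stability == "stable":
        return LimitCycleInfo(0.0, near_eq.EA, 0.0, cycle_found=False,
                              message="stable equilibrium: no cycle")
    if abs(lead.imag) < 1e-12:
        t_est = 200.0
    else:
        t_est = 2.0 * np.pi / abs(lead.imag)
    t_end = max(n_periods * t_est, 500.0)

    x0 = near_eq.state.to_array().copy()
    bump = 1.0 + perturbation * (1 if seed_direction % 2 == 0 else -1)
    x0 = np.maximum(x0 * bump + 1e-6, 0.0)
    mode = InfluxMode.constant(params)
    sol = solve_ivp(
        lambda t, x: rhs(t, x, params, mode),
        (0.0, t_end), x0, method="LSODA", rtol=1e-9, atol=1e-10,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"limit-cycle integration failed: {sol.message}")
    t_grid = np.linspace(t_end / 2.0, t_end, 40000)
    EA = sol.sol(t_grid)[7]

    spread = EA.max() - EA.min()
    if spread <= 1e-8 * max(EA.max(), 1.0):
        return LimitCycleInfo(0.0, float(np.median(EA)), 0.0, cycle_found=False,
                              message="converged to equilibrium: no cycle")
    peaks, _ = find_peaks(EA, prominence=0.05 * spread)
    if len(peaks) < 4:
        return LimitCycleInfo(0.0, float(np.median(EA)), float(spread),
                              cycle_found=False,
                              message="too few oscillations detected within budget")
    periods = np.diff(t_grid[peaks])
    period = float(np.median(periods))
    jitter = float(np.std(periods[-5:]) / period) if len(periods) >= 5 else \
        float(np.std(periods) / period)
    if jitter > jitter_tol:
        raise RuntimeError(
            f"no regular periodicity detected (relative jitter {jitter:.2e})"
        )
    # one full period ending at the last detected peak
    t1 = t_grid[peaks[-1]]
    tt = np.linspace(t1 - period, t1, 4001)
    EA_cycle = sol.sol(tt)[7]
    return LimitCycleInfo(
        period=period,
        median_EA=float(np.median(EA_cycle)),
        amplitude_EA=float(EA_cycle.max() - EA_cycle.min()),
        min_EA=float(EA_cycle.min()),
        max_EA=float(EA_cycle.max()),
    )


@dataclass
class RegionCell:
    label: str                  # disease-free | bistable | high-disease
    attractor_EAs: list[float]
    limit_cycle: bool = False
    reclassified: bool = False
    error: str = ""


def classify_region(
    params: ParameterSet,
    *,
    threshold: float = DEFAULT_EPSILON,
    threshold_scale: float = 1.0,
    n_starts: int = 30,
    seed: int = 0,
) -> RegionCell:
    """Label a parameter point by its inventory of stable attractors.

    ``bistable`` when stable attractors (equilibria, or limit cycles judged
    by their median EA) exist on both sides of ``threshold*threshold_scale``;
    otherwise ``disease-free`` / ``high-disease`` by the attractors' side.
    """
    thr = threshold * threshold_scale
    eqs = find_equilibria(params, n_starts=n_starts, seed=seed)
    if not eqs:
        raise RuntimeError("no equilibrium found")
    attractors: list[float] = []
    limit_cycle = False
    reclassified = False
    for e in eqs:
        if e.stability == "stable":
            attractors.append(e.EA)
    # unstable foci may orbit a stable limit cycle that is itself an attractor
    for e in eqs:
        if e.stability != "unstable":
            continue
        lead = e.eigenvalues[np.argmax(e.eigenvalues.real)]
        if abs(lead.imag) < 1e-10:
            continue
        near_stable = any(
            abs(a - e.EA) <= 0.5 * max(abs(e.EA), 1.0) for a in attractors
        )
        if near_stable:
            continue
        try:
            lc = characterize_limit_cycle(params, e)
        except RuntimeError:
            continue
        if lc.cycle_found:
            limit_cycle = True
            reclassified = True
            attractors.append(lc.median_EA)
    if not attractors:
        raise RuntimeError("no stable attractor found")
    low = any(a <= thr for a in attractors)
    high = any(a > thr for a in attractors)
    if low and high:
        label = "bistable"
    elif high:
        label = "high-disease"
    else:
        label = "disease-free"
    return RegionCell(label=label, attractor_EAs=sorted(attractors),
                      limit_cycle=limit_cycle, reclassified=reclassified)


@dataclass
class RegionMap:
    beta1_grid: np.ndarray
    omega_grid: np.ndarray
    rho0_levels: np.ndarray
    #: labels[r][i][j] for rho0 level r, beta1 i, omega j; "" marks failures
    labels: list[list[list[str]]]
    limit_cycle_flags: list[list[list[bool]]]
    reclassified_flags: list[list[list[bool]]]
    errors: list[list[list[str]]]

    def to_json(self, path=None) -> str:
        payload = {
            "beta1_grid": np.asarray(self.beta1_grid).tolist(),
            "omega_grid": np.asarray(self.omega_grid).tolist(),
            "rho0_levels": np.asarray(self.rho0_levels).tolist(),
            "labels": self.labels,
            "limit_cycle_flags": self.limit_cycle_flags,
            "reclassified_flags": self.reclassified_flags,
            "errors": self.errors,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "RegionMap":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            beta1_grid=np.array(payload["beta1_grid"]),
            omega_grid=np.array(payload["omega_grid"]),
            rho0_levels=np.array(payload["rho0_levels"]),
            labels=payload["labels"],
            limit_cycle_flags=payload["limit_cycle_flags"],
            reclassified_flags=payload["reclassified_flags"],
            errors=payload["errors"],
        )

    def labels_array(self, level: int = 0) -> np.ndarray:
        return np.array(self.labels[level], dtype=object)


def codim2_region_map(
    params: ParameterSet,
    beta1_grid,
    omega_grid,
    rho0_levels=(0.005, 0.05, 0.1),
    *,
    n_starts: int = 25,
    seed: int = 0,
) -> RegionMap:
    """Region labels over a (beta_1, omega) grid at one or more retrograde
    influx levels.  Per-cell failures are recorded, not raised."""
    beta1_grid = np.atleast_1d(np.asarray(beta1_grid, dtype=float))
    omega_grid = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    rho0_levels = np.atleast_1d(np.asarray(rho0_levels, dtype=float))
    labels, lc_flags, rc_flags, errors = [], [], [], []
    for r in rho0_levels:
        L, C, R, E = [], [], [], []
        for b1 in beta1_grid:
            Lr, Cr, Rr, Er = [], [], [], []
            for w in omega_grid:
                p = params.replace(beta_1=float(b1), omega=float(w),
                                   rho_0=float(r))
                try:
                    cell = classify_region(p, n_starts=n_starts, seed=seed)
                    Lr.append(cell.label)
                    Cr.append(cell.limit_cycle)
                    Rr.append(cell.reclassified)
                    Er.append("")
                except RuntimeError as exc:
                    Lr.append("")
                    Cr.append(False)
                    Rr.append(False)
                    Er.append(str(exc))
            L.append(Lr); C.append(Cr); R.append(Rr); E.append(Er)
        labels.append(L); lc_flags.append(C); rc_flags.append(R); errors.append(E)
    return RegionMap(beta1_grid, omega_grid, rho0_levels,
                     labels, lc_flags, rc_flags, errors)


@dataclass
class SweepTrace:
    direction: str                   # forward | backward
    param_values: np.ndarray
    end_states: np.ndarray           # (n, 8)
    converged: np.ndarray            # bool per step

    @property
    def EA(self) -> np.ndarray:
        return self.end_states[:, 7]


def hysteresis_sweep(
    params: ParameterSet,
    vary: str,
    p_range: tuple[float, float],
    n_steps: int = 25,
    *,
    t_settle: float = 3000.0,
) -> tuple[SweepTrace, SweepTrace]:
    """Quasi-static forward/backward sweeps of *vary* over *p_range*.

    At each parameter step the constant-mode dynamics are integrated to the
    attractor using the previous attractor as initial condition.  The
    forward trace decreases the parameter (declining immune function); the
    backward trace retraces it upward.  In a bistable window the traces
    disagree (hysteresis loop).
    """
    if vary not in VARYABLE:
        raise ValueError(f"vary must be one of {VARYABLE}, got {vary!r}")
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    lo, hi = sorted(float(v) for v in p_range)
    values_down = np.geomspace(hi, lo, n_steps)

    def settle(p: ParameterSet, x0: np.ndarray) -> tuple[np.ndarray, bool]:
        mode = InfluxMode.constant(p)
        sol = solve_ivp(
            lambda t, x: rhs(t, x, p, mode),
            (0.0, t_settle), np.maximum(x0, 0.0),
            method="LSODA", rtol=1e-9, atol=1e-10,
        )
        if not sol.success:
            return x0, False
        x_end = sol.y[:, -1]
        res = root(lambda y: rhs(0.0, y, p, mode), np.maximum(x_end, 0.0),
                   method="hybr", tol=1e-13)
        if res.success and res.x.min() > -1e-6:
            return np.maximum(res.x, 0.0), True
        return np.maximum(x_end, 0.0), True

    def run(values: np.ndarray, x_start: np.ndarray, direction: str) -> SweepTrace:
        states = np.empty((values.size, 8))
        ok = np.empty(values.size, dtype=bool)
        x = x_start.copy()
        for i, v in enumerate(values):
            p = params.replace(**{vary: float(v)})
            x, ok[i] = settle(p, x)
            states[i] = x
        return SweepTrace(direction, values.copy(), states, ok)

    # start the forward (downward) sweep from the attractor at the top end
    p_top = params.replace(**{vary: float(hi)})
    from .simulate import surrogate_steady_state

    ss = surrogate_steady_state(p_top)
    fwd = run(values_down, ss.state.to_array(), "forward")
    bwd = run(values_down[::-1], fwd.end_states[-1].copy(), "backward")
    return fwd, bwd
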