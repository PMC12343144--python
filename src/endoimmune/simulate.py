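"""Stiff-capable integration of the model and the two-stage initialization.

The standard experiment protocol is:

1. solve the constant-influx surrogate model to steady state (long-time
   integration followed by Newton polishing) — this plays the role of the
   pre-study resting state of the peritoneal environment;
2. use that steady state as the initial condition for the full cyclic-influx
   system and integrate over the requested number of menstrual cycles.

:func:`run_study` composes the two stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_core import (
    STATE_VARS,
    InfluxMode,
    ParameterSet,
    SystemState,
    rhs,
)

__all__ = [
    "SolverSettings",
    "Trajectory",
    "SteadyStateResult",
    "surrogate_steady_state",
    "integrate",
    "run_study",
]

#: Largest negative excursion (cells·ml⁻¹) tolerated before aborting.
NEGATIVE_TOL = -1e-6


@dataclass(frozen=True)
class SolverSettings:
    """Integration settings: a stiff-capable variable-step method sampled on
    a uniform output grid (`dense_output_dt`, days)."""

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = np.inf
    dense_output_dt: float = 0.1
    stiff: bool = True

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.dense_output_dt <= 0:
            raise ValueError("dense_output_dt must be > 0")

    @property
    def method(self) -> str:
        return "LSODA" if self.stiff else "RK45"


@dataclass
class Trajectory:
    """Uniformly sampled solution: times (days, starting at 0) and an
    ``(n_times, 8)`` state array in :data:`~endoimmune.model_core.STATE_VARS`
    order."""

    times: np.ndarray
    states: np.ndarray
    mode: InfluxMode
    params_hash: str
    cycle_length: float
    init_residual: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, len(STATE_VARS)):
            raise ValueError("states must be (n_times, 8)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("non-finite states in trajectory")
        if self.states.min() < NEGATIVE_TOL:
            i, j = np.unravel_index(np.argmin(self.states), self.states.shape)
            raise ValueError(
                f"negative excursion in {STATE_VARS[j]} at t={self.times[i]:.3f}: "
                f"{self.states[i, j]:.3e} cells/ml"
            )

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_VARS.index(name)]

    def at(self, t) -> np.ndarray:
        """State interpolated at time(s) *t* (linear in the dense grid)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t.size, len(STATE_VARS)))
        for j in range(len(STATE_VARS)):
            out[:, j] = np.interp(t, self.times, self.states[:, j])
        return out[0] if out.shape[0] == 1 else out

    def final_state(self) -> SystemState:
        return SystemState.from_array(
            np.maximum(self.states[-1], 0.0), validate=True
        )

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SteadyStateResult:
    state: SystemState
    residual_norm: float
    limit_cycle: bool = False
    message: str = ""


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def _rhs_constant(params: ParameterSet, mode: InfluxMode):
    def f(x):
        return rhs(0.0, x, params, mode)

    return f


def surrogate_steady_state(
    params: ParameterSet,
    guess: SystemState | None = None,
    settings: SolverSettings | None = None,
    *,
    t_settle: float = 4000.0,
    tol: float = 1e-8,
) -> SteadyStateResult:
    """Steady state of the constant-influx surrogate model.

    Long-time integration from *guess* (default: 1 cell·ml⁻¹ in every
    immune compartment, endometrial compartments empty) followed by Newton
    polishing of the algebraic system.  If the long-time dynamics settle
    onto a limit cycle instead, the cycle-mean state is returned with
    ``limit_cycle=True``.
    """
    settings = settings or SolverSettings()
    mode = InfluxMode.constant(params)
    if guess is None:
        x0 = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    else:
        x0 = guess.to_array()
        if np.any(x0 < 0):
            raise ValueError("steady-state guess must be non-negative")

    t_settle = max(t_settle, 2000.0)
    sol = solve_ivp(
        lambda t, x: rhs(t, x, params, mode),
        (0.0, t_settle),
        x0,
        method=settings.method,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        dense_output=True,
    )
    if not sol.success:
        raise ConvergenceError(f"surrogate integration failed: {sol.message}")
    x_end = sol.y[:, -1]

    from .equilibria import jacobian  # deferred: avoids circular import

    f = _rhs_constant(params, mode)
    res = root(f, np.maximum(x_end, 0.0), method="hybr",
               jac=lambda y: jacobian(np.maximum(y, 0.0), params), tol=1e-13)
    x_star = res.x
    rnorm = float(np.max(np.abs(f(x_star))))
    if rnorm <= tol and x_star.min() >= NEGATIVE_TOL:
        return SteadyStateResult(
            SystemState.from_array(np.maximum(x_star, 0.0)), rnorm
        )

    # polishing failed or converged to an inadmissible root: check for a
    # limit cycle by comparing the last two windows of the settle run
    t_tail = np.linspace(t_settle - 400.0, t_settle, 2001)
    tail = sol.sol(t_tail)
    spread = tail.max(axis=1) - tail.min(axis=1)
    scale = np.maximum(np.abs(tail).max(axis=1), 1.0)
    if np.any(spread / scale > 1e-4):
        mean_state = np.maximum(tail.mean(axis=1), 0.0)
        rnorm_mean = float(np.max(np.abs(f(mean_state))))
        return SteadyStateResult(
            SystemState.from_array(mean_state),
            rnorm_mean,
            limit_cycle=True,
            message="oscillatory non-convergence: returning cycle-mean state",
        )
    raise ConvergenceError(
        f"surrogate steady state did not converge (residual {rnorm:.3e})",
        residual=rnorm,
    )


def integrate(
    params: ParameterSet,
    ic: SystemState,
    n_cycles: int,
    settings: SolverSettings | None = None,
    mode: InfluxMode | None = None,
) -> Trajectory:
    """Integrate the model over ``n_cycles`` menstrual cycles from *ic*.

    Returns a :class:`Trajectory` uniformly sampled at
    ``settings.dense_output_dt``; raises on solver failure or on negative
    excursions beyond tolerance.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    settings = settings or SolverSettings()
    mode = mode or InfluxMode.cyclic()
    x0 = ic.to_array()
    if np.any(x0 < 0):
        raise ValueError("initial condition must be non-negative")

    t_end = n_cycles * params.cycle_length
    n_out = int(round(t_end / settings.dense_output_dt))
    t_eval = np.linspace(0.0, t_end, n_out + 1)
    sol = solve_ivp(
        lambda t, x: rhs(t, x, params, mode),
        (0.0, t_end),
        x0,
        method=settings.method,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        max_step=settings.max_step,
        t_eval=t_eval,
    )
    if not sol.success:
        raise ConvergenceError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0:.3f}: {sol.message}"
        )
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        mode=mode,
        params_hash=params.params_hash(),
        cycle_length=params.cycle_length,
    )


def run_study(
    params: ParameterSet,
    n_cycles: int = 10,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Two-stage protocol: surrogate steady state, then cyclic integration.

    The returned trajectory is tagged with the initialization residual of
    the surrogate solve.
    """
    settings = settings or SolverSettings()
    ss = surrogate_steady_state(params, settings=settings)
    traj = integrate(params, ss.state, n_cycles, settings, InfluxMode.cyclic())
    traj.init_residual = ss.residual_norm
    return traj
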