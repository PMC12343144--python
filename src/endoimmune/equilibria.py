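"""Equilibria of the constant-influx surrogate model: root finding,
Jacobian eigenvalue stability analysis, the disease-free stability
inequality, and the (detection, clearance) partition boundary.

The disease-free steady state is stable only when M2-upregulated
proliferation of attached cells is outweighed by immune clearance plus
natural turnover::

    eta_E * M2* / (C_M2 + M2*)  <  omega * [gamma*KA* + (1-gamma)*M1*] + delta_EA

evaluated at the disease-free equilibrium.  The *margin* (right minus left
side, day⁻¹) is positive in the low-attachment regime; its zero contour in
the (beta_1, omega) plane is the analytic partition between predicted low
and high attachment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .model_core import InfluxMode, ParameterSet, SystemState, rhs
from .simulate import NEGATIVE_TOL

__all__ = [
    "Equilibrium",
    "StabilityMargin",
    "EPS_EQ",
    "jacobian",
    "find_equilibria",
    "stability_margin",
    "partition_boundary",
    "disease_free_equilibrium",
]

#: EA tolerance below which an equilibrium is labelled disease-free.
EPS_EQ = 1e-3          # cells/ml
#: residual tolerance for accepted equilibria
RESIDUAL_TOL = 1e-8
#: |max Re eigenvalue| below this is labelled marginal
MARGINAL_TOL = 1e-6


@dataclass
class Equilibrium:
    state: SystemState
    residual_norm: float
    eigenvalues: np.ndarray
    stability: str       # stable | unstable | marginal
    kind: str            # disease-free | diseased | other

    @property
    def max_re(self) -> float:
        return float(np.max(self.eigenvalues.real))

    @property
    def EA(self) -> float:
        return self.state.EA

    def to_dict(self) -> dict:
        return {
            "state": self.state.to_dict(),
            "residual_norm": self.residual_norm,
            "eigenvalues_re": self.eigenvalues.real.tolist(),
            "eigenvalues_im": self.eigenvalues.imag.tolist(),
            "stability": self.stability,
            "kind": self.kind,
        }


@dataclass
class StabilityMargin:
    """Terms of the disease-free inequality at an equilibrium (day⁻¹)."""

    lhs: float      # eta_E * M2/(C_M2+M2): proliferation upregulation
    rhs: float      # omega*[gamma KA + (1-gamma) M1] + delta_EA: removal
    margin: float   # rhs - lhs; > 0 predicts low attachment

    @property
    def satisfied(self) -> bool:
        return self.margin > 0


def jacobian(state, params: ParameterSet) -> np.ndarray:
    """Analytic 8×8 Jacobian of the constant-mode right-hand side (day⁻¹)."""
    if isinstance(state, SystemState):
        x = state.to_array()
    else:
        x = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state")
    M0, M1, M2, K0, KA, E0, EF, EA = x
    p = params

    Mtot = M0 + M1 + M2
    E = EF + EA
    h_KA = KA / (p.C_KA + KA)
    dh_KA = p.C_KA / (p.C_KA + KA) ** 2
    h_M1 = M1 / (p.C_M1 + M1)
    dh_M1 = p.C_M1 / (p.C_M1 + M1) ** 2
    h_M2 = M2 / (p.C_M2 + M2)
    dh_M2 = p.C_M2 / (p.C_M2 + M2) ** 2
    immune = p.gamma * KA + (1.0 - p.gamma) * M1
    g = p.eta_M * (1.0 - 2.0 * Mtot / p.M_C)   # d/dX of logistic production

    J = np.zeros((8, 8))
    # M0 row
    J[0, 0] = g - p.theta_M * h_KA - p.beta_1 * E - p.beta_2 - p.delta_M0
    J[0, 1] = g
    J[0, 2] = g
    J[0, 4] = -p.theta_M * dh_KA * M0
    J[0, 6] = -p.beta_1 * M0
    J[0, 7] = -p.beta_1 * M0
    # M1 row
    J[1, 0] = p.beta_1 * E + p.theta_M * h_KA
    J[1, 1] = -p.beta_12 - p.delta_M1
    J[1, 2] = p.beta_21
    J[1, 4] = p.theta_M * dh_KA * M0
    J[1, 6] = p.beta_1 * M0
    J[1, 7] = p.beta_1 * M0
    # M2 row
    J[2, 0] = p.beta_2
    J[2, 1] = p.beta_12
    J[2, 2] = -p.beta_21 - p.delta_M2
    # K0 row
    J[3, 1] = -p.theta_K * K0 * dh_M1
    J[3, 3] = -p.theta_K * h_M1 - p.delta_K0
    # KA row
    J[4, 1] = p.theta_K * K0 * dh_M1
    J[4, 3] = p.theta_K * h_M1 - p.eta_K * KA / p.K_C
    J[4, 4] = (
        p.eta_K * (1.0 - (K0 + 2.0 * KA) / p.K_C)
        - p.sigma * E
        - p.delta_KA
    )
    J[4, 6] = -p.sigma * KA
    J[4, 7] = -p.sigma * KA
    # E0 row (linear: source is state-independent)
    J[5, 5] = -p.delta_E0
    # EF row
    J[6, 1] = -p.omega * (1.0 - p.gamma) * EF
    J[6, 4] = -p.omega * p.gamma * EF
    J[6, 5] = p.delta_E0 * p.rho_0
    J[6, 6] = -p.omega * immune - p.rho_F - p.delta_EF
    # EA row
    J[7, 1] = -p.omega * (1.0 - p.gamma) * EA
    J[7, 2] = p.eta_E * EA * (1.0 - EA / p.E_C) * dh_M2
    J[7, 4] = -p.omega * p.gamma * EA
    J[7, 6] = p.rho_F
    J[7, 7] = (
        p.eta_E * (1.0 - 2.0 * EA / p.E_C) * h_M2
        - p.omega * immune
        - p.delta_EA
    )
    return J


def _classify(x: np.ndarray, params: ParameterSet, rnorm: float,
              eps_eq: float = EPS_EQ) -> Equilibrium:
    J = jacobian(x, params)
    eig = np.linalg.eigvals(J)
    max_re = float(np.max(eig.real))
    if abs(max_re) <= MARGINAL_TOL:
        stability = "marginal"
    elif max_re < 0:
        stability = "stable"
    else:
        stability = "unstable"
    kind = "disease-free" if x[7] <= eps_eq else "diseased"
    return Equilibrium(
        state=SystemState.from_array(np.maximum(x, 0.0)),
        residual_norm=rnorm,
        eigenvalues=np.sort_complex(eig),
        stability=stability,
        kind=kind,
    )


def find_equilibria(
    params: ParameterSet,
    n_starts: int = 40,
    seed: int = 0,
    *,
    eps_eq: float = EPS_EQ,
) -> list[Equilibrium]:
    """Multi-start root finding on the surrogate right-hand side.

    Starts are drawn log-uniformly per compartment (seeded, reproducible);
    converged roots are deduplicated at relative distance 1e-6, restricted
    to the non-negative orthant, polished to residual <= 1e-8 and classified
    by the eigenvalues of the analytic Jacobian.  Two deterministic starts
    (near-empty and near-capacity) are always included.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    mode = InfluxMode.constant(params)

    def f(x):
        return rhs(0.0, x, params, mode)

    def fprime(x):
        return jacobian(np.maximum(x, 0.0), params)

    rng = np.random.default_rng(seed)
    scales = np.array([
        params.M_C, params.M_C, params.M_C,
        params.K_C, params.K_C,
        max(mode.mu_bar_E / max(params.delta_E0, 1e-12), 1.0),
        params.E_C, params.E_C,
    ])
    lo = np.log10(np.maximum(scales * 1e-4, 1e-6))
    hi = np.log10(scales * 2.0)
    starts = [10.0 ** (lo + (hi - lo) * rng.random(8)) for _ in range(n_starts)]
    starts.append(np.full(8, 1.0))
    starts.append(scales * 0.5)

    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = root(f, x0, jac=fprime, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        x = sol.x
        if x.min() < NEGATIVE_TOL:
            continue
        x = np.maximum(x, 0.0)
        rnorm = float(np.max(np.abs(f(x))))
        if rnorm > RESIDUAL_TOL:
            continue
        if any(np.max(np.abs(x - r) / np.maximum(np.maximum(np.abs(r), np.abs(x)), 1.0)) < 1e-6
               for r in roots):
            continue
        roots.append(x)

    eqs = [_classify(x, params, float(np.max(np.abs(f(x)))), eps_eq) for x in roots]
    eqs.sort(key=lambda e: e.EA)
    return eqs


def stability_margin(params: ParameterSet, eq: Equilibrium) -> StabilityMargin:
    """Evaluate the disease-free inequality at an equilibrium."""
    s = eq.state
    lhs = params.eta_E * s.M2 / (params.C_M2 + s.M2)
    rhs_ = (
        params.omega * (params.gamma * s.KA + (1.0 - params.gamma) * s.M1)
        + params.delta_EA
    )
    return StabilityMargin(lhs=float(lhs), rhs=float(rhs_), margin=float(rhs_ - lhs))


def disease_free_equilibrium(
    params: ParameterSet, n_starts: int = 30, seed: int = 0
) -> Equilibrium | None:
    """The stable equilibrium with smallest EA (fallback: smallest EA of
    any kind), or None if no equilibrium is found."""
    eqs = find_equilibria(params, n_starts=n_starts, seed=seed)
    if not eqs:
        return None
    stable = [e for e in eqs if e.stability == "stable"]
    pool = stable or eqs
    return min(pool, key=lambda e: e.EA)


def partition_boundary(
    params: ParameterSet,
    beta1_grid,
    omega_grid,
    *,
    n_starts: int = 20,
    seed: int = 0,
):
    """Zero-level contour of the stability margin over a (beta_1, omega) grid.

    At each grid point the margin of the disease-free (smallest-EA stable)
    surrogate equilibrium is computed; boundary points are obtained by
    linear interpolation along grid edges where the margin changes sign.
    Returns ``(points, margins)`` where *points* is an (n, 2) array of
    (beta_1, omega) boundary coordinates and *margins* the (nb, nw) margin
    grid.
    """
    beta1_grid = np.asarray(beta1_grid, dtype=float)
    omega_grid = np.asarray(omega_grid, dtype=float)
    for g, name in ((beta1_grid, "beta1_grid"), (omega_grid, "omega_grid")):
        if g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} must be strictly increasing with >= 2 points")

    margins = np.empty((beta1_grid.size, omega_grid.size))
    for i, b1 in enumerate(beta1_grid):
        for j, w in enumerate(omega_grid):
            p = params.replace(beta_1=float(b1), omega=float(w))
            eq = disease_free_equilibrium(p, n_starts=n_starts, seed=seed)
            margins[i, j] = np.nan if eq is None else stability_margin(p, eq).margin

    points: list[tuple[float, float]] = []
    # sign changes along omega (fixed beta_1)
    for i, b1 in enumerate(beta1_grid):
        row = margins[i]
        for j in range(omega_grid.size - 1):
            a, b = row[j], row[j + 1]
            if np.isfinite(a) and np.isfinite(b) and a * b < 0:
                t = a / (a - b)
                points.append((float(b1), float(omega_grid[j] + t * (omega_grid[j + 1] - omega_grid[j]))))
    # sign changes along beta_1 (fixed omega)
    for j, w in enumerate(omega_grid):
        col = margins[:, j]
        for i in range(beta1_grid.size - 1):
            a, b = col[i], col[i + 1]
            if np.isfinite(a) and np.isfinite(b) and a * b < 0:
                t = a / (a - b)
                points.append((float(beta1_grid[i] + t * (beta1_grid[i + 1] - beta1_grid[i])), float(w)))

    return np.array(points).reshape(-1, 2), margins
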