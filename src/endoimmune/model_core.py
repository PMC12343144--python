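"""Core model definitions: parameters, state, menstrual influx forcing and ODE right-hand side.

The model tracks eight interacting cell populations in peritoneal fluid
(concentrations in cells·ml⁻¹, time in days):

* macrophages — resting ``M0``, pro-inflammatory ``M1``, pro-repair ``M2``;
* natural killer (NK) cells — resting ``K0``, activated ``KA``;
* endometrial cells — eutopic ``E0`` (inside the uterus), in peritoneal
  fluid ``EF``, attached to the peritoneum ``EA`` (early lesion cells).

Eutopic cells are shed cyclically with the menstrual cycle; a fraction
``rho_0`` exits retrograde into the peritoneal fluid, where fluid cells may
attach and attached cells may proliferate (upregulated by M2) or be cleared
by activated immune cells (KA and M1, split by ``gamma``).

Two influx modes are supported: the full cyclic forcing and a constant
"surrogate" influx equal to the cycle average, used for equilibrium,
stability and bifurcation analysis.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import quad

__all__ = [
    "STATE_VARS",
    "ParameterSet",
    "SystemState",
    "InfluxMode",
    "ValidationReport",
    "eval_influx_cyclic",
    "eval_influx_mean",
    "rhs",
    "macrophage_fractions",
    "validate_parameters",
]

#: Fixed compartment ordering used by every array-valued interface.
STATE_VARS = ("M0", "M1", "M2", "K0", "KA", "E0", "EF", "EA")

# Parameter names accepted in serialized mappings, in canonical order.
PARAM_NAMES = (
    "mu_M", "eta_M", "M_C", "theta_M", "C_KA",
    "beta_1", "beta_2", "beta_12", "beta_21",
    "delta_M0", "delta_M1", "delta_M2",
    "mu_K", "theta_K", "C_M1", "eta_K", "K_C", "sigma",
    "delta_K0", "delta_KA",
    "a_E", "b_E", "d_E", "delta_E0", "rho_0", "rho_F",
    "delta_EF", "delta_EA", "omega", "gamma",
    "eta_E", "E_C", "C_M2", "cycle_length",
)


@dataclass(frozen=True)
class ParameterSet:
    """All model constants (rates, capacities, proportions) plus cycle shape.

    Units: rates are day⁻¹ unless stated otherwise; bimolecular rates
    (``beta_1``, ``sigma``, ``omega``) are cells⁻¹·ml·day⁻¹; supplies
    (``mu_M``, ``mu_K``, ``a_E``) are cells·ml⁻¹·day⁻¹; capacities and
    half-saturation constants are cells·ml⁻¹.
    """

    mu_M: float        # circulating M0 supply
    eta_M: float       # macrophage production rate
    M_C: float         # macrophage carrying capacity
    theta_M: float     # KA-upregulated M1 activation rate
    C_KA: float        # half-saturation of KA upregulation
    beta_1: float      # M1 activation via EF/EA detection
    beta_2: float      # constant M2 activation rate
    beta_12: float     # M1 -> M2 repolarization
    beta_21: float     # M2 -> M1 repolarization
    delta_M0: float
    delta_M1: float
    delta_M2: float
    mu_K: float        # circulating K0 supply
    theta_K: float     # M1-upregulated NK activation rate
    C_M1: float        # half-saturation of M1 upregulation
    eta_K: float       # KA proliferation rate
    K_C: float         # NK carrying capacity
    sigma: float       # KA exhaustion rate per endometrial encounter
    delta_K0: float
    delta_KA: float
    a_E: float         # influx amplitude
    b_E: float         # influx shape exponent (sharpness of the menstrual peak)
    d_E: float         # influx phase shift, days
    delta_E0: float    # eutopic clearance rate (retrograde + cervical)
    rho_0: float       # retrograde fraction, in [0, 1]
    rho_F: float       # fluid-cell attachment rate
    delta_EF: float
    delta_EA: float
    omega: float       # immune clearance rate of EF/EA
    gamma: float       # KA share of immune clearance, in [0, 1]
    eta_E: float       # attached-cell proliferation rate
    E_C: float         # lesion carrying capacity
    C_M2: float        # half-saturation of M2 upregulation of proliferation
    cycle_length: float = 28.0

    def __post_init__(self) -> None:
        report = validate_parameters(self)
        if report.violations:
            raise ValueError(
                "invalid ParameterSet: " + "; ".join(report.violations)
            )

    # -- derived clearance split (omega_K + omega_M == omega) ---------------
    @property
    def omega_K(self) -> float:
        """NK-cell share of the immune clearance rate, ``gamma * omega``."""
        return self.gamma * self.omega

    @property
    def omega_M(self) -> float:
        """M1 share of the immune clearance rate, ``(1 - gamma) * omega``."""
        return (1.0 - self.gamma) * self.omega

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        unknown = sorted(set(mapping) - set(PARAM_NAMES))
        if unknown:
            raise KeyError(f"unknown parameter keys: {unknown}")
        missing = sorted(set(PARAM_NAMES) - set(mapping) - {"cycle_length"})
        if missing:
            raise KeyError(f"missing parameter keys: {missing}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def params_hash(self) -> str:
        """Short stable identifier of the parameter values."""
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


class SystemState:
    """The eight compartment concentrations in cells·ml⁻¹, fixed ordering.

    Thin wrapper over a length-8 float array; named access via attributes.
    Construction validates finiteness and (by default) non-negativity;
    solver internals may bypass the sign check with ``validate=False``.
    """

    __slots__ = ("_x",)

    def __init__(self, M0=0.0, M1=0.0, M2=0.0, K0=0.0, KA=0.0,
                 E0=0.0, EF=0.0, EA=0.0, *, validate: bool = True):
        x = np.array([M0, M1, M2, K0, KA, E0, EF, EA], dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("SystemState components must be finite")
        if validate and np.any(x < 0):
            bad = [STATE_VARS[i] for i in np.flatnonzero(x < 0)]
            raise ValueError(f"negative compartment(s): {bad}")
        self._x = x

    @classmethod
    def from_array(cls, arr: Iterable[float], *, validate: bool = True) -> "SystemState":
        a = np.asarray(arr, dtype=float)
        if a.shape != (len(STATE_VARS),):
            raise ValueError(f"expected length-{len(STATE_VARS)} array, got {a.shape}")
        return cls(*a, validate=validate)

    def to_array(self) -> np.ndarray:
        return self._x.copy()

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(STATE_VARS, self._x)}

    def __getattr__(self, name: str):
        try:
            return float(self._x[STATE_VARS.index(name)])
        except ValueError:
            raise AttributeError(name) from None

    def __iter__(self):
        return iter(self._x)

    def __repr__(self) -> str:
        body = ", ".join(f"{k}={v:.6g}" for k, v in zip(STATE_VARS, self._x))
        return f"SystemState({body})"


@dataclass(frozen=True)
class InfluxMode:
    """Influx mode for the E0 source: ``cyclic`` forcing or a ``constant``
    surrogate with rate ``mu_bar_E`` (the cycle average of the forcing)."""

    tag: str = "cyclic"
    mu_bar_E: float = 0.0

    def __post_init__(self) -> None:
        if self.tag not in ("cyclic", "constant"):
            raise ValueError(f"invalid influx mode tag: {self.tag!r}")
        if self.tag == "constant" and not (self.mu_bar_E >= 0):
            raise ValueError("mu_bar_E must be non-negative")

    @classmethod
    def cyclic(cls) -> "InfluxMode":
        return cls(tag="cyclic")

    @classmethod
    def constant(cls, params: "ParameterSet") -> "InfluxMode":
        """Constant surrogate mode with the cycle-average influx of *params*."""
        return cls(tag="constant", mu_bar_E=eval_influx_mean(params))


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_parameters(params: "ParameterSet") -> ValidationReport:
    """Report invariant violations and biological warnings; never mutates."""
    rep = ValidationReport()
    g = lambda k: getattr(params, k)

    nonneg = ("mu_M", "eta_M", "theta_M", "beta_1", "beta_2", "beta_12",
              "beta_21", "delta_M0", "delta_M1", "delta_M2", "mu_K",
              "theta_K", "eta_K", "sigma", "delta_K0", "delta_KA", "a_E",
              "d_E", "delta_E0", "rho_F", "delta_EF", "delta_EA", "omega",
              "eta_E")
    for k in nonneg:
        if not (g(k) >= 0):
            rep.violations.append(f"{k} must be >= 0 (got {g(k)})")
    for k in ("M_C", "K_C", "E_C", "C_KA", "C_M1", "C_M2"):
        if not (g(k) > 0):
            rep.violations.append(f"{k} must be > 0 (got {g(k)})")
    for k in ("rho_0", "gamma"):
        if not (0.0 <= g(k) <= 1.0):
            rep.violations.append(f"{k} outside [0,1] (got {g(k)})")
    if not (g("cycle_length") > 0):
        rep.violations.append(f"cycle_length must be > 0 (got {g('cycle_length')})")
    if not (g("b_E") > 0):
        rep.violations.append(f"b_E must be > 0 (got {g('b_E')})")

    if rep.ok:
        if params.rho_0 == 0:
            rep.warnings.append("rho_0 = 0 disables the retrograde disease pathway")
        if params.a_E == 0:
            rep.warnings.append("a_E = 0: no endometrial shedding")
        if params.omega == 0:
            rep.warnings.append("omega = 0: no immune clearance of ectopic cells")
    return rep


# ---------------------------------------------------------------------------
# Influx forcing
# ---------------------------------------------------------------------------

def eval_influx_cyclic(t, params: ParameterSet):
    """Cyclic eutopic-cell shedding rate at time *t* (days).

    ``a_E * |sin(pi * (t + d_E) / cycle_length)| ** b_E`` — non-negative,
    periodic with period ``cycle_length``, one menstrual peak per cycle.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    val = params.a_E * np.abs(
        np.sin(np.pi * (t + params.d_E) / params.cycle_length)
    ) ** params.b_E
    return float(val) if val.ndim == 0 else val


def eval_influx_mean(params: ParameterSet) -> float:
    """Cycle-average of the cyclic influx, by adaptive quadrature.

    By periodicity this equals ``a_E`` times the mean of ``|sin|**b_E`` over
    a half period (e.g. ``a_E / 2`` for ``b_E = 2``).
    """
    if params.a_E == 0:
        return 0.0
    L = params.cycle_length
    # integrate one half-period of |sin|^b and exploit symmetry; avoids
    # quadrature issues at the non-smooth |.| points for odd b_E
    val, _ = quad(
        lambda t: math.sin(math.pi * t / L) ** params.b_E,
        0.0, L / 2.0, epsrel=1e-12, epsabs=0.0, limit=200,
    )
    return params.a_E * 2.0 * val / L


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _influx_at(t: float, params: ParameterSet, mode: InfluxMode) -> float:
    if mode.tag == "cyclic":
        return eval_influx_cyclic(t, params)
    if mode.tag == "constant":
        return mode.mu_bar_E
    raise ValueError(f"invalid influx mode tag: {mode.tag!r}")


def rhs(t, state, params: ParameterSet, mode: InfluxMode, *, clamp: bool = True):
    """Time derivative of the eight compartments (cells·ml⁻¹·day⁻¹).

    *state* may be a :class:`SystemState` or a length-8 array in
    :data:`STATE_VARS` order.  With ``clamp=True`` (default) small negative
    excursions produced by the solver are treated as 0 inside saturating and
    mass-action terms; the linear turnover terms always use the raw values so
    that excursions decay back to the admissible region.
    """
    if isinstance(state, SystemState):
        x = state.to_array()
    else:
        x = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state passed to rhs")
    M0r, M1r, M2r, K0r, KAr, E0r, EFr, EAr = x
    if clamp:
        M0, M1, M2, K0, KA, E0, EF, EA = np.maximum(x, 0.0)
    else:
        M0, M1, M2, K0, KA, E0, EF, EA = x

    p = params
    Mtot = M0 + M1 + M2
    E = EF + EA
    hill_KA = KA / (p.C_KA + KA)
    hill_M1 = M1 / (p.C_M1 + M1)
    hill_M2 = M2 / (p.C_M2 + M2)
    immune = p.gamma * KA + (1.0 - p.gamma) * M1  # clearance-competent pool

    mu_E = _influx_at(t, p, mode)

    dM0 = (
        p.mu_M
        + p.eta_M * (1.0 - Mtot / p.M_C) * Mtot
        - p.theta_M * hill_KA * M0
        - p.beta_1 * E * M0
        - p.beta_2 * M0
        - p.delta_M0 * M0r
    )
    dM1 = (
        p.beta_1 * E * M0
        + p.theta_M * hill_KA * M0
        + p.beta_21 * M2
        - p.beta_12 * M1
        - p.delta_M1 * M1r
    )
    dM2 = (
        p.beta_2 * M0
        + p.beta_12 * M1
        - p.beta_21 * M2
        - p.delta_M2 * M2r
    )
    dK0 = (
        p.mu_K
        - p.theta_K * K0 * hill_M1
        - p.delta_K0 * K0r
    )
    dKA = (
        p.theta_K * K0 * hill_M1
        + p.eta_K * (1.0 - (KA + K0) / p.K_C) * KA
        - p.sigma * E * KA
        - p.delta_KA * KAr
    )
    # retrograde + cervical clearance split sums to delta_E0 * E0
    dE0 = mu_E - p.delta_E0 * E0r
    dEF = (
        p.delta_E0 * p.rho_0 * E0
        - p.omega * immune * EF
        - p.rho_F * EF
        - p.delta_EF * EFr
    )
    dEA = (
        p.rho_F * EF
        + p.eta_E * EA * (1.0 - EA / p.E_C) * hill_M2
        - p.omega * immune * EA
        - p.delta_EA * EAr
    )
    return np.array([dM0, dM1, dM2, dK0, dKA, dE0, dEF, dEA])


def macrophage_fractions(state) -> tuple[float, float]:
    """Proportions of total macrophages in the M1 and M2 activation states.

    Returns ``(M1/(M0+M1+M2), M2/(M0+M1+M2))``; raises on zero total.
    """
    if isinstance(state, SystemState):
        M0, M1, M2 = state.M0, state.M1, state.M2
    else:
        x = np.asarray(state, dtype=float)
        M0, M1, M2 = x[0], x[1], x[2]
    total = M0 + M1 + M2
    if total <= 0:
        raise ValueError("macrophage fractions undefined: zero total macrophages")
    return M1 / total, M2 / total
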