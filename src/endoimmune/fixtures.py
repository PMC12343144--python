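"""Named parameter sets spanning the model's qualitative regimes.

The defaults are a calibrated set: every rate printed in the primary
sources of the model is kept verbatim (``beta_1 = 1e-6`` cells⁻¹·ml·day⁻¹,
``omega = 1e-5`` cells⁻¹·ml·day⁻¹, ``rho_0`` spanning 0.005–0.1, 28-day
cycle), and the remaining constants were calibrated once so that the
package reproduces the documented qualitative regimes:

* ``reference`` — moderate retrograde influx; all ectopic cells (EF, EA)
  are cleared before each cycle end (low/no disease baseline);
* ``low_influx`` — reference with ``rho_0 = 0.005``;
* ``transient`` — reference with a 150-fold higher attachment rate
  (adhesion-prone peritoneal surface): within-cycle attachment exceeds the
  1 cell·ml⁻¹ threshold but is cleared by each cycle end;
* ``bistable`` — ``beta_1 = 1e-6``, ``omega = 1e-5``, ``rho_0 = 0.1``:
  the surrogate model has coexisting low- and high-attachment stable
  equilibria (hysteresis window in ``omega`` roughly (5e-6, 1.1e-5));
* ``diseased`` — immune clearance reduced to ``omega = 3e-6``: sustained
  attachment (diseased state).

The calibration acceptance checks (each fixture produces its defining
behaviour) are part of the test suite.
"""

from __future__ import annotations

from .model_core import ParameterSet

__all__ = ["DEFAULTS", "fixtures", "get_fixture"]

#: Calibrated default parameter values (cells·ml⁻¹ and days).
DEFAULTS: dict[str, float] = {
    # macrophages
    "mu_M": 1.0e3,      # circulating M0 supply
    "eta_M": 0.03,      # production rate
    "M_C": 1.0e5,       # carrying capacity
    "theta_M": 0.01,    # KA-upregulated M1 activation
    "C_KA": 1.0e4,
    "beta_1": 1.0e-6,   # detection rate (printed value)
    "beta_2": 0.015,    # constant M2 activation
    "beta_12": 0.002,   # M1 -> M2 repolarization
    "beta_21": 0.01,    # M2 -> M1 repolarization
    "delta_M0": 0.05,
    "delta_M1": 0.05,
    "delta_M2": 0.05,
    # NK cells
    "mu_K": 2.5e3,
    "theta_K": 0.8,
    "C_M1": 3.0e4,
    "eta_K": 0.05,
    "K_C": 2.0e4,
    "sigma": 3.0e-6,    # exhaustion per ectopic-cell encounter
    "delta_K0": 0.3,
    "delta_KA": 0.05,
    # endometrial cells
    "a_E": 1.0e5,       # shedding amplitude
    "b_E": 20.0,        # pulse sharpness (~5-day menstrual pulse)
    "d_E": 9.0,         # phase: pulse peaks early in the cycle
    "delta_E0": 0.5,
    "rho_0": 0.1,       # retrograde fraction (printed high level)
    "rho_F": 1.0e-6,    # attachment rate
    "delta_EF": 2.0,
    "delta_EA": 0.005,
    "omega": 1.0e-5,    # immune clearance rate (printed value)
    "gamma": 0.95,      # NK share of clearance
    "eta_E": 0.075,     # attached-cell proliferation
    "E_C": 1.0e6,       # lesion carrying capacity
    "C_M2": 1.0e3,
    "cycle_length": 28.0,
}

_FIXTURE_OVERRIDES: dict[str, dict[str, float]] = {
    "reference": {"rho_0": 0.05},
    "low_influx": {"rho_0": 0.005},
    "transient": {"rho_0": 0.05, "rho_F": 1.5e-4},
    "bistable": {"rho_0": 0.1, "omega": 1.0e-5, "beta_1": 1.0e-6},
    "diseased": {"rho_0": 0.1, "omega": 3.0e-6},
}


def fixtures() -> dict[str, ParameterSet]:
    """All named parameter sets, keyed by regime name."""
    return {name: get_fixture(name) for name in _FIXTURE_OVERRIDES}


def get_fixture(name: str) -> ParameterSet:
    """Parameter set for a named regime (see module docstring)."""
    if name == "default":
        return ParameterSet(**DEFAULTS)
    try:
        overrides = _FIXTURE_OVERRIDES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: "
            f"{['default', *list(_FIXTURE_OVERRIDES)]}"
        ) from None
    return ParameterSet(**{**DEFAULTS, **overrides})
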