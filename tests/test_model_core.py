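"""Unit and property tests for the parameter/state model, the menstrual
influx forcing and the ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endoimmune.fixtures import DEFAULTS, get_fixture
from endoimmune.model_core import (
    InfluxMode,
    ParameterSet,
    SystemState,
    eval_influx_cyclic,
    eval_influx_mean,
    macrophage_fractions,
    rhs,
    validate_parameters,
)

from conftest import random_params, random_state


def params_with(**over) -> ParameterSet:
    return ParameterSet(**{**DEFAULTS, **over})


# ---------------------------------------------------------------------------
# influx forcing
# ---------------------------------------------------------------------------

class TestInflux:
    def test_zero_at_phase_origin(self):
        p = params_with(a_E=7.0, b_E=3.0, d_E=5.0)
        assert eval_influx_cyclic(-p.d_E, p) == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_at_half_period(self):
        p = params_with(a_E=5.0, b_E=4.0, d_E=3.0)
        t = p.cycle_length / 2.0 - p.d_E
        assert eval_influx_cyclic(t, p) == pytest.approx(5.0, rel=1e-12)

    def test_mean_of_squared_sine_is_half_amplitude(self):
        # closed form: mean of sin^2 over a period is 1/2
        p = params_with(a_E=2.0, b_E=2.0, d_E=0.0)
        assert eval_influx_mean(p) == pytest.approx(1.0, rel=1e-10)
        p4 = params_with(a_E=4.0, b_E=2.0, d_E=11.0)
        assert eval_influx_mean(p4) == pytest.approx(2.0, rel=1e-10)

    def test_mean_zero_amplitude(self):
        assert eval_influx_mean(params_with(a_E=0.0)) == 0.0

    @pytest.mark.parametrize("b_E", [1.0, 6.0, 20.0])
    def test_mean_matches_trapezoid_oracle(self, b_E):
        # independent high-resolution quadrature of the forcing itself
        p = params_with(a_E=1.0, b_E=b_E, d_E=4.0)
        t = np.linspace(0.0, p.cycle_length, 2_000_001)
        oracle = np.trapezoid(eval_influx_cyclic(t, p), t) / p.cycle_length
        assert eval_influx_mean(p) == pytest.approx(oracle, rel=1e-8)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(t=st.floats(-200.0, 200.0), b_E=st.floats(1.0, 24.0))
    def test_periodic_and_nonnegative(self, t, b_E):
        p = params_with(a_E=3.0, b_E=b_E, d_E=9.0)
        v = eval_influx_cyclic(t, p)
        assert v >= 0.0
        assert eval_influx_cyclic(t + p.cycle_length, p) == pytest.approx(
            v, abs=1e-12 * max(1.0, abs(v))
        )

    def test_nonfinite_time_rejected(self):
        with pytest.raises(ValueError):
            eval_influx_cyclic(np.nan, params_with())


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _rhs_oracle(x, p: ParameterSet, mu_E: float) -> np.ndarray:
    """Independent term-by-term transcription of the model equations."""
    M0, M1, M2, K0, KA, E0, EF, EA = x
    M = M0 + M1 + M2
    dM0 = (p.mu_M
           + p.eta_M * (1 - M / p.M_C) * M
           - p.theta_M * (KA / (p.C_KA + KA)) * M0
           - p.beta_1 * (EF + EA) * M0
           - p.beta_2 * M0
           - p.delta_M0 * M0)
    dM1 = (p.beta_1 * (EF + EA) * M0
           + p.theta_M * (KA / (p.C_KA + KA)) * M0
           + p.beta_21 * M2
           - p.beta_12 * M1
           - p.delta_M1 * M1)
    dM2 = p.beta_2 * M0 + p.beta_12 * M1 - p.beta_21 * M2 - p.delta_M2 * M2
    dK0 = p.mu_K - p.theta_K * K0 * (M1 / (p.C_M1 + M1)) - p.delta_K0 * K0
    dKA = (p.theta_K * K0 * (M1 / (p.C_M1 + M1))
           + p.eta_K * (1 - (KA + K0) / p.K_C) * KA
           - p.sigma * (EF + EA) * KA
           - p.delta_KA * KA)
    dE0 = mu_E - p.delta_E0 * p.rho_0 * E0 - p.delta_E0 * (1 - p.rho_0) * E0
    clr = p.omega * (p.gamma * KA + (1 - p.gamma) * M1)
    dEF = p.delta_E0 * p.rho_0 * E0 - clr * EF - p.rho_F * EF - p.delta_EF * EF
    dEA = (p.rho_F * EF
           + p.eta_E * EA * (1 - EA / p.E_C) * (M2 / (p.C_M2 + M2))
           - clr * EA
           - p.delta_EA * EA)
    return np.array([dM0, dM1, dM2, dK0, dKA, dE0, dEF, dEA])


class TestRHS:
    def test_only_supplies_survive_at_origin(self):
        p = params_with(mu_M=3.0, mu_K=2.0)
        mode = InfluxMode(tag="constant", mu_bar_E=1.0)
        d = rhs(0.0, np.zeros(8), p, mode)
        np.testing.assert_allclose(d, [3.0, 0, 0, 2.0, 0, 1.0, 0, 0], atol=0)

    def test_mass_action_terms_vanish_without_ectopic_cells(self):
        p = params_with()
        x = np.array([10.0, 5.0, 4.0, 8.0, 6.0, 100.0, 0.0, 0.0])
        d = rhs(0.0, x, p, InfluxMode(tag="constant", mu_bar_E=0.0))
        # dKA has no exhaustion contribution; recompute with sigma=0
        d2 = rhs(0.0, x, p.replace(sigma=0.0), InfluxMode(tag="constant", mu_bar_E=0.0))
        assert d[4] == d2[4]
        # dEA = 0 when EF = EA = 0
        assert d[7] == 0.0

    def test_matches_independent_oracle_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            p = random_params(rng)
            x = random_state(rng)
            mu = float(rng.uniform(0, 1e4))
            got = rhs(0.0, x, p, InfluxMode(tag="constant", mu_bar_E=mu))
            want = _rhs_oracle(x, p, mu)
            scale = np.maximum(np.abs(want), 1.0)
            assert np.max(np.abs(got - want) / scale) <= 1e-12

    def test_cyclic_mode_uses_forcing(self):
        p = params_with()
        x = np.zeros(8)
        d = rhs(3.0, x, p, InfluxMode.cyclic())
        assert d[5] == pytest.approx(eval_influx_cyclic(3.0, p), rel=1e-14)

    def test_E0_row_is_linear_in_E0(self):
        # d(dE0/dt)/dE0 = -delta_E0 independent of all other compartments
        rng = np.random.default_rng(7)
        p = random_params(rng)
        mode = InfluxMode(tag="constant", mu_bar_E=5.0)
        for _ in range(20):
            x = random_state(rng)
            x2 = x.copy()
            x2[5] += 1.0
            d1 = rhs(0.0, x, p, mode)
            d2 = rhs(0.0, x2, p, mode)
            assert d2[5] - d1[5] == pytest.approx(-p.delta_E0, rel=1e-6)
            # other rows affected only through the retrograde source in EF
            assert d2[6] - d1[6] == pytest.approx(p.delta_E0 * p.rho_0, rel=1e-6)

    @pytest.mark.parametrize("gamma,expect_m1,expect_ka", [(1.0, 0.0, 1.0), (0.0, 1.0, 0.0)])
    def test_clearance_split(self, gamma, expect_m1, expect_ka):
        # gamma=1: clearance depends only on KA; gamma=0: only on M1
        rng = np.random.default_rng(11)
        p = random_params(rng).replace(gamma=gamma)
        x = random_state(rng)
        mode = InfluxMode(tag="constant", mu_bar_E=0.0)
        base = rhs(0.0, x, p, mode)
        xm = x.copy(); xm[1] *= 2.0       # double M1
        xk = x.copy(); xk[4] *= 2.0       # double KA
        d_m1 = rhs(0.0, xm, p, mode)[6] - base[6]
        d_ka = rhs(0.0, xk, p, mode)[6] - base[6]
        clr_m1 = -p.omega * (1 - p.gamma) * x[1] * x[6]
        clr_ka = -p.omega * p.gamma * x[4] * x[6]
        assert d_m1 == pytest.approx(clr_m1, abs=1e-9 * max(1, abs(clr_m1)))
        assert d_ka == pytest.approx(clr_ka, abs=1e-9 * max(1, abs(clr_ka)))

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            rhs(0.0, np.array([1, 2, 3, 4, np.inf, 5, 6, 7.0]), params_with(),
                InfluxMode.cyclic())

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            InfluxMode(tag="weekly")


# ---------------------------------------------------------------------------
# macrophage fractions, state, validation, serialization
# ---------------------------------------------------------------------------

class TestFractionsAndState:
    def test_equal_split(self):
        s = SystemState(M0=1, M1=1, M2=1)
        assert macrophage_fractions(s) == pytest.approx((1 / 3, 1 / 3))

    def test_all_resting(self):
        assert macrophage_fractions(SystemState(M0=5.0)) == (0.0, 0.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            macrophage_fractions(SystemState())

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.tuples(*[st.floats(1e-6, 1e8) for _ in range(3)]))
    def test_fractions_normalize(self, triple):
        m0, m1, m2 = triple
        f1, f2 = macrophage_fractions(SystemState(M0=m0, M1=m1, M2=m2))
        f0 = m0 / (m0 + m1 + m2)
        assert f0 + f1 + f2 == pytest.approx(1.0, abs=1e-14)

    def test_negative_state_rejected_on_construction(self):
        with pytest.raises(ValueError):
            SystemState(M0=-1.0)
        # solver internals may bypass validation
        s = SystemState.from_array([-1e-9, 0, 0, 0, 0, 0, 0, 0], validate=False)
        assert s.M0 < 0


class TestValidationAndSerialization:
    def test_fixture_sets_are_valid(self):
        for name in ("reference", "low_influx", "transient", "bistable", "diseased"):
            assert validate_parameters(get_fixture(name)).ok

    def test_gamma_out_of_range_flagged(self):
        with pytest.raises(ValueError, match="gamma"):
            params_with(gamma=1.5)

    def test_negative_omega_flagged(self):
        with pytest.raises(ValueError, match="omega"):
            params_with(omega=-1e-6)

    def test_warning_for_disabled_disease_pathway(self):
        rep = validate_parameters(params_with(rho_0=0.0))
        assert rep.ok and any("rho_0" in w for w in rep.warnings)

    def test_round_trip(self):
        p = get_fixture("bistable")
        q = ParameterSet.from_dict(p.to_dict())
        assert q == p

    def test_unknown_key_rejected(self):
        d = dict(DEFAULTS)
        d["omega_typo"] = 1.0
        with pytest.raises(KeyError, match="omega_typo"):
            ParameterSet.from_dict(d)

    def test_missing_keys_listed(self):
        d = dict(DEFAULTS)
        d.pop("mu_M"); d.pop("sigma")
        with pytest.raises(KeyError) as err:
            ParameterSet.from_dict(d)
        assert "mu_M" in str(err.value) and "sigma" in str(err.value)

    def test_clearance_split_identity(self):
        p = params_with(gamma=0.3, omega=2e-5)
        assert p.omega_K == pytest.approx(0.3 * 2e-5)
        assert p.omega_K + p.omega_M == pytest.approx(p.omega)

    def test_constant_mode_mean_consistency(self):
        # constant-mode rate equals the cycle average of the cyclic forcing
        p = params_with(a_E=123.0, b_E=7.0)
        mode = InfluxMode.constant(p)
        t = np.linspace(0, p.cycle_length, 400_001)
        quad = np.trapezoid(eval_influx_cyclic(t, p), t) / p.cycle_length
        assert mode.mu_bar_E == pytest.approx(quad, rel=1e-8)
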