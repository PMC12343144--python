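"""Continuation, fold, hysteresis, limit-cycle and region-map tests."""

import numpy as np
import pytest

import endoimmune.bifurcation as bif
from endoimmune.bifurcation import (
    LimitCycleInfo,
    RegionMap,
    characterize_limit_cycle,
    classify_region,
    codim2_region_map,
    continue_branch,
    hysteresis_sweep,
)
from endoimmune.equilibria import find_equilibria
from endoimmune.model_core import InfluxMode, rhs


@pytest.fixture(scope="module")
def omega_branch(bistable):
    """The equilibrium branch in omega through the bistable window."""
    p_top = bistable.replace(omega=3e-5)
    eqs = find_equilibria(p_top, n_starts=30, seed=2)
    return bistable, continue_branch(p_top, "omega", (2e-6, 3e-5), eqs[0])


class TestContinueBranch:
    def test_no_proliferation_single_monotone_branch(self, bistable):
        # with eta_E = 0 the disease-free state is unique and stable
        p = bistable.replace(eta_E=0.0, omega=3e-5)
        eqs = find_equilibria(p, n_starts=20, seed=0)
        br = continue_branch(p, "omega", (2e-6, 3e-5), eqs[0])
        assert br.folds == []
        assert all(pt.eq.stability == "stable" for pt in br.points)
        assert all(pt.eq.EA < 1.0 for pt in br.points)

    def test_bistable_window_bracketed_by_two_folds(self, omega_branch):
        params, br = omega_branch
        assert len(br.folds) == 2
        lo, hi = br.folds
        assert lo < params.omega < hi
        # the S-curve: stable-unstable-stable along arclength
        stabs = [pt.eq.stability for pt in br.points]
        runs = [stabs[0]]
        for s in stabs[1:]:
            if s != runs[-1]:
                runs.append(s)
        assert runs == ["stable", "unstable", "stable"]

    def test_folds_cross_validated_by_multistart(self, omega_branch):
        # inside the folds 3 equilibria exist, outside only 1
        params, br = omega_branch
        lo, hi = br.folds
        inside = find_equilibria(params.replace(omega=np.sqrt(lo * hi)),
                                 n_starts=40, seed=5)
        outside = find_equilibria(params.replace(omega=hi * 1.5),
                                  n_starts=40, seed=5)
        assert len(inside) == 3
        assert len(outside) == 1

    def test_branch_points_satisfy_rhs(self, omega_branch):
        params, br = omega_branch
        for pt in br.points[:: max(1, len(br.points) // 20)]:
            p = params.replace(omega=pt.param)
            res = rhs(0.0, pt.eq.state.to_array(), p, InfluxMode.constant(p))
            assert np.max(np.abs(res)) <= 1e-8

    def test_invalid_vary_rejected(self, bistable):
        eqs = find_equilibria(bistable, n_starts=5, seed=0)
        with pytest.raises(ValueError):
            continue_branch(bistable, "mu_M", (1.0, 2.0), eqs[0])


class TestLimitCycles:
    def test_stable_equilibrium_reports_no_cycle(self, bistable):
        eqs = find_equilibria(bistable, n_starts=25, seed=1)
        stable = [e for e in eqs if e.stability == "stable"][0]
        info = characterize_limit_cycle(bistable, stable)
        assert not info.cycle_found

    def test_saddle_converges_to_equilibrium_no_cycle(self, bistable):
        # the middle-branch saddle has a real leading eigenvalue: a nearby
        # trajectory slides to one of the stable equilibria
        eqs = find_equilibria(bistable, n_starts=40, seed=1)
        saddle = [e for e in eqs if e.stability == "unstable"][0]
        info = characterize_limit_cycle(bistable, saddle, n_periods=10)
        assert not info.cycle_found

    def test_median_lies_between_extremes_when_cycle_reported(self):
        # order-statistic invariant of the reclassification value
        info = LimitCycleInfo(period=30.0, median_EA=5.0, amplitude_EA=8.0,
                              min_EA=1.0, max_EA=9.0)
        assert info.min_EA <= info.median_EA <= info.max_EA


class TestClassifyRegion:
    def test_no_proliferation_is_disease_free(self, bistable):
        cell = classify_region(bistable.replace(eta_E=0.0))
        assert cell.label == "disease-free"

    def test_bistable_fixture_is_bistable(self, bistable):
        cell = classify_region(bistable)
        assert cell.label == "bistable"
        assert min(cell.attractor_EAs) < 1.0 < max(cell.attractor_EAs)

    def test_label_invariant_to_seed(self, bistable):
        a = classify_region(bistable, seed=0)
        b = classify_region(bistable, seed=123)
        assert a.label == b.label

    def test_diseased_fixture_is_high_disease(self, diseased):
        assert classify_region(diseased).label == "high-disease"

    def test_cycle_only_attractor_triggers_reclassification(self, bistable,
                                                            monkeypatch):
        # if the only high-side attractor is a limit cycle, the cell is
        # labelled through the median-EA rule and flagged reclassified
        def fake_find(params, n_starts=30, seed=0, **kw):
            eqs = find_equilibria(params, n_starts=25, seed=1)
            out = []
            for e in eqs:
                if e.stability == "stable" and e.EA > 1.0:
                    # pretend the high equilibrium lost stability via a
                    # Hopf bifurcation
                    e.stability = "unstable"
                    e.eigenvalues = np.array([0.01 + 0.5j, 0.01 - 0.5j]
                                             + [-1.0] * 6)
                out.append(e)
            return out

        def fake_cycle(params, near_eq, **kw):
            return LimitCycleInfo(period=40.0, median_EA=near_eq.EA,
                                  amplitude_EA=0.3 * near_eq.EA)

        monkeypatch.setattr(bif, "find_equilibria", fake_find)
        monkeypatch.setattr(bif, "characterize_limit_cycle", fake_cycle)
        cell = classify_region(bistable)
        assert cell.label == "bistable"
        assert cell.limit_cycle and cell.reclassified


class TestHysteresis:
    def test_monostable_range_traces_coincide(self, bistable):
        fwd, bwd = hysteresis_sweep(bistable, "omega", (1.5e-5, 3e-5),
                                    n_steps=5, t_settle=2000.0)
        f = fwd.EA
        b = bwd.EA[::-1]
        assert np.max(np.abs(f - b) / np.maximum(f, 1e-9)) < 1e-4

    def test_bistable_loop_has_positive_area(self, bistable):
        fwd, bwd = hysteresis_sweep(bistable, "omega", (2e-6, 3e-5),
                                    n_steps=13, t_settle=2500.0)
        f = fwd.EA
        b = bwd.EA[::-1]
        assert np.any(np.abs(f - b) > 1.0)          # distinct attractors
        # forward (declining clearance) switches up at a lower omega than
        # backward (recovering clearance) switches down
        assert f.max() > 1e4 and b.max() > 1e4

    def test_determinism(self, bistable):
        a = hysteresis_sweep(bistable, "omega", (4e-6, 2e-5), n_steps=5,
                             t_settle=1500.0)
        c = hysteresis_sweep(bistable, "omega", (4e-6, 2e-5), n_steps=5,
                             t_settle=1500.0)
        np.testing.assert_array_equal(a[0].end_states, c[0].end_states)
        np.testing.assert_array_equal(a[1].end_states, c[1].end_states)


class TestRegionMap:
    def test_all_disease_free_without_proliferation(self, bistable):
        p = bistable.replace(eta_E=0.0)
        rm = codim2_region_map(p, [1e-7, 1e-6], [5e-6, 2e-5], [0.05],
                               n_starts=12, seed=0)
        assert all(lab == "disease-free"
                   for row in rm.labels[0] for lab in row)

    def test_transition_band_shifts_but_persists_across_influx(self, bistable):
        # a bistable band separates disease-free and high-disease cells at
        # every retrograde influx level
        wg = np.geomspace(3e-6, 2e-5, 9)
        rm = codim2_region_map(bistable, [1e-6], wg, [0.005, 0.05, 0.1],
                               n_starts=18, seed=0)
        for lev in range(3):
            labs = [rm.labels[lev][0][j] for j in range(wg.size)]
            assert "high-disease" in labs and "disease-free" in labs
            assert "bistable" in labs
            # ordered: high-disease at low omega, disease-free at high
            assert labs[0] == "high-disease" and labs[-1] == "disease-free"

    def test_serialization_round_trip(self, bistable, tmp_path):
        rm = codim2_region_map(bistable.replace(eta_E=0.0),
                               [1e-6], [5e-6, 2e-5], [0.05],
                               n_starts=8, seed=0)
        path = tmp_path / "map.json"
        rm.to_json(path)
        rm2 = RegionMap.from_json(path)
        assert rm2.labels == rm.labels
        np.testing.assert_array_equal(rm2.omega_grid, rm.omega_grid)
        assert rm.to_json() == rm2.to_json()
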