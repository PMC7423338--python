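import numpy as np
import pytest
from scipy import stats

from iceswitch import (
    SimState,
    build_feedback_only,
    compile_network,
    endpoint,
    integrate_species,
    propensities,
    simulate_cell,
    simulate_cell_summary,
)
from iceswitch.ssa import Trajectory, _FREE


def _state(compiled, counts, occupancy=None):
    occ = np.full(compiled.n_promoters, _FREE, dtype=np.int64)
    if occupancy is not None:
        occ[:] = occupancy
    return SimState(time=0.0, counts=np.asarray(counts, dtype=np.int64), occupancy=occ)


class TestPropensities:
    def test_binding_counts_oligomer_combinations(self):
        # 8 free monomers, dimer binding at A1=0.01: C(8,2)=28 pairs -> 0.28
        compiled = compile_network(build_feedback_only({"A1": 0.01}))
        a = propensities(_state(compiled, [8]), compiled)
        assert a[0] == pytest.approx(0.28)

    def test_binding_zero_below_oligomer_order(self):
        compiled = compile_network(build_feedback_only())
        a = propensities(_state(compiled, [1]), compiled)
        assert a[0] == 0.0

    def test_degradation_is_mass_action(self):
        compiled = compile_network(build_feedback_only({"A4": 0.3}))
        a = propensities(_state(compiled, [10]), compiled)
        assert a[3] == pytest.approx(3.0)

    def test_bound_promoter_exposes_unbinding_and_production(self):
        compiled = compile_network(build_feedback_only({"A2": 5.0, "A3": 10.0}))
        a = propensities(_state(compiled, [4], occupancy=[0]), compiled)
        assert a[0] == 0.0          # no double binding
        assert a[1] == pytest.approx(5.0)
        assert a[2] == pytest.approx(10.0)

    def test_all_zero_vector_signals_absorbed_state(self):
        compiled = compile_network(build_feedback_only())
        a = propensities(_state(compiled, [0]), compiled)
        assert np.all(a == 0.0)


class TestSimulateCell:
    def test_absorbed_at_start_has_no_events(self, death_model):
        tr = simulate_cell(death_model, {"X": 0}, 50.0, seed=1)
        assert tr.n_events == 0
        assert tr.endpoint("X", 50.0) == 0

    def test_pure_death_ensemble_mean(self, death_model):
        # linear death: E[X(t)] = x0 * exp(-gamma t) = 8 e^-3
        n = 10_000
        vals = np.array([
            simulate_cell_summary(death_model, {"X": 8}, 10.0, seed=s).final_counts[0]
            for s in range(n)
        ])
        expected = 8 * np.exp(-3.0)
        se = vals.std(ddof=1) / np.sqrt(n)
        assert abs(vals.mean() - expected) < 3 * se

    def test_same_seed_is_bit_identical(self):
        model = build_feedback_only()
        a = simulate_cell(model, {"BisDC": 8}, 100.0, seed=123)
        b = simulate_cell(model, {"BisDC": 8}, 100.0, seed=123)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.counts, b.counts)

    def test_summary_matches_trajectory_endpoint(self):
        model = build_feedback_only()
        for seed in range(5):
            tr = simulate_cell(model, {"BisDC": 8}, 100.0, seed=seed)
            cs = simulate_cell_summary(model, {"BisDC": 8}, 100.0, seed=seed)
            assert tr.endpoint("BisDC", 100.0) == cs.final_counts[0]
            assert tr.n_events == cs.n_events

    def test_recorded_integral_matches_trajectory(self):
        model = build_feedback_only()
        tr = simulate_cell(model, {"BisDC": 8}, 100.0, seed=7)
        cs = simulate_cell_summary(model, {"BisDC": 8}, 100.0, seed=7,
                                   windows=[("BisDC", 10.0, 20.0)])
        assert cs.integrals[0] == pytest.approx(tr.integrate("BisDC", 10.0, 20.0))

    def test_invalid_t_end(self, death_model):
        with pytest.raises(ValueError):
            simulate_cell(death_model, {"X": 1}, 0.0, seed=1)

    def test_zero_state_is_absorbing(self):
        # no basal production: once counts and occupancy hit zero, nothing fires
        model = build_feedback_only({"A1": 0.0})
        tr = simulate_cell(model, {"BisDC": 5}, 200.0, seed=11)
        assert tr.endpoint("BisDC", 200.0) == 0
        assert tr.counts[-1, 0] == 0


class TestMassConservation:
    @pytest.mark.parametrize("seed", range(8))
    def test_free_plus_sequestered_changes_one_at_a_time(self, seed):
        model = build_feedback_only()
        compiled = compile_network(model)
        n = compiled.cfg_order[0]
        tr = simulate_cell(model, {"BisDC": 8}, 50.0, seed=seed)
        total = tr.counts[:, 0] + n * (tr.occupancy[:, 0] != _FREE)
        deltas = np.diff(total)
        # bind/unbind conserve mass; production +1; degradation -1
        assert set(np.unique(deltas)).issubset({-1, 0, 1})


class TestTrajectoryQueries:
    def _manual_traj(self):
        # count 2 on [10, 15), 4 on [15, 20]; single species "X"
        times = np.array([0.0, 10.0, 15.0])
        counts = np.array([[0], [2], [4]])
        occ = np.zeros((3, 0), dtype=np.int64)
        return Trajectory(times, counts, occ, 20.0, ["X"])

    def test_piecewise_integral(self):
        tr = self._manual_traj()
        assert tr.integrate("X", 10.0, 20.0) == pytest.approx(30.0)
        assert tr.integrate("X", 0.0, 10.0) == pytest.approx(0.0)

    def test_integral_is_additive_over_subwindows(self):
        tr = self._manual_traj()
        whole = tr.integrate("X", 0.0, 20.0)
        parts = tr.integrate("X", 0.0, 12.5) + tr.integrate("X", 12.5, 20.0)
        assert whole == pytest.approx(parts)

    def test_constant_count_integral(self):
        times = np.array([0.0])
        tr = Trajectory(times, np.array([[2]]), np.zeros((1, 0), dtype=np.int64),
                        30.0, ["X"])
        assert tr.integrate("X", 10.0, 20.0) == pytest.approx(20.0)

    def test_endpoint_is_right_continuous(self):
        tr = self._manual_traj()
        assert tr.endpoint("X", 0.0) == 0
        assert tr.endpoint("X", 15.0) == 4   # post-event value at an event time
        assert tr.endpoint("X", 14.999) == 2

    def test_window_validation(self):
        tr = self._manual_traj()
        with pytest.raises(ValueError):
            tr.integrate("X", 5.0, 25.0)
        with pytest.raises(ValueError):
            tr.integrate("X", 15.0, 15.0)
        with pytest.raises(KeyError):
            tr.endpoint("Y", 1.0)


class TestDistributionOracles:
    def test_birth_death_stationary_poisson(self, birth_death_model):
        # constant production k=5, degradation 1: stationary Poisson(5)
        n = 10_000
        vals = np.array([
            simulate_cell_summary(birth_death_model, {"X": 0}, 15.0, seed=s).final_counts[0]
            for s in range(n)
        ])
        kmax = max(vals.max(), 12)
        observed = np.bincount(vals, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), 5.0) * n
        # pool sparse tail bins for a valid chi-square
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        chi2 = ((obs - exp) ** 2 / exp).sum()
        pval = stats.chi2.sf(chi2, len(obs) - 1)
        assert pval > 0.01

    def test_waiting_times_are_exponential(self, pure_birth_model):
        # single channel with constant propensity 3
        tr = simulate_cell(pure_birth_model, {"X": 0}, 3500.0, seed=42)
        gaps = np.diff(tr.times)
        assert len(gaps) > 9_000
        _, pval = stats.kstest(gaps, "expon", args=(0, 1 / 3.0))
        assert pval > 0.01
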