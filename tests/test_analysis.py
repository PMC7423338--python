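import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iceswitch import (
    InputSpec,
    build_feedback_only,
    build_kickstart,
    classify_states,
    compare_feedback,
    dose_response,
    parameter_sweep,
    run_ensemble,
)
from iceswitch.analysis import bootstrap_median_ci, cascade_bimodality


class TestClassifyStates:
    def test_partition_at_exact_zero(self):
        s = classify_states([0, 0, 5, 3])
        assert s.zero_fraction == 0.5
        assert s.positive_count == 2
        assert s.positive_median == 4.0

    def test_all_zero_population(self):
        s = classify_states([0, 0, 0])
        assert s.zero_fraction == 1.0
        assert s.positive_count == 0
        assert s.positive_median is None and s.positive_iqr is None

    def test_zero_bar_is_its_own_bin(self):
        s = classify_states([0, 0, 5, 3], bin_width=1.0)
        assert s.bin_counts[0] == 2                 # [-0.5, 0.5) holds the zero state
        assert s.bin_counts.sum() == s.n

    def test_empty_and_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_states([])
        with pytest.raises(ValueError):
            classify_states([-1.0, 2.0])

    @settings(max_examples=40, deadline=None)
    @given(
        values=st.lists(
            st.one_of(st.just(0.0), st.floats(0.5, 1e4)), min_size=1, max_size=60
        ),
        c=st.floats(0.01, 100.0),
    )
    def test_scale_covariance_of_positive_part(self, values, c):
        base = classify_states(values)
        scaled = classify_states([c * v for v in values])
        assert scaled.zero_fraction == base.zero_fraction
        if base.positive_count:
            assert scaled.positive_median == pytest.approx(c * base.positive_median)


class TestParameterSweep:
    def test_empty_grid_rejected(self, binomial_input):
        with pytest.raises(ValueError):
            parameter_sweep(build_feedback_only, {}, binomial_input, 10, 50.0, 1)
        with pytest.raises(ValueError):
            parameter_sweep(build_feedback_only, {"A4": []}, binomial_input, 10, 50.0, 1)

    def test_no_production_gives_all_zero(self, binomial_input):
        # t_end = 100 >> 1/A4 so every initial molecule is gone at the end
        df = parameter_sweep(build_feedback_only, {"A3": [0.0], "A4": [1.0]},
                             binomial_input, 200, 100.0, 3)
        assert df.zero_fraction.iloc[0] == 1.0

    def test_sweep_reports_one_row_per_grid_point(self, binomial_input):
        df = parameter_sweep(build_feedback_only, {"A4": [0.1, 0.3]},
                             binomial_input, 100, 50.0, 3)
        assert list(df["A4"]) == [0.1, 0.3]
        assert {"zero_fraction", "positive_median"} <= set(df.columns)


class TestDoseResponse:
    def test_requires_increasing_levels(self):
        with pytest.raises(ValueError):
            dose_response(build_kickstart, [4], 10, 50.0, 1)
        with pytest.raises(ValueError):
            dose_response(build_kickstart, [4, 2], 10, 50.0, 1)

    def test_zero_input_level_never_activates(self):
        spec = InputSpec("BisR", "point", {"value": 0})
        ens = run_ensemble(build_kickstart(), spec, 300, 100.0, root_seed=4)
        assert (ens.endpoint("BisDC") == 0).all()


class TestCascadeBimodality:
    def test_zero_tcir_gives_zero_everywhere(self):
        from iceswitch import build_full_cascade
        spec = InputSpec("TciR", "point", {"value": 0})
        ens = run_ensemble(build_full_cascade(), spec, 200, 100.0, root_seed=6,
                           windows=[("BisR", 10.0, 20.0)])
        nodes = cascade_bimodality(ens)
        assert nodes["BisR"].zero_fraction == 1.0
        assert nodes["BisDC"].zero_fraction == 1.0

    def test_missing_window_raises(self):
        from iceswitch import build_full_cascade
        spec = InputSpec("TciR", "uniform", {"low": 0, "high": 16})
        ens = run_ensemble(build_full_cascade(), spec, 50, 100.0, root_seed=6)
        with pytest.raises(ValueError):
            cascade_bimodality(ens)


class TestCompareFeedback:
    def test_identical_ensembles_give_ratio_one(self):
        from iceswitch import build_full_cascade
        spec = InputSpec("TciR", "uniform", {"low": 0, "high": 16})
        model = build_full_cascade(include_late=True)
        ens = run_ensemble(model, spec, 2000, 100.0, root_seed=8)
        rec = compare_feedback(ens, ens)
        assert rec["median_ratio"] == pytest.approx(1.0)

    def test_mismatched_ensembles_rejected(self):
        from iceswitch import build_full_cascade
        model = build_full_cascade(include_late=True)
        a = run_ensemble(model, InputSpec("TciR", "point", {"value": 8}),
                         50, 100.0, root_seed=1)
        b = run_ensemble(model, InputSpec("TciR", "point", {"value": 8}),
                         60, 100.0, root_seed=1)
        with pytest.raises(ValueError):
            compare_feedback(a, b)
        c = run_ensemble(model, InputSpec("TciR", "point", {"value": 4}),
                         50, 100.0, root_seed=1)
        with pytest.raises(ValueError):
            compare_feedback(a, c)

    def test_unstable_protein_has_lower_endpoint_than_stable(self):
        # birth-death logic: at matched production the mean scales as 1/gamma
        from iceswitch import build_full_cascade
        spec = InputSpec("TciR", "uniform", {"low": 0, "high": 16})
        medians = {}
        for stability in ("stable", "unstable"):
            model = build_full_cascade(include_feedback=False, include_late=True,
                                       late_stability=stability)
            ens = run_ensemble(model, spec, 4000, 100.0, root_seed=12)
            vals = ens.endpoint("Late")
            medians[stability] = np.median(vals[vals > 0])
        assert medians["unstable"] < medians["stable"]


def test_bootstrap_ci_brackets_median():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(3, 0.4, size=500)
    lo, hi = bootstrap_median_ci(vals, seed=1)
    assert lo < np.median(vals) < hi
    with pytest.raises(ValueError):
        bootstrap_median_ci([])
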