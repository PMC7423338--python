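import numpy as np
import pytest
from scipy import stats

from iceswitch import (
    InputSpec,
    build_kickstart,
    generate_cells,
    link_ensemble,
    percentile_summary,
    qq_subpopulation_estimate,
    run_ensemble,
)


class TestGenerateCells:
    def test_degenerate_fractions(self):
        assert not generate_cells(200, 0.0, rng=1).labels.any()
        assert generate_cells(200, 1.0, rng=1).labels.all()

    def test_realized_active_count_is_binomial(self):
        n, f = 1000, 0.05
        sample = generate_cells(n, f, rng=np.random.default_rng(7))
        se = np.sqrt(n * f * (1 - f))
        assert abs(sample.labels.sum() - n * f) < 4 * se

    def test_intensities_positive_and_components_separated(self):
        sample = generate_cells(2000, 0.5, rng=np.random.default_rng(3))
        assert (sample.intensities > 0).all()
        active_med = np.median(sample.intensities[sample.labels])
        bg_med = np.median(sample.intensities[~sample.labels])
        assert active_med > 5 * bg_med

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            generate_cells(0, 0.1)
        with pytest.raises(ValueError):
            generate_cells(10, 1.5)
        with pytest.raises(ValueError):
            generate_cells(10, 0.1, active_params={"median": 50.0})  # below background


class TestQQEstimator:
    def test_pure_background_estimates_near_zero(self):
        sample = generate_cells(1000, 0.0, rng=np.random.default_rng(5))
        est = qq_subpopulation_estimate(sample)
        assert est.estimated_fraction <= 0.01

    @pytest.mark.parametrize("true_f,tol", [(0.05, 0.02), (0.5, 0.05)])
    def test_recovery_at_known_fraction(self, true_f, tol):
        errors = []
        for rep in range(100):
            sample = generate_cells(1000, true_f,
                                    rng=np.random.default_rng(1000 * rep + 17))
            est = qq_subpopulation_estimate(sample)
            errors.append(est.estimated_fraction - true_f)
        assert np.median(np.abs(errors)) <= tol

    def test_estimate_monotone_in_true_fraction(self):
        grid = [0.01, 0.02, 0.05, 0.1, 0.2]
        means = []
        for f in grid:
            ests = [
                qq_subpopulation_estimate(
                    generate_cells(1000, f, rng=np.random.default_rng(50 * r + int(1e4 * f)))
                ).estimated_fraction
                for r in range(30)
            ]
            means.append(np.mean(ests))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_small_samples_and_bad_values_rejected(self):
        with pytest.raises(ValueError):
            qq_subpopulation_estimate(np.full(50, 100.0))
        with pytest.raises(ValueError):
            qq_subpopulation_estimate(np.concatenate([np.full(200, 100.0), [-1.0]]))

    def test_normal_reference_supported(self):
        sample = generate_cells(1000, 0.05, rng=np.random.default_rng(2))
        est = qq_subpopulation_estimate(sample, reference="normal")
        assert 0.0 <= est.estimated_fraction <= 1.0


@pytest.fixture(scope="module")
def bistable_ensemble():
    # low-dose input: a minority of cells activates, the estimator's regime
    spec = InputSpec("BisR", "uniform", {"low": 0, "high": 4})
    return run_ensemble(build_kickstart(), spec, 2000, 100.0, root_seed=31)


class TestLinkEnsemble:
    def test_all_zero_ensemble_is_pure_background(self):
        from iceswitch import build_feedback_only
        spec = InputSpec("BisDC", "point", {"value": 0})
        ens = run_ensemble(build_feedback_only(), spec, 1000, 50.0, root_seed=1)
        sample = link_ensemble(ens, "BisDC", rng=np.random.default_rng(4))
        reference = generate_cells(1000, 0.0, rng=np.random.default_rng(99))
        _, pval = stats.ks_2samp(sample.intensities, reference.intensities)
        assert pval > 0.01

    def test_zero_gain_is_pure_background(self, bistable_ensemble):
        sample = link_ensemble(bistable_ensemble, "BisDC", gain=0.0,
                               rng=np.random.default_rng(4))
        reference = generate_cells(2000, 0.0, rng=np.random.default_rng(99))
        _, pval = stats.ks_2samp(sample.intensities, reference.intensities)
        assert pval > 0.01

    def test_intensity_ranking_recovers_true_labels(self, bistable_ensemble):
        sample = link_ensemble(bistable_ensemble, "BisDC",
                               rng=np.random.default_rng(8))
        est = qq_subpopulation_estimate(sample)
        thresh = np.quantile(sample.intensities, est.breakpoint_quantile)
        called = sample.intensities > thresh
        recovered = (called & sample.labels).sum() / sample.labels.sum()
        assert recovered >= 0.90

    def test_active_median_invariant_across_input_levels(self):
        # two input doses: activated-cell intensity median moves < 10%
        meds = []
        for i, mult in enumerate((0.5, 2.0)):
            spec = InputSpec("BisR", "uniform", {"low": 0, "high": 16},
                             scale_multiplier=mult)
            ens = run_ensemble(build_kickstart(), spec, 3000, 100.0, root_seed=77)
            sample = link_ensemble(ens, "BisDC", rng=np.random.default_rng(60 + i))
            meds.append(np.median(sample.intensities[sample.labels]))
            fracs = sample.true_active_fraction
        assert abs(meds[1] - meds[0]) / meds[0] < 0.10


class TestPercentileSummary:
    def test_midpoint_convention(self):
        assert percentile_summary(np.array([1.0, 2.0, 3.0, 4.0]), 0.5) == 2.5

    def test_constant_sample(self):
        assert percentile_summary(np.full(10, 7.0), 0.3) == 7.0
        assert percentile_summary(np.full(10, 7.0), 0.9) == 7.0

    def test_validation(self):
        with pytest.raises(ValueError):
            percentile_summary(np.array([]), 0.5)
        with pytest.raises(ValueError):
            percentile_summary(np.array([1.0]), 1.0)

    def test_skewed_mixture_quantile_sensitivity(self):
        # a 5% activated tail moves the 99th percentile far more than the 75th
        bg = generate_cells(10_000, 0.0, rng=np.random.default_rng(11))
        mix = generate_cells(10_000, 0.05, rng=np.random.default_rng(12))
        gap_75 = percentile_summary(mix, 0.75) - percentile_summary(bg, 0.75)
        gap_99 = percentile_summary(mix, 0.99) - percentile_summary(bg, 0.99)
        median_gap = 1000.0 - 100.0  # activated vs background medians
        assert abs(gap_75) < median_gap
        assert gap_99 > median_gap
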