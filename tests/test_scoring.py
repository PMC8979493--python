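import math

import numpy as np
import pytest

from sdx.scoring import (
    DegenerateProfileError,
    DependencyMatrix,
    MixtureFit,
    compute_2c_profile,
    fit_mixture,
    norm_lrt,
    posterior_log_ratio,
    select_two_component,
    sigma_outlier_filter,
    zscore_profile,
)


class TestZscore:
    def test_already_standardized(self):
        np.testing.assert_allclose(zscore_profile([-1, 0, 1]), [-1, 0, 1], atol=1e-12)

    def test_constant_raises(self):
        with pytest.raises(DegenerateProfileError):
            zscore_profile([2, 2, 2])

    def test_recovers_standard_moments(self):
        x = np.random.default_rng(0).normal(5, 2, 1000)
        z = zscore_profile(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_nan_passthrough(self):
        z = zscore_profile([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(z[1]) and np.isfinite(z[[0, 2, 3]]).all()


class TestSigmaFilter:
    def test_single_big_outlier_kept(self):
        row = np.zeros(101)
        row[-1] = 10.0
        m = DependencyMatrix(["g"], [f"s{i}" for i in range(101)], row[None, :])
        assert sigma_outlier_filter(m, 6.0) == ["g"]
        # the outlier's z-score is 9.95 with sample sd
        z = zscore_profile(row)
        assert abs(z[-1] - 9.95) < 0.005

    def test_constant_row_excluded(self):
        m = DependencyMatrix(["g"], ["a", "b", "c"], np.ones((1, 3)))
        assert sigma_outlier_filter(m, 6.0) == []

    def test_gaussian_rows_rarely_pass_six_sigma(self):
        kept = 0
        for seed in range(100):
            row = np.random.default_rng(seed).normal(0, 1, 769)
            m = DependencyMatrix(["g"], [f"s{i}" for i in range(769)], row[None, :])
            kept += len(sigma_outlier_filter(m, 6.0))
        assert kept < 5

    def test_min_fraction_threshold(self):
        # 3-sigma mode: needs ceil(0.2 * n) outliers
        row = np.zeros(20)
        row[:3] = 50.0
        m = DependencyMatrix(["g"], [f"s{i}" for i in range(20)], row[None, :])
        assert sigma_outlier_filter(m, 1.5, 0.20) == []  # 3 < ceil(0.2*20)=4
        row[3] = 50.0
        m = DependencyMatrix(["g"], [f"s{i}" for i in range(20)], row[None, :])
        assert sigma_outlier_filter(m, 1.5, 0.20) == ["g"]


class TestFitMixture:
    def test_bic_identity(self):
        fit = MixtureFit(1, "gaussian", [1.0], [0.0], [1.0], None, -100.0, 3, 100)
        assert fit.bic == pytest.approx(3 * math.log(100) + 200, abs=1e-9)
        assert fit.bic == pytest.approx(213.8155, abs=1e-3)

    def test_constant_input_floored_scale(self):
        fit = fit_mixture(np.full(25, 3.0), 1, "gaussian")
        assert fit.locations[0] == pytest.approx(3.0)
        assert fit.scales[0] == pytest.approx(1e-6)
        assert np.isfinite(fit.log_likelihood)

    def test_parameter_recovery_gaussian(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 1, 800), rng.normal(-5, 1, 200)])
        fit = fit_mixture(x, 2, "gaussian", seed=1)
        assert fit.locations[0] == pytest.approx(-5, abs=0.15)
        assert fit.locations[1] == pytest.approx(0, abs=0.15)
        assert fit.weights[0] == pytest.approx(0.2, abs=0.03)

    def test_parameter_recovery_t(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 800), rng.normal(-5, 1, 200)])
        fit = fit_mixture(x, 2, "t", seed=1)
        assert fit.locations[0] == pytest.approx(-5, abs=0.15)
        assert fit.locations[1] == pytest.approx(0, abs=0.15)
        assert fit.weights[0] == pytest.approx(0.2, abs=0.03)
        assert fit.n_params == 7

    def test_bic_invariant_holds_for_every_fit(self):
        x = np.random.default_rng(3).normal(0, 1, 200)
        for nc, fam in [(1, "t"), (2, "t"), (1, "gaussian"), (2, "gaussian")]:
            fit = fit_mixture(x, nc, fam, seed=0)
            assert fit.bic == pytest.approx(
                fit.n_params * math.log(fit.n_obs) - 2 * fit.log_likelihood, abs=1e-9
            )

    def test_too_few_values(self):
        with pytest.raises(DegenerateProfileError):
            fit_mixture(np.arange(5.0), 1, "t")

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(-4, 1, 100)])
        f1 = fit_mixture(x, 2, "t", seed=9)
        f2 = fit_mixture(x, 2, "t", seed=9)
        assert f1.log_likelihood == f2.log_likelihood
        np.testing.assert_array_equal(f1.locations, f2.locations)


class TestSelectTwoComponent:
    def test_bimodal_called(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.8, 592), rng.normal(-4, 0.8, 177)])
        assert select_two_component(x, seed=0)

    def test_unimodal_not_called(self):
        x = np.random.default_rng(0).standard_t(5, 769)
        assert not select_two_component(x, seed=0)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 600), rng.normal(-4, 1, 169)])
        assert select_two_component(x, seed=4) == select_two_component(x, seed=4)


class TestTwoComponentProfile:
    @pytest.fixture
    def symmetric_fit(self):
        ll = 0.0
        return MixtureFit(2, "gaussian", [0.5, 0.5], [-1.0, 0.0], [0.5, 0.5], None, ll, 5, 100)

    def test_midpoint_score_zero(self, symmetric_fit):
        assert posterior_log_ratio(symmetric_fit, [-0.5])[0] == pytest.approx(0.0, abs=1e-12)

    def test_score_at_lower_mean(self, symmetric_fit):
        # ln N(-1; 0, 0.5) - ln N(-1; -1, 0.5) = -1 / (2 * 0.25)
        assert posterior_log_ratio(symmetric_fit, [-1.0])[0] == pytest.approx(-2.0, abs=1e-12)

    def test_direction_increased_for_low_minority(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 800), rng.normal(-5, 1, 200)])
        prof = compute_2c_profile(x, seed=1)
        assert prof.direction == "increased"
        assert prof.responsive_component == 1
        assert prof.responsive_n == pytest.approx(200, abs=10)

    def test_direction_decreased_for_high_minority(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 800), rng.normal(5, 1, 200)])
        prof = compute_2c_profile(x, seed=1)
        assert prof.direction == "decreased"
        assert prof.responsive_component == 2

    def test_posterior_normalization(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(-4, 1, 80)])
        prof = compute_2c_profile(x, seed=2)
        np.testing.assert_allclose(prof.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_monotone_between_means(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(-4, 1.4, 80)])
        prof = compute_2c_profile(x, seed=3)
        lo, hi = prof.fit.locations
        grid = np.linspace(lo, hi, 200)
        d = posterior_log_ratio(prof.fit, grid)
        assert (np.diff(d) >= -1e-12).all()

    def test_missing_scores_stay_missing(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(-4, 1, 80)])
        x[5] = np.nan
        prof = compute_2c_profile(x, seed=4)
        assert np.isnan(prof.d[5])
        assert np.isfinite(np.delete(prof.d, 5)).all()


class TestNormLrt:
    def test_gaussian_near_zero(self):
        x = np.random.default_rng(11).normal(0, 1, 769)
        assert norm_lrt(x) < 10

    def test_left_skewed_mixture_large(self):
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(0, 1, 692), rng.normal(-6, 1, 77)])
        assert norm_lrt(x) > 125

    def test_deterministic(self):
        x = np.random.default_rng(13).normal(0, 1, 100)
        assert norm_lrt(x, seed=1) == norm_lrt(x, seed=2)


class TestDependencyMatrix:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            DependencyMatrix(["a"], ["s1", "s2"], np.zeros((2, 2)))

    def test_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            DependencyMatrix(["a", "a"], ["s1"], np.zeros((2, 1)))
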