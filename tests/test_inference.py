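import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from runcompare import (
    BootstrapConfig,
    DiffMatrix,
    bootstrap_mean_test,
    cohens_d,
    distribution_diagnostics,
    effect_band,
    percentile_bootstrap_ci,
    run_weekly_inference,
    sidak_alpha,
)
from runcompare.weekly import N_WEEKS


def _diff_matrix(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    frame = pd.DataFrame(
        values,
        index=pd.Index(range(values.shape[0]), name="athlete"),
        columns=range(1, N_WEEKS + 1),
    )
    return DiffMatrix("distance", frame, baseline_mean=1.0)


def enumerate_resample_means(x):
    """Exhaustive n^n bootstrap distribution of the mean (oracle, n <= 5)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return np.array(
        [np.mean(pick) for pick in itertools.product(x, repeat=n)]
    )


class TestPercentileCI:
    def test_constant_sample_degenerates_to_point(self):
        lo, hi = percentile_bootstrap_ci(
            np.full(10, 3.7), BootstrapConfig(n_resamples=500, seed=1)
        )
        assert lo == hi == pytest.approx(3.7)

    def test_matches_exhaustive_enumeration(self):
        """MC quantiles approach the fully enumerated 27-resample law."""
        x = np.array([0.0, 1.0, 2.0])
        exact = enumerate_resample_means(x)
        lo_e, hi_e = np.quantile(exact, [0.025, 0.975])
        config = BootstrapConfig(n_resamples=50_000, seed=3)
        lo, hi = percentile_bootstrap_ci(x, config)
        # quantile SE of the enumerated law, ~3 sigma slack
        tol = 3 * exact.std() / np.sqrt(config.n_resamples) + np.diff(
            np.unique(exact)
        ).max()
        assert abs(lo - lo_e) < tol and abs(hi - hi_e) < tol

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(12)
        small = rng.normal(0, 1, 100)
        large = rng.normal(0, 1, 400)
        config = BootstrapConfig(n_resamples=4000, seed=5)
        w_small = np.diff(percentile_bootstrap_ci(small, config))[0]
        w_large = np.diff(percentile_bootstrap_ci(large, config))[0]
        assert w_large < w_small

    def test_sample_too_small_rejected(self):
        with pytest.raises(ValueError):
            percentile_bootstrap_ci(np.array([1.0]), BootstrapConfig(n_resamples=10))

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(0).normal(size=50)
        config = BootstrapConfig(n_resamples=2000, seed=42)
        assert percentile_bootstrap_ci(x, config) == percentile_bootstrap_ci(x, config)


class TestBootstrapMeanTest:
    def test_all_zero_sample_gives_p_one(self):
        config = BootstrapConfig(n_resamples=1000, seed=1)
        assert bootstrap_mean_test(np.zeros(10), config) == 1.0

    def test_exhaustive_oracle_unreachable_mean(self):
        """For {1,1,2} no centered resample mean reaches |4/3|: raw p = 0."""
        x = np.array([1.0, 1.0, 2.0])
        centered = x - x.mean()
        exact = enumerate_resample_means(centered)
        assert np.abs(exact).max() < abs(x.mean())
        config = BootstrapConfig(n_resamples=5000, seed=7, p_smoothing="raw_fraction")
        assert bootstrap_mean_test(x, config) == 0.0

    def test_add_one_smoothing_avoids_zero(self):
        x = np.array([1.0, 1.0, 2.0])
        config = BootstrapConfig(n_resamples=5000, seed=7, p_smoothing="add_one")
        assert bootstrap_mean_test(x, config) == pytest.approx(1 / 5001)

    def test_matches_exhaustive_fraction(self):
        """MC p approaches the enumerated achieved significance level."""
        x = np.array([-1.0, 0.5, 2.0, 1.5])
        centered = x - x.mean()
        exact = enumerate_resample_means(centered)
        p_exact = np.mean(np.abs(exact) >= abs(x.mean()))
        config = BootstrapConfig(
            n_resamples=40_000, seed=11, p_smoothing="raw_fraction"
        )
        p_mc = bootstrap_mean_test(x, config)
        se = np.sqrt(p_exact * (1 - p_exact) / config.n_resamples)
        assert abs(p_mc - p_exact) < 3 * se

    def test_null_p_values_approximately_uniform(self):
        """Under a zero-mean null the ASL is ~Uniform(0,1) (KS check)."""
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(300):
            x = rng.normal(0, 1, 40)
            config = BootstrapConfig(
                n_resamples=400,
                seed=int(rng.integers(2**31)),
                p_smoothing="raw_fraction",
            )
            pvals.append(bootstrap_mean_test(x, config))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_sample_warns(self, caplog):
        config = BootstrapConfig(n_resamples=100, seed=0, p_smoothing="raw_fraction")
        with caplog.at_level("WARNING"):
            p = bootstrap_mean_test(np.full(5, 2.0), config)
        assert p == 0.0
        assert "degenerate" in caplog.text


class TestEffectSize:
    def test_zero_mean_gives_zero_d(self):
        assert cohens_d(np.array([-1.0, 1.0])) == 0.0

    def test_direct_formula(self):
        x = np.random.default_rng(9).normal(2, 3, 10)
        expected = x.mean() / x.std(ddof=1)
        assert cohens_d(x) == pytest.approx(expected, abs=1e-12)

    @given(scale=st.floats(0.01, 1000.0))
    def test_scale_invariance(self, scale):
        x = np.array([0.3, -1.2, 2.4, 0.9, -0.6])
        assert cohens_d(scale * x) == pytest.approx(cohens_d(x), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.full(5, 1.0))

    @pytest.mark.parametrize(
        "d, label",
        [
            (0.005, "negligible"),
            (0.05, "very small"),
            (0.34, "small"),
            (-0.34, "small"),
            (0.5, "medium"),
            (0.9, "large"),
            (1.5, "very large"),
            (2.5, "huge"),
        ],
    )
    def test_effect_bands(self, d, label):
        assert effect_band(d) == label

    def test_non_finite_effect_rejected(self):
        with pytest.raises(ValueError):
            effect_band(float("nan"))


class TestSidak:
    def test_52_weeks_gives_one_per_mille(self):
        alpha = sidak_alpha(0.05, 52)
        assert alpha == pytest.approx(0.000986, abs=5e-7)
        assert round(alpha, 3) == 0.001

    def test_single_test_is_identity(self):
        assert sidak_alpha(0.05, 1) == pytest.approx(0.05)

    @given(alpha=st.floats(0.001, 0.2), m=st.integers(1, 500))
    def test_algebraic_inverse(self, alpha, m):
        per_test = sidak_alpha(alpha, m)
        assert 1 - (1 - per_test) ** m == pytest.approx(alpha, abs=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            sidak_alpha(0.05, 0)
        with pytest.raises(ValueError):
            sidak_alpha(1.5, 10)


class TestDiagnostics:
    def test_symmetric_sample_has_zero_skew(self):
        diag = distribution_diagnostics(np.array([-2.0, -1.0, 1.0, 2.0]))
        assert diag.skewness == pytest.approx(0.0, abs=1e-12)

    def test_zero_fraction(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        assert distribution_diagnostics(x).zero_fraction == 0.5

    def test_jarque_bera_matches_scipy(self):
        x = np.random.default_rng(31).standard_t(5, 500)
        diag = distribution_diagnostics(x)
        assert diag.jarque_bera == pytest.approx(stats.jarque_bera(x).statistic, rel=1e-9)

    def test_normal_draw_not_rejected(self):
        x = np.random.default_rng(33).standard_normal(2000)
        diag = distribution_diagnostics(x)
        # chi2(2) 95% critical value
        assert diag.jarque_bera < stats.chi2.ppf(0.95, 2)


class TestWeeklyInference:
    def test_all_zero_matrix_is_flat_and_nonsignificant(self):
        result = run_weekly_inference(
            _diff_matrix(np.zeros((6, N_WEEKS))), BootstrapConfig(n_resamples=200, seed=1)
        )
        assert (result["mean"] == 0).all()
        assert not result["significant"].any()
        assert len(result) == N_WEEKS

    def test_injected_effect_recovered_in_one_week(self):
        rng = np.random.default_rng(19)
        values = rng.normal(0, 1, (200, N_WEEKS))
        values[:, 29] += 10.0  # week 30
        result = run_weekly_inference(
            _diff_matrix(values), BootstrapConfig(n_resamples=3000, seed=2)
        )
        assert bool(result.loc[result["week"] == 30, "significant"].iloc[0])
        assert int(result["significant"].sum()) == 1

    def test_point_estimates_invariant_to_resample_count(self):
        rng = np.random.default_rng(4)
        values = rng.normal(1, 3, (50, N_WEEKS))
        small = run_weekly_inference(
            _diff_matrix(values), BootstrapConfig(n_resamples=100, seed=3)
        )
        large = run_weekly_inference(
            _diff_matrix(values), BootstrapConfig(n_resamples=2000, seed=3)
        )
        np.testing.assert_allclose(small["mean"], large["mean"], rtol=1e-12)
        np.testing.assert_allclose(small["cohens_d"], large["cohens_d"], rtol=1e-12)

    def test_degenerate_week_flagged_not_fatal(self):
        values = np.random.default_rng(5).normal(0, 1, (20, N_WEEKS))
        values[:, 10] = 7.0  # zero-variance week
        result = run_weekly_inference(
            _diff_matrix(values), BootstrapConfig(n_resamples=200, seed=1)
        )
        row = result.loc[result["week"] == 11].iloc[0]
        assert row["band"] == "undefined"
        assert not row["significant"]
        assert np.isnan(row["cohens_d"])
        assert len(result) == N_WEEKS

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0.5, 2, (120, N_WEEKS))
        result = run_weekly_inference(
            _diff_matrix(values), BootstrapConfig(n_resamples=1500, seed=8)
        )
        assert (result["ci_low"] <= result["mean"]).all()
        assert (result["mean"] <= result["ci_high"]).all()
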