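import numpy as np
import pytest
from scipy import linalg, stats
from statsmodels.tsa.stattools import kpss as sm_kpss

from searchsurge.arima import (
    ArimaOrder,
    DegenerateSeriesError,
    FitRejectedError,
    aicc,
    choose_d,
    difference,
    fit_arima,
    hk_stepwise_select,
    kpss_statistic,
    ljung_box,
    seasonal_strength,
)


class TestDifference:
    def test_first_difference_of_ramp(self):
        assert np.array_equal(difference([1, 2, 3, 4], d=1), [1, 1, 1])

    def test_seasonal_difference(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8]
        assert np.array_equal(difference(x, d=0, D=1, m=4), [4, 4, 4, 4])

    def test_identity_when_no_differencing(self):
        x = np.array([3.0, 1.0, 4.0])
        assert np.array_equal(difference(x), x)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            difference([1, 2], d=1, D=1, m=4)


class TestKpss:
    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            kpss_statistic(np.full(50, 5.0))

    def test_linear_ramp_rejects_stationarity(self):
        stat = kpss_statistic(np.arange(1.0, 201.0), lag_truncation=4)
        assert stat > 0.463

    def test_white_noise_accepts_stationarity(self):
        x = np.random.default_rng(3).normal(size=500)
        assert kpss_statistic(x) < 0.463

    def test_matches_statsmodels_at_same_truncation(self):
        x = np.random.default_rng(8).normal(size=200).cumsum()
        for lags in (4, 9):
            ours = kpss_statistic(x, lag_truncation=lags)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                theirs = sm_kpss(x, regression="c", nlags=lags)[0]
            assert ours == pytest.approx(theirs, rel=1e-10)


class TestChooseD:
    def test_stationary_ar1_needs_no_differencing(self, ar1_sample):
        assert choose_d(ar1_sample(0.5, 300, seed=1)) == 0

    def test_random_walk_needs_one_difference(self, ar1_sample):
        walk = np.cumsum(ar1_sample(0.0, 300, seed=1))
        assert choose_d(walk) == 1

    def test_ramp_plus_walk_differences_to_stationarity(self, ar1_sample):
        x = 0.5 * np.arange(300) + np.cumsum(ar1_sample(0.0, 300, seed=2))
        d = choose_d(x)
        assert d in (1, 2)
        assert kpss_statistic(difference(x, d=d)) < 0.463


class TestSeasonalStrength:
    def test_pure_sinusoid_is_fully_seasonal(self):
        t = np.arange(140)
        x = 10 + 4 * np.sin(2 * np.pi * t / 7)
        assert seasonal_strength(x, 7) >= 0.99

    def test_white_noise_is_weakly_seasonal(self):
        x = np.random.default_rng(5).normal(size=280)
        assert seasonal_strength(x, 7) < 0.2

    def test_constant_series_returns_zero(self):
        assert seasonal_strength(np.full(50, 3.0), 7) == 0.0


class TestAicc:
    def test_closed_form(self):
        assert aicc(-100.0, 3, 50) == pytest.approx(206 + 24 / 46)

    def test_model_too_big_is_infinite(self):
        assert aicc(-100.0, 49, 50) == np.inf

    def test_strictly_increasing_in_k(self):
        values = [aicc(-100.0, k, 50) for k in range(1, 10)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestFitArima:
    def test_white_noise_closed_form_mle(self):
        y = np.random.default_rng(7).normal(10, 2, 300)
        fit = fit_arima(y, ArimaOrder(0, 0, 0, include_constant=True))
        assert fit.constant == pytest.approx(y.mean(), abs=1e-6)
        assert fit.sigma2 == pytest.approx(y.var(), abs=1e-6)

    def test_ar1_recovers_coefficient_and_exact_likelihood(self, ar1_sample):
        y = ar1_sample(0.7, 500, seed=7, mean=5.0)
        fit = fit_arima(y, ArimaOrder(1, 0, 0, include_constant=True))
        phi = fit.ar[0]
        assert abs(phi - 0.7) < 0.1
        # brute-force oracle: stationary Gaussian AR(1) density with
        # mean = constant / (1 - phi) and Toeplitz autocovariance
        n = len(y)
        mean = fit.constant / (1 - phi)
        cov = fit.sigma2 / (1 - phi**2) * linalg.toeplitz(phi ** np.arange(n))
        brute = stats.multivariate_normal.logpdf(y, mean=np.full(n, mean), cov=cov)
        assert fit.loglik == pytest.approx(brute, abs=1e-4)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            fit_arima(np.full(60, 42.0), ArimaOrder(1, 0, 0))

    def test_residual_length_is_effective_sample(self, ar1_sample):
        y = np.cumsum(ar1_sample(0.3, 120, seed=4))
        fit = fit_arima(y, ArimaOrder(1, 1, 0, include_constant=True))
        assert fit.n_effective == len(y) - 1


class TestLjungBox:
    def test_zero_autocorrelation_gives_zero_q(self):
        # alternating 1,0,-1,0 has exactly zero lag-1 autocovariance
        x = np.tile([1.0, 0.0, -1.0, 0.0], 25)
        q, p = ljung_box(x, h=1)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic_and_chi_square_pvalue(self):
        # Q = n(n+2) r1^2/(n-1) evaluated for r1 found in the data
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        e = x - x.mean()
        r1 = (e[1:] @ e[:-1]) / (e @ e)
        q, p = ljung_box(x, h=1)
        assert q == pytest.approx(100 * 102 * r1**2 / 99, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(q, 1), rel=1e-12)
        # the worked constant: r1 = 0.3 at n = 100 gives Q = 9.27273
        assert 100 * 102 * 0.3**2 / 99 == pytest.approx(9.27273, abs=5e-6)

    def test_scale_invariance(self):
        x = np.random.default_rng(1).normal(size=200)
        q1, _ = ljung_box(x, h=5)
        q2, _ = ljung_box(17.3 * x, h=5)
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError, match="exceed"):
            ljung_box(np.random.default_rng(2).normal(size=50), h=2, fitted_params=2)


class TestStepwiseSelection:
    def test_white_noise_matches_exhaustive_search(self):
        y = np.random.default_rng(0).normal(0, 1, 300)
        best = hk_stepwise_select(y, m=1)
        assert best.order.p + best.order.q <= 1
        # exhaustive oracle over p,q <= 2 with and without a constant
        exhaustive = np.inf
        for p in range(3):
            for q in range(3):
                for const in (True, False):
                    try:
                        fit = fit_arima(y, ArimaOrder(p, 0, q, include_constant=const))
                    except (FitRejectedError, DegenerateSeriesError):
                        continue
                    exhaustive = min(exhaustive, fit.aicc)
        assert best.aicc == pytest.approx(exhaustive, abs=1e-6)

    def test_ar1_sample_selects_autoregression(self, ar1_sample):
        y = ar1_sample(0.8, 500, seed=13)
        best = hk_stepwise_select(y, m=1)
        assert best.order.p >= 1
        null_fit = fit_arima(y, ArimaOrder(0, best.order.d, 0, include_constant=True))
        assert best.aicc <= null_fit.aicc

    def test_strong_weekly_cycle_selects_seasonal_difference(self):
        rng = np.random.default_rng(17)
        t = np.arange(140)
        y = 50 + 10 * np.sin(2 * np.pi * t / 7) + rng.normal(0, 1.5, 140)
        best = hk_stepwise_select(y, m=7)
        assert best.order.D == 1

    def test_never_worse_than_any_evaluated_candidate(self, null_series):
        y = null_series(seed=3).values[:91]
        trace = []
        best = hk_stepwise_select(y, m=7, trace=trace)
        evaluated = [a for _, a in trace if np.isfinite(a)]
        assert best.aicc == pytest.approx(min(evaluated))


def test_ar1_estimate_consistency_improves_with_n(ar1_sample):
    """Median |phi_hat - phi| shrinks as the sample grows (consistency)."""
    errs = {}
    for n in (100, 1000):
        errors = []
        for seed in range(20):
            y = ar1_sample(0.6, n, seed=seed)
            fit = fit_arima(y, ArimaOrder(1, 0, 0, include_constant=False))
            errors.append(abs(fit.ar[0] - 0.6))
        errs[n] = np.median(errors)
    assert errs[1000] < errs[100]
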