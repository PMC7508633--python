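import dataclasses

import numpy as np
import pytest

from searchsurge.arima import ArimaOrder, FittedArima, fit_arima
from searchsurge.forecast import forecast_bootstrap, forecast_gaussian, psi_weights


def make_fitted(order, ar=(), ma=(), sar=(), sma=(), sigma2=1.0):
    """A coefficient-only FittedArima for closed-form weight checks."""
    return FittedArima(
        order=order,
        ar=np.array(ar, dtype=float),
        ma=np.array(ma, dtype=float),
        sar=np.array(sar, dtype=float),
        sma=np.array(sma, dtype=float),
        constant=0.0,
        sigma2=sigma2,
        loglik=0.0,
        aicc=0.0,
        residuals=np.zeros(20),
        n=20,
    )


class TestPsiWeights:
    def test_ma1_weights_truncate(self):
        f = make_fitted(ArimaOrder(0, 0, 1), ma=[0.4])
        assert np.allclose(psi_weights(f, 3), [1.0, 0.4, 0.0])

    def test_ar1_weights_are_geometric(self):
        f = make_fitted(ArimaOrder(1, 0, 0, include_constant=False), ar=[0.5])
        assert np.allclose(psi_weights(f, 3), [1.0, 0.5, 0.25])

    def test_random_walk_weights_cumulate(self):
        f = make_fitted(ArimaOrder(0, 1, 0, include_constant=False))
        assert np.allclose(psi_weights(f, 3), [1.0, 1.0, 1.0])

    def test_seasonal_ar_appears_at_multiples_of_m(self):
        f = make_fitted(
            ArimaOrder(0, 0, 0, P=1, D=0, Q=0, m=7, include_constant=False), sar=[0.6]
        )
        psi = psi_weights(f, 15)
        expected = np.zeros(15)
        expected[[0, 7, 14]] = [1.0, 0.6, 0.36]
        assert np.allclose(psi, expected)

    def test_ar1_se_closed_form(self):
        f = make_fitted(ArimaOrder(1, 0, 0, include_constant=False), ar=[0.5])
        psi = psi_weights(f, 2)
        se2 = np.sqrt(f.sigma2 * np.cumsum(psi**2))[1]
        assert se2 == pytest.approx(np.sqrt(1.25))


@pytest.fixture(scope="module")
def white_noise_fit():
    # large sample: the residual pool's own tail quantile must sit close to
    # the Gaussian one for the bootstrap-convergence check
    y = np.random.default_rng(19).normal(30, 3, 10_000)
    return fit_arima(y, ArimaOrder(0, 0, 0, include_constant=True))


class TestGaussianBand:
    def test_white_noise_band_closed_form(self, white_noise_fit):
        f = white_noise_fit
        band = forecast_gaussian(f, 5)
        assert np.allclose(band.point, f.constant)
        assert np.allclose(band.se, np.sqrt(f.sigma2))
        assert np.allclose(band.upper - band.point, 1.645 * np.sqrt(f.sigma2))

    def test_zero_z_collapses_to_point(self, white_noise_fit):
        band = forecast_gaussian(white_noise_fit, 4, z=0.0)
        assert np.allclose(band.upper, band.point)

    def test_variance_additivity(self, ar1_sample):
        y = ar1_sample(0.6, 300, seed=23, mean=10)
        fit = fit_arima(y, ArimaOrder(1, 0, 1, include_constant=True))
        band = forecast_gaussian(fit, 10)
        psi = psi_weights(fit, 10)
        increments = band.se[1:] ** 2 - band.se[:-1] ** 2
        assert np.allclose(increments, fit.sigma2 * psi[1:] ** 2, atol=1e-10)

    def test_se_nondecreasing_for_stationary_model(self, ar1_sample):
        y = ar1_sample(0.5, 200, seed=2)
        fit = fit_arima(y, ArimaOrder(1, 0, 0, include_constant=True))
        band = forecast_gaussian(fit, 12)
        assert np.all(np.diff(band.se) >= -1e-12)

    def test_nonpositive_horizon_rejected(self, white_noise_fit):
        with pytest.raises(ValueError):
            forecast_gaussian(white_noise_fit, 0)

    def test_integrated_forecast_continues_the_level(self, ar1_sample):
        """ARIMA(0,1,0) without drift forecasts the last observed value."""
        y = np.cumsum(ar1_sample(0.0, 150, seed=5))
        fit = fit_arima(y, ArimaOrder(0, 1, 0, include_constant=False))
        band = forecast_gaussian(fit, 6)
        assert np.allclose(band.point, y[-1])
        assert np.allclose(band.se, np.sqrt(fit.sigma2 * np.arange(1, 7)))


class TestBootstrapBand:
    def test_degenerate_residuals_collapse_to_point(self, white_noise_fit):
        f = dataclasses.replace(white_noise_fit, residuals=np.zeros(100))
        band = forecast_bootstrap(f, 5, B=200, seed=0)
        assert np.allclose(band.upper, band.point)

    def test_converges_to_gaussian_for_gaussian_residuals(self, white_noise_fit):
        gauss = forecast_gaussian(white_noise_fit, 5)
        boot = forecast_bootstrap(white_noise_fit, 5, B=5000, seed=42)
        assert np.max(np.abs(boot.upper - gauss.upper)) < 0.1 * gauss.se[0]

    def test_seed_determinism(self, white_noise_fit):
        a = forecast_bootstrap(white_noise_fit, 5, B=300, seed=9)
        b = forecast_bootstrap(white_noise_fit, 5, B=300, seed=9)
        c = forecast_bootstrap(white_noise_fit, 5, B=300, seed=10)
        assert np.array_equal(a.upper, b.upper)
        assert not np.array_equal(a.upper, c.upper)

    def test_small_b_rejected(self, white_noise_fit):
        with pytest.raises(ValueError, match="B >= 100"):
            forecast_bootstrap(white_noise_fit, 5, B=50, seed=0)
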