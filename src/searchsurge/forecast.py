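"""Counterfactual forecasts with one-sided upper bounds.

The forecast says what search interest would have looked like had the
baseline-period process simply continued.  Per-horizon uncertainty comes
either from the Gaussian closed form — ``se(h) = sqrt(sigma2 * sum_{j<h}
psi_j^2)`` with the psi-weights of the model's infinite moving-average
representation — or from residual-bootstrap sample paths.  Parameter
uncertainty is not propagated, matching standard ARIMA forecasting
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arima import FittedArima

__all__ = ["ForecastBand", "psi_weights", "forecast_gaussian", "forecast_bootstrap"]

#: One-sided 95% normal quantile as conventionally printed.
DEFAULT_Z = 1.645


@dataclass
class ForecastBand:
    """Point forecasts with per-horizon standard errors and upper bounds."""

    point: np.ndarray
    se: np.ndarray
    upper: np.ndarray
    method: str  # "gaussian" | "bootstrap"
    z: float = DEFAULT_Z
    level: float = 0.95

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.point) == len(self.se) == len(self.upper)):
            raise ValueError("point/se/upper length mismatch")

    @property
    def horizons(self) -> np.ndarray:
        return np.arange(1, len(self.point) + 1)

    def __len__(self) -> int:
        return len(self.point)


def _poly_from_lags(coefs: np.ndarray, lag: int) -> np.ndarray:
    """(1 - c1 B^lag - c2 B^2lag - ...) as a dense lag polynomial."""
    out = np.zeros(len(coefs) * lag + 1)
    out[0] = 1.0
    for i, c in enumerate(coefs, start=1):
        out[i * lag] = -c
    return out


def psi_weights(fitted: FittedArima, h: int) -> np.ndarray:
    """First ``h`` coefficients of the integrated MA(inf) representation.

    The full AR side multiplies the non-seasonal and seasonal AR polynomials
    with the differencing operators ``(1-B)^d (1-B^m)^D``; the MA side
    multiplies the two MA polynomials.  ``psi_0 = 1`` always.
    """
    o = fitted.order
    ar_poly = _poly_from_lags(fitted.ar, 1)
    ar_poly = np.convolve(ar_poly, _poly_from_lags(fitted.sar, o.m))
    for _ in range(o.d):
        ar_poly = np.convolve(ar_poly, [1.0, -1.0])
    for _ in range(o.D):
        ar_poly = np.convolve(ar_poly, _poly_from_lags(np.array([1.0]), o.m))
    ma_poly = np.convolve(_poly_from_lags(-fitted.ma, 1), _poly_from_lags(-fitted.sma, o.m))
    phi = -ar_poly[1:]  # ar_poly = 1 - phi_1 B - phi_2 B^2 - ...
    psi = np.zeros(h)
    psi[0] = 1.0
    for j in range(1, h):
        acc = ma_poly[j] if j < len(ma_poly) else 0.0
        kmax = min(j, len(phi))
        for i in range(1, kmax + 1):
            acc += phi[i - 1] * psi[j - i]
        psi[j] = acc
    return psi


def _invert_diff(forecasts: np.ndarray, history: np.ndarray, lag: int) -> np.ndarray:
    """Undo one differencing step: out[t] = forecasts[t] + (history+out)[t-lag]."""
    ext = list(history[-lag:]) if lag <= len(history) else list(history)
    out = []
    for value in forecasts:
        nxt = value + ext[-lag]
        ext.append(nxt)
        out.append(nxt)
    return np.asarray(out)


def _point_forecast(fitted: FittedArima, h: int) -> np.ndarray:
    """Conditional-mean forecasts on the original (undifferenced) scale."""
    if fitted._sm_results is None:
        raise ValueError("this FittedArima carries no fitted state; refit to forecast")
    o = fitted.order
    w_fc = np.asarray(fitted._sm_results.forecast(h), dtype=float)
    # invert seasonal differencing first, then the ordinary differences
    from .arima import difference

    fc = w_fc
    for j in range(o.D, 0, -1):
        hist = difference(fitted.values, d=o.d, D=j - 1, m=o.m)
        fc = _invert_diff(fc, hist, o.m)
    for j in range(o.d, 0, -1):
        hist = difference(fitted.values, d=j - 1, D=0, m=o.m)
        fc = _invert_diff(fc, hist, 1)
    return fc


def forecast_gaussian(
    fitted: FittedArima, h: int, z: float = DEFAULT_Z, level: float = 0.95
) -> ForecastBand:
    """Gaussian forecast band: ``upper = point + z * se``.

    ``se(h) = sqrt(sigma2 * sum_{j<h} psi_j^2)`` accumulates innovation
    variance through the psi-weights; with ``z = 1.645`` the upper bound is
    the one-tailed 95% limit.
    """
    if h <= 0:
        raise ValueError("forecast horizon must be positive")
    point = _point_forecast(fitted, h)
    psi = psi_weights(fitted, h)
    se = np.sqrt(fitted.sigma2 * np.cumsum(psi**2))
    return ForecastBand(point=point, se=se, upper=point + z * se, method="gaussian", z=z, level=level)


def forecast_bootstrap(
    fitted: FittedArima,
    h: int,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> ForecastBand:
    """Residual-bootstrap forecast band.

    Simulates ``B`` future paths by adding psi-weighted draws (i.i.d. with
    replacement from the centred residuals) to the conditional mean —
    exactly the model's linear forecast-error recursion.  The point forecast
    is the per-horizon mean of paths and the upper bound the per-horizon
    empirical ``level`` quantile (type-7 interpolation).  Deterministic
    given ``seed``.
    """
    if h <= 0:
        raise ValueError("forecast horizon must be positive")
    if B < 100:
        raise ValueError("B < 100 gives too unstable a quantile; use B >= 100")
    resid = np.asarray(fitted.residuals, dtype=float)
    if resid.size == 0:
        raise ValueError("fitted model has no residuals to resample")
    centred = resid - resid.mean()
    rng = np.random.default_rng(seed)
    eps = rng.choice(centred, size=(B, h), replace=True)
    psi = psi_weights(fitted, h)
    shocks = np.zeros((B, h))
    for t in range(h):
        shocks[:, t] = eps[:, : t + 1] @ psi[: t + 1][::-1]
    paths = _point_forecast(fitted, h)[None, :] + shocks
    point = paths.mean(axis=0)
    se = paths.std(axis=0, ddof=1)
    upper = np.quantile(paths, level, axis=0)  # linear interpolation = type 7
    return ForecastBand(point=point, se=se, upper=upper, method="bootstrap", z=np.nan, level=level)
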