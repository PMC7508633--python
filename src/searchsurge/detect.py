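"""Exceedance-day detection against a counterfactual forecast.

A day in the evaluation window is an *exceedance day* when the observed
relative search volume strictly exceeds the one-tailed 95% upper forecast
bound (expected + 1.645·SE under the Gaussian method).  The per-series
statistic is simply the count of such days.  No multiple-testing correction
is applied across days: the statistic deliberately counts marginal
one-tailed exceedances, so under the null it has mean ≈ 0.05 × horizon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, column_or_1d

from .arima import default_ljung_box_lags, hk_stepwise_select, ljung_box
from .forecast import DEFAULT_Z, ForecastBand, forecast_bootstrap, forecast_gaussian
from .io import TrendSeries, WindowSpec

__all__ = ["DetectionConfig", "ExceedanceResult", "flag_days", "ArimaExceedanceDetector", "run_country"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """How observed days are compared with the forecast band."""

    z: float = DEFAULT_Z
    level: float = 0.95
    method: str = "gaussian"  # or "bootstrap"
    strict: bool = True  # flag only on strict exceedance of the bound
    bootstrap_B: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")
        if not 0.5 < self.level < 1:
            raise ValueError("level must lie in (0.5, 1)")
        if self.method not in ("gaussian", "bootstrap"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ExceedanceResult:
    """Per-day exceedance flags and the day-count statistic for one series."""

    country: str
    keyword: str
    flags: np.ndarray
    window: WindowSpec | None = None
    band: ForecastBand | None = field(default=None, repr=False)
    observed: np.ndarray | None = field(default=None, repr=False)
    metadata: dict = field(default_factory=dict)

    @property
    def n_days(self) -> int:
        return int(np.sum(self.flags))


def flag_days(
    observed: np.ndarray,
    band: ForecastBand,
    config: DetectionConfig = DetectionConfig(),
    country: str = "",
    keyword: str = "",
    window: WindowSpec | None = None,
) -> ExceedanceResult:
    """Flag evaluation days whose observed value exceeds the upper bound."""
    obs = np.asarray(observed, dtype=float)
    if len(obs) != len(band):
        raise ValueError(f"observed has {len(obs)} days but the band covers {len(band)}")
    flags = obs > band.upper if config.strict else obs >= band.upper
    return ExceedanceResult(
        country=country,
        keyword=keyword,
        flags=flags,
        window=window,
        band=band,
        observed=obs,
    )


class ArimaExceedanceDetector(BaseEstimator):
    """Counterfactual-forecast exceedance detector.

    ``fit`` selects and estimates a seasonal ARIMA on the baseline series
    via the stepwise AICc search; ``predict`` forecasts over the evaluation
    window and returns a boolean flag per day (True where the observed
    value exceeds the one-tailed upper bound).

    Parameters
    ----------
    seasonal_period : int
        Seasonal period of the baseline model; 7 captures the weekly cycle
        of daily search data, 1 disables seasonal terms.
    z : float
        One-sided normal multiplier for the Gaussian bound (1.645 ≙ 95%).
    level : float
        One-sided coverage of the bound (used by the bootstrap method).
    method : {"gaussian", "bootstrap"}
        Forecast-uncertainty method.
    strict : bool
        Require strict inequality for a flag (ties at the bound never flag).
    max_p, max_q, max_P, max_Q, max_d, max_D : int
        Order-search bounds for the stepwise selection.
    bootstrap_B : int
        Number of bootstrap sample paths (bootstrap method only).
    random_state : int or None
        Seed for the bootstrap innovations.

    Attributes
    ----------
    model_ : FittedArima
        The selected and fitted baseline model.
    ljung_box_ : tuple (Q, p)
        Residual portmanteau diagnostic at the default lag count.
    """

    def __init__(
        self,
        seasonal_period: int = 7,
        z: float = DEFAULT_Z,
        level: float = 0.95,
        method: str = "gaussian",
        strict: bool = True,
        max_p: int = 5,
        max_q: int = 5,
        max_P: int = 2,
        max_Q: int = 2,
        max_d: int = 2,
        max_D: int = 1,
        bootstrap_B: int = 1000,
        random_state: int | None = None,
    ):
        self.seasonal_period = seasonal_period
        self.z = z
        self.level = level
        self.method = method
        self.strict = strict
        self.max_p = max_p
        self.max_q = max_q
        self.max_P = max_P
        self.max_Q = max_Q
        self.max_d = max_d
        self.max_D = max_D
        self.bootstrap_B = bootstrap_B
        self.random_state = random_state

    # -- estimator API ------------------------------------------------

    def fit(self, y, X=None):
        """Select and fit the baseline model on the 1-d series ``y``."""
        y = column_or_1d(y)
        if self.method not in ("gaussian", "bootstrap"):
            raise ValueError(f"unknown method {self.method!r}")
        self.model_ = hk_stepwise_select(
            y,
            m=self.seasonal_period,
            max_p=self.max_p,
            max_q=self.max_q,
            max_P=self.max_P,
            max_Q=self.max_Q,
            max_d=self.max_d,
            max_D=self.max_D,
        )
        o = self.model_.order
        n_eff = self.model_.n_effective
        fitted_params = o.p + o.q + o.P + o.Q
        h = default_ljung_box_lags(n_eff, self.seasonal_period)
        if h > fitted_params and n_eff > h:
            self.ljung_box_ = ljung_box(self.model_.residuals, h, fitted_params)
            if self.ljung_box_[1] < 0.05:
                warnings.warn(
                    f"Ljung-Box rejects white-noise residuals for {o} "
                    f"(Q={self.ljung_box_[0]:.2f}, p={self.ljung_box_[1]:.3f})",
                    UserWarning,
                )
        else:
            self.ljung_box_ = (np.nan, np.nan)
        return self

    def forecast(self, h: int) -> ForecastBand:
        """Counterfactual band for the next ``h`` days after the baseline."""
        check_is_fitted(self, "model_")
        if self.method == "bootstrap":
            return forecast_bootstrap(
                self.model_, h, B=self.bootstrap_B, seed=self.random_state, level=self.level
            )
        return forecast_gaussian(self.model_, h, z=self.z, level=self.level)

    def decision_function(self, y_observed) -> np.ndarray:
        """Signed margin observed − upper bound (positive ⇒ exceedance)."""
        y_observed = column_or_1d(y_observed)
        band = self.forecast(len(y_observed))
        return y_observed - band.upper

    def predict(self, y_observed) -> np.ndarray:
        """Boolean exceedance flag per observed evaluation day."""
        margin = self.decision_function(y_observed)
        return margin > 0 if self.strict else margin >= 0

    def exceedance_count(self, y_observed) -> int:
        """The day-count statistic: number of flagged evaluation days."""
        return int(self.predict(y_observed).sum())


def run_country(
    series: TrendSeries,
    window: WindowSpec = WindowSpec(),
    detection: DetectionConfig = DetectionConfig(),
    seasonal_period: int = 7,
    **selection_bounds,
) -> ExceedanceResult:
    """End-to-end detection for one series: fit on the baseline only,
    forecast the evaluation window, flag exceedance days.

    The model is fit once on the baseline slice and never refit inside the
    evaluation window — the forecast is a pure counterfactual.
    """
    baseline = series.baseline(window)
    observed = series.evaluation(window)
    detector = ArimaExceedanceDetector(
        seasonal_period=seasonal_period,
        z=detection.z,
        level=detection.level,
        method=detection.method,
        strict=detection.strict,
        bootstrap_B=detection.bootstrap_B,
        random_state=detection.seed,
        **selection_bounds,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", UserWarning)
        detector.fit(baseline)
    band = detector.forecast(len(observed))
    result = flag_days(
        observed,
        band,
        detection,
        country=series.country,
        keyword=series.keyword,
        window=window,
    )
    lb_q, lb_p = detector.ljung_box_
    result.metadata = {
        "order": str(detector.model_.order),
        "aicc": detector.model_.aicc,
        "ljung_box_Q": lb_q,
        "ljung_box_p": lb_p,
        "ljung_box_rejected": bool(lb_p < 0.05) if np.isfinite(lb_p) else False,
        "warnings": [str(w.message) for w in caught],
    }
    logger.info(
        "%s/%s: order=%s n_days=%d LB p=%.3f",
        series.country,
        series.keyword,
        result.metadata["order"],
        result.n_days,
        lb_p if np.isfinite(lb_p) else float("nan"),
    )
    return result
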