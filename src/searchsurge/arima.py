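"""Seasonal ARIMA estimation with automatic order selection.

Order selection follows the Hyndman–Khandakar stepwise scheme: the ordinary
differencing order ``d`` comes from repeated KPSS level-stationarity tests,
the seasonal differencing order ``D`` from a seasonal-strength heuristic,
and the ARMA orders from a hill-climbing search over AICc starting from four
standard candidate models.  The Gaussian likelihood of each candidate
``(p,d,q)(P,D,Q)_m`` model is evaluated exactly on the differenced series by
a state-space routine (statsmodels SARIMAX); everything around that inner
evaluation — differencing decisions, the AICc search, validity guards,
residual diagnostics — lives here.

Fits whose AR or MA characteristic roots come within 0.1% of the unit
circle are rejected: such near-unit roots produce numerically unstable
forecast variances and signal an over-differenced or over-parameterised
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.statespace.sarimax import SARIMAX

__all__ = [
    "ArimaOrder",
    "FittedArima",
    "ArimaError",
    "DegenerateSeriesError",
    "FitRejectedError",
    "difference",
    "kpss_statistic",
    "choose_d",
    "seasonal_strength",
    "fit_arima",
    "aicc",
    "ljung_box",
    "default_ljung_box_lags",
    "hk_stepwise_select",
]

#: KPSS level-stationarity critical values (Bartlett kernel).
KPSS_CRITICAL = {0.10: 0.347, 0.05: 0.463, 0.025: 0.574, 0.01: 0.739}

#: Seasonal differencing is applied when seasonal strength exceeds this.
SEASONAL_STRENGTH_THRESHOLD = 0.64

#: Characteristic roots must have modulus strictly above this.
UNIT_ROOT_GUARD = 1.001


class ArimaError(RuntimeError):
    """Base class for estimation failures."""


class DegenerateSeriesError(ArimaError):
    """The input series carries no usable variation."""


class FitRejectedError(ArimaError):
    """The optimiser failed or the fit violated a validity invariant."""


@dataclass(frozen=True)
class ArimaOrder:
    """Orders of a seasonal ARIMA ``(p,d,q)(P,D,Q)_m`` model.

    ``m=1`` means non-seasonal (seasonal orders must then be zero).  A
    constant term is only allowed when the total differencing ``d+D <= 1``.
    The constant is the intercept of the ARMA equation — the process mean
    times ``(1 - sum of AR coefficients)`` — a drift when ``d+D == 1``.
    """

    p: int = 0
    d: int = 0
    q: int = 0
    P: int = 0
    D: int = 0
    Q: int = 0
    m: int = 1
    include_constant: bool = True

    def __post_init__(self) -> None:
        for name, bound in (("p", 5), ("q", 5), ("d", 2), ("P", 2), ("Q", 2), ("D", 1)):
            v = getattr(self, name)
            if not 0 <= v <= bound:
                raise ValueError(f"{name}={v} outside [0, {bound}]")
        if self.m < 1:
            raise ValueError("seasonal period m must be >= 1")
        if self.m == 1 and (self.P or self.D or self.Q):
            raise ValueError("seasonal orders require m > 1")
        if self.d + self.D >= 2 and self.include_constant:
            raise ValueError("constant not identifiable with d+D >= 2")

    @property
    def k_params(self) -> int:
        """Number of estimated parameters including the innovation variance."""
        return self.p + self.q + self.P + self.Q + int(self.include_constant) + 1

    def __str__(self) -> str:
        s = f"({self.p},{self.d},{self.q})"
        if self.m > 1:
            s += f"({self.P},{self.D},{self.Q})[{self.m}]"
        if self.include_constant:
            s += "+c"
        return s


@dataclass
class FittedArima:
    """A fitted seasonal ARIMA model.

    ``residuals`` are one-step-ahead innovations of the differenced series
    (length ``n_effective = n - d - D*m``); ``loglik`` is the exact Gaussian
    log-likelihood of the differenced series at the optimum.
    """

    order: ArimaOrder
    ar: np.ndarray
    ma: np.ndarray
    sar: np.ndarray
    sma: np.ndarray
    constant: float
    sigma2: float
    loglik: float
    aicc: float
    residuals: np.ndarray = field(repr=False)
    n: int
    values: np.ndarray = field(repr=False, default=None)
    _sm_results: Any = field(repr=False, default=None, compare=False)

    @property
    def n_effective(self) -> int:
        return len(self.residuals)


def difference(values: np.ndarray, d: int = 0, D: int = 0, m: int = 1) -> np.ndarray:
    """Apply ordinary differencing ``d`` times then seasonal (lag m) ``D`` times."""
    x = np.asarray(values, dtype=float)
    if len(x) <= d + D * m:
        raise ValueError(f"series of length {len(x)} too short for d={d}, D={D}, m={m}")
    for _ in range(d):
        x = np.diff(x)
    for _ in range(D):
        x = x[m:] - x[:-m]
    return x


def kpss_statistic(values: np.ndarray, lag_truncation: int | None = None) -> float:
    """KPSS level-stationarity statistic with Bartlett-window long-run variance.

    eta = n^-2 * sum(S_t^2) / s^2(l) with S_t the partial sums of the demeaned
    series and l the lag truncation (default trunc(3*sqrt(n)/13)).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("KPSS needs at least 10 observations")
    e = x - x.mean()
    if np.allclose(e, 0.0):
        raise DegenerateSeriesError("KPSS undefined for a constant series")
    if lag_truncation is None:
        lag_truncation = int(3 * np.sqrt(n) / 13)
    s2 = e @ e / n
    for j in range(1, lag_truncation + 1):
        w = 1.0 - j / (lag_truncation + 1)
        s2 += 2.0 * w * (e[j:] @ e[:-j]) / n
    partial = np.cumsum(e)
    return float(partial @ partial / (n**2 * s2))


def choose_d(values: np.ndarray, max_d: int = 2, alpha: float = 0.05) -> int:
    """Smallest differencing order whose KPSS test accepts level stationarity.

    Returns ``max_d`` when every order up to it still rejects.  A series
    that becomes exactly constant raises :class:`DegenerateSeriesError`.
    """
    try:
        crit = KPSS_CRITICAL[alpha]
    except KeyError:
        raise ValueError(f"no KPSS critical value tabulated for alpha={alpha}")
    for d in range(max_d + 1):
        if kpss_statistic(difference(values, d=d)) < crit:
            return d
    return max_d


def seasonal_strength(values: np.ndarray, m: int) -> float:
    """Strength of the period-``m`` component, in [0, 1].

    Classical additive decomposition: trend by a centred moving average of
    window ``m`` (``m+1`` with half-weights at the ends when m is even),
    seasonal by centred periodic means of the detrended series.  Strength is
    ``max(0, 1 - Var(remainder) / Var(seasonal + remainder))``; a constant
    series returns 0 by convention.
    """
    x = np.asarray(values, dtype=float)
    if m < 2:
        raise ValueError("seasonal strength needs m >= 2")
    if len(x) < 2 * m:
        raise ValueError(f"need at least 2*m={2 * m} observations")
    if np.allclose(x, x[0]):
        return 0.0
    if m % 2:
        weights = np.full(m, 1.0 / m)
    else:
        weights = np.r_[0.5, np.ones(m - 1), 0.5] / m
    trend = np.convolve(x, weights, mode="valid")
    half = (len(weights) - 1) // 2
    detrended = x[half : half + len(trend)] - trend
    phases = (np.arange(len(x)) % m)[half : half + len(trend)]
    seasonal_means = np.array(
        [detrended[phases == ph].mean() for ph in range(m)]
    )
    seasonal_means -= seasonal_means.mean()
    seasonal = seasonal_means[phases]
    remainder = detrended - seasonal
    total = np.var(seasonal + remainder)
    if total == 0:
        return 0.0
    return float(max(0.0, 1.0 - np.var(remainder) / total))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2*loglik + 2k + 2k(k+1)/(n-k-1)``.

    Returns ``+inf`` when ``n <= k+1`` (model too large for the sample).
    """
    if n <= k + 1:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _check_roots(coefs: np.ndarray, what: str) -> None:
    """Reject characteristic roots at or inside modulus UNIT_ROOT_GUARD."""
    if len(coefs) == 0:
        return
    poly = np.r_[1.0, -np.asarray(coefs)]  # 1 - c1 z - c2 z^2 - ...
    roots = np.roots(poly[::-1])
    if len(roots) and np.abs(roots).min() <= UNIT_ROOT_GUARD:
        raise FitRejectedError(f"near-unit {what} root (modulus <= {UNIT_ROOT_GUARD})")


def fit_arima(
    values: np.ndarray,
    order: ArimaOrder,
    maxiter: int = 500,
    tol: float = 1e-8,
) -> FittedArima:
    """Gaussian maximum-likelihood fit of a seasonal ARIMA model.

    Raises :class:`FitRejectedError` on non-convergence or near-unit
    characteristic roots, and :class:`DegenerateSeriesError` when the
    (differenced) series has no variation to model.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    min_n = order.k_params + order.d + order.D * order.m + 4
    if n <= min_n:
        raise ValueError(f"series of length {n} too short for order {order} (need > {min_n})")
    w = difference(y, order.d, order.D, order.m)
    if np.allclose(w, w[0]) and (order.p + order.q + order.P + order.Q) > 0:
        raise DegenerateSeriesError("differenced series is constant; ARMA fit undefined")
    seasonal = (order.P, order.D, order.Q, order.m) if order.m > 1 else (0, 0, 0, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            y,
            order=(order.p, order.d, order.q),
            seasonal_order=seasonal,
            trend="c" if order.include_constant else "n",
            simple_differencing=True,
            concentrate_scale=True,  # profile sigma2 out: same MLE, fewer free params
        )
        try:
            if model.k_params == 0:
                # no free parameters (scale is concentrated): pure filter pass
                res = model.filter(np.zeros(0))
            else:
                res = model.fit(disp=0, method="lbfgs", maxiter=maxiter, pgtol=tol)
                if not res.mle_retvals.get("converged", False):
                    # lbfgs occasionally aborts its line search with the
                    # gradient already tiny; polish with plain BFGS before
                    # declaring failure
                    res = model.fit(
                        start_params=res.params, disp=0, method="bfgs", maxiter=maxiter
                    )
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise FitRejectedError(f"optimiser failed for {order}: {exc}") from exc
    if model.k_params > 0 and not res.mle_retvals.get("converged", False):
        raise FitRejectedError(f"no convergence within {maxiter} iterations for {order}")
    params = dict(zip(res.param_names, np.asarray(res.params, dtype=float)))
    ar = np.array([params[f"ar.L{i}"] for i in range(1, order.p + 1)])
    ma = np.array([params[f"ma.L{i}"] for i in range(1, order.q + 1)])
    sar = np.array([params[f"ar.S.L{i * order.m}"] for i in range(1, order.P + 1)])
    sma = np.array([params[f"ma.S.L{i * order.m}"] for i in range(1, order.Q + 1)])
    _check_roots(ar, "AR")
    _check_roots(sar, "seasonal-AR")
    _check_roots(-ma, "MA")  # invertibility: roots of 1 + t1 z + ...
    _check_roots(-sma, "seasonal-MA")
    sigma2 = float(res.scale)
    if not np.isfinite(sigma2) or sigma2 < 0:
        raise FitRejectedError(f"invalid innovation variance {sigma2}")
    residuals = np.asarray(res.resid, dtype=float)
    n_eff = len(residuals)
    loglik = float(res.llf)
    return FittedArima(
        order=order,
        ar=ar,
        ma=ma,
        sar=sar,
        sma=sma,
        constant=float(params.get("intercept", 0.0)),
        sigma2=float(sigma2),
        loglik=loglik,
        aicc=aicc(loglik, order.k_params, n_eff),
        residuals=residuals,
        n=n,
        values=y,
        _sm_results=res,
    )


def default_ljung_box_lags(n: int, m: int = 1) -> int:
    """Portmanteau lag count: min(10, n/5) non-seasonal, min(2m, n/5) seasonal."""
    return min(10, n // 5) if m == 1 else min(2 * m, n // 5)


def ljung_box(residuals: np.ndarray, h: int, fitted_params: int = 0) -> tuple[float, float]:
    """Ljung–Box portmanteau test of residual autocorrelation up to lag ``h``.

    Returns ``(Q, p)`` with ``Q = n(n+2) sum_k r_k^2/(n-k)`` and the p-value
    from chi-square with ``h - fitted_params`` degrees of freedom.
    """
    x = np.asarray(residuals, dtype=float)
    if h <= fitted_params:
        raise ValueError(f"h={h} must exceed the {fitted_params} fitted parameters")
    if len(x) <= h:
        raise ValueError(f"need more than h={h} residuals, got {len(x)}")
    table = acorr_ljungbox(x, lags=[h], model_df=fitted_params)
    q = float(table["lb_stat"].iloc[0])
    p = float(stats.chi2.sf(q, h - fitted_params))
    return q, p


# ---------------------------------------------------------------------------
# stepwise order selection


def _candidate_orders(d: int, D: int, m: int, constant_ok: bool) -> list[ArimaOrder]:
    pairs = [((2, 2), (1, 1)), ((0, 0), (0, 0)), ((1, 0), (1, 0)), ((0, 1), (0, 1))]
    orders = []
    for (p, q), (P, Q) in pairs:
        if m == 1:
            P = Q = 0
        orders.append(
            ArimaOrder(p=p, d=d, q=q, P=P, D=D, Q=Q, m=m, include_constant=constant_ok)
        )
    # the no-constant random walk / white noise baseline
    if constant_ok:
        orders.append(ArimaOrder(p=0, d=d, q=0, P=0, D=D, Q=0, m=m, include_constant=False))
    return orders


def _neighbours(
    order: ArimaOrder,
    bounds: dict[str, int],
    constant_ok: bool,
) -> list[ArimaOrder]:
    out = []

    def push(**changes):
        try:
            cand = replace(order, **changes)
        except ValueError:
            return
        if (
            cand.p <= bounds["max_p"]
            and cand.q <= bounds["max_q"]
            and cand.P <= bounds["max_P"]
            and cand.Q <= bounds["max_Q"]
        ):
            out.append(cand)

    for delta in (-1, 1):
        push(p=order.p + delta)
        push(q=order.q + delta)
        push(p=order.p + delta, q=order.q + delta)
        if order.m > 1:
            push(P=order.P + delta)
            push(Q=order.Q + delta)
            push(P=order.P + delta, Q=order.Q + delta)
    if constant_ok:
        push(include_constant=not order.include_constant)
    return out


def hk_stepwise_select(
    values: np.ndarray,
    m: int = 1,
    max_p: int = 5,
    max_q: int = 5,
    max_P: int = 2,
    max_Q: int = 2,
    max_d: int = 2,
    max_D: int = 1,
    alpha: float = 0.05,
    trace: list | None = None,
) -> FittedArima:
    """Automatic seasonal ARIMA selection by stepwise AICc search.

    ``D`` is set to 1 when the seasonal strength of the series exceeds
    0.64 (and ``m > 1``); ``d`` then comes from KPSS tests on the
    (seasonally differenced) series.  Four standard starting models seed a
    hill-climb that perturbs one or two of p, q, P, Q by one, or toggles the
    constant, accepting any move that lowers AICc.  Candidate fits that fail
    to converge or violate the root guards are skipped.  Pass a list as
    ``trace`` to record ``(order, aicc)`` for every attempted candidate.
    """
    y = np.asarray(values, dtype=float)
    if m > 1 and len(y) < 2 * m:
        raise ValueError(f"need at least two seasonal periods ({2 * m} points) for m={m}")
    D = 0
    if m > 1 and max_D >= 1 and seasonal_strength(y, m) > SEASONAL_STRENGTH_THRESHOLD:
        D = 1
    w = difference(y, d=0, D=D, m=m)
    try:
        d = choose_d(w, max_d=max_d, alpha=alpha)
    except DegenerateSeriesError:
        d = 0  # constant after seasonal differencing: trivially stationary
    constant_ok = (d + D) <= 1
    bounds = {"max_p": max_p, "max_q": max_q, "max_P": max_P, "max_Q": max_Q}

    cache: dict[ArimaOrder, FittedArima | None] = {}

    def evaluate(order: ArimaOrder) -> FittedArima | None:
        if order in cache:
            return cache[order]
        try:
            fit = fit_arima(y, order)
        except ArimaError:
            fit = None
        cache[order] = fit
        if trace is not None:
            trace.append((order, fit.aicc if fit else np.inf))
        return fit

    best: FittedArima | None = None
    for order in _candidate_orders(d, D, m, constant_ok):
        fit = evaluate(order)
        if fit is not None and (best is None or fit.aicc < best.aicc):
            best = fit
    if best is None:
        raise FitRejectedError(
            "all starting fits failed: " + ", ".join(str(o) for o in cache)
        )
    improved = True
    while improved:
        improved = False
        for order in _neighbours(best.order, bounds, constant_ok):
            fit = evaluate(order)
            if fit is not None and fit.aicc < best.aicc:
                best = fit
                improved = True
                break
    return best
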