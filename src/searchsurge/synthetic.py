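"""Synthetic Trends-like series with known injected effects.

The generator emulates the structure of daily relative-search-volume data:
a level, a weekly sinusoidal cycle, stationary AR(1) noise, and an optional
effect (step, ramp or pulse) confined to the evaluation window.  Following
the Trends convention the series can be rescaled so its maximum is 100 and
rounded to integers.  Because the injected effect days are known exactly,
every downstream stage — model selection, forecasting, exceedance counting,
rank correlation — can be validated against ground truth without any
download.

Defaults describe the study conditions used throughout the test-bench:
a 91-day baseline plus 31-day evaluation window, level 50, weekly sinusoid
of amplitude 8, AR(1) noise with coefficient 0.5 and innovation SD 3.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import TrendSeries, WindowSpec

__all__ = ["SyntheticConfig", "generate_trend_series", "generate_panel"]

#: AR(1) start-up steps discarded so the baseline begins in stationarity.
BURN_IN = 100

EFFECT_SHAPES = ("none", "step", "ramp", "pulse")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic (country, keyword) series."""

    n_baseline_days: int = 91
    n_eval_days: int = 31
    level: float = 50.0
    seasonal_amplitude: float = 8.0
    seasonal_period: int = 7
    ar_coefficient: float = 0.5
    noise_sd: float = 3.0
    effect_shape: str = "none"
    effect_magnitude: float = 0.0
    effect_onset: int = 0
    pulse_width: int = 7
    rescale_to_100: bool = True
    round_to_int: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baseline_days < 2 * self.seasonal_period:
            raise ValueError("baseline must cover at least two seasonal periods")
        if self.n_eval_days < 1:
            raise ValueError("evaluation window needs at least one day")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1 for stationary noise")
        if self.noise_sd < 0 or self.seasonal_amplitude < 0:
            raise ValueError("noise_sd and seasonal_amplitude must be >= 0")
        if self.effect_shape not in EFFECT_SHAPES:
            raise ValueError(f"effect_shape must be one of {EFFECT_SHAPES}")
        if not 0 <= self.effect_onset < self.n_eval_days:
            raise ValueError("effect_onset must lie inside the evaluation window")
        if self.pulse_width < 1:
            raise ValueError("pulse_width must be >= 1")


def _effect_profile(config: SyntheticConfig) -> np.ndarray:
    """Additive effect per evaluation day (zeros outside the effect)."""
    n, onset, mag = config.n_eval_days, config.effect_onset, config.effect_magnitude
    profile = np.zeros(n)
    if config.effect_shape == "none" or mag == 0:
        return profile
    if config.effect_shape == "step":
        profile[onset:] = mag
    elif config.effect_shape == "ramp":
        span = n - onset
        profile[onset:] = mag * np.arange(1, span + 1) / span
    elif config.effect_shape == "pulse":
        profile[onset : onset + config.pulse_width] = mag
    return profile


def generate_trend_series(
    config: SyntheticConfig,
    country: str = "SYN",
    keyword: str = "synthetic",
    eval_start: dt.date = dt.date(2020, 3, 20),
) -> tuple[TrendSeries, np.ndarray]:
    """One synthetic daily series plus the true effect-day mask.

    Returns ``(series, effect_days)`` where ``effect_days`` is a boolean
    array over the evaluation window marking days carrying a nonzero
    injected effect.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_baseline_days + config.n_eval_days
    # AR(1) noise with burn-in so the series starts in stationarity
    innov = rng.normal(0.0, config.noise_sd, size=BURN_IN + n)
    noise = np.zeros(BURN_IN + n)
    for t in range(1, BURN_IN + n):
        noise[t] = config.ar_coefficient * noise[t - 1] + innov[t]
    noise = noise[BURN_IN:]
    t_idx = np.arange(n)
    values = (
        config.level
        + config.seasonal_amplitude * np.sin(2 * np.pi * t_idx / config.seasonal_period)
        + noise
    )
    profile = _effect_profile(config)
    values[config.n_baseline_days :] += profile
    effect_days = profile != 0
    if config.rescale_to_100:
        peak = values.max()
        if peak <= 0:
            raise ValueError("cannot rescale: series maximum is not positive")
        values = values * (100.0 / peak)
    if config.round_to_int:
        values = np.floor(values + 0.5)  # round half-up
    values = np.clip(values, 0.0, 100.0)
    start = eval_start - dt.timedelta(days=config.n_baseline_days)
    dates = pd.date_range(start=start, periods=n, freq="D")
    return TrendSeries(country=country, keyword=keyword, dates=dates, values=values), effect_days


def generate_panel(
    n_countries: int,
    effect_days_per_country: list[int],
    base_config: SyntheticConfig = SyntheticConfig(effect_magnitude=20.0),
    seed: int = 0,
) -> tuple[list[TrendSeries], pd.DataFrame]:
    """A multi-country panel with known per-country effect-day counts.

    Country ``i`` receives a step effect of ``base_config.effect_magnitude``
    covering exactly ``effect_days_per_country[i]`` evaluation days — a
    contiguous block ending at the window end, mimicking a sustained
    pandemic-era rise rather than a transient.  Returns the series and a
    truth table with columns ``country,true_effect_days``.
    """
    if len(effect_days_per_country) != n_countries:
        raise ValueError("effect_days_per_country must have one entry per country")
    seeds = np.random.SeedSequence(seed).generate_state(n_countries) % (2**31)
    series_list: list[TrendSeries] = []
    rows = []
    for i, k in enumerate(effect_days_per_country):
        if not 0 <= k <= base_config.n_eval_days:
            raise ValueError(
                f"country {i}: requested {k} effect days but the window has "
                f"{base_config.n_eval_days}"
            )
        if k > 0:
            cfg = replace(
                base_config,
                effect_shape="step",
                effect_onset=base_config.n_eval_days - k,
                seed=int(seeds[i]),
            )
        else:
            cfg = replace(base_config, effect_shape="none", seed=int(seeds[i]))
        series, _ = generate_trend_series(cfg, country=f"C{i:02d}")
        series_list.append(series)
        rows.append({"country": f"C{i:02d}", "true_effect_days": k})
    return series_list, pd.DataFrame(rows)
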