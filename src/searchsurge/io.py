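"""Reading and writing search-interest series and country panels.

Search-interest series follow the Google Trends convention: one value per
calendar day on a relative 0–100 scale, where 100 marks the day of peak
popularity of the term within the queried window.  Two CSV dialects are
supported: the raw multi-line-header export produced by the Trends UI, and
a plain ``date,value`` file.

The module also ships a packaged fixture: a 19-country panel of
exceedance-day counts for the keywords insomnia / depression / suicide
together with COVID-19 burden columns (deaths and confirmed cases,
cumulative to 2020-03-20 and increases over 2020-03-20 → 2020-04-19).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TrendSeries",
    "WindowSpec",
    "PANEL_COLUMNS",
    "DAY_COUNT_COLUMNS",
    "BURDEN_COLUMNS",
    "read_trends_csv",
    "write_trends_csv",
    "load_table1_fixture",
    "read_panel",
    "write_panel",
    "validate_panel",
]

#: Canonical column order of a country panel.
DAY_COUNT_COLUMNS = ("days_insomnia", "days_depression", "days_suicide")
BURDEN_COLUMNS = (
    "deaths_increase",
    "deaths_cum_mar20",
    "cases_increase",
    "cases_cum_mar20",
)
PANEL_COLUMNS = ("country",) + DAY_COUNT_COLUMNS + BURDEN_COLUMNS


class TrendsValidationError(ValueError):
    """A series or panel violates the format's invariants."""


@dataclass(frozen=True)
class WindowSpec:
    """Baseline and evaluation windows, all endpoints inclusive.

    The defaults are the study windows used throughout: a 91-day baseline
    (2019-12-20 → 2020-03-19) and a 31-day evaluation window
    (2020-03-20 → 2020-04-19) starting the day the baseline ends.
    """

    baseline_start: dt.date = dt.date(2019, 12, 20)
    baseline_end: dt.date = dt.date(2020, 3, 19)
    eval_start: dt.date = dt.date(2020, 3, 20)
    eval_end: dt.date = dt.date(2020, 4, 19)

    def __post_init__(self) -> None:
        if self.baseline_end + dt.timedelta(days=1) != self.eval_start:
            raise ValueError(
                "evaluation window must start the day after the baseline ends "
                f"(baseline_end={self.baseline_end}, eval_start={self.eval_start})"
            )
        if self.baseline_start > self.baseline_end or self.eval_start > self.eval_end:
            raise ValueError("window endpoints out of order")

    @property
    def n_baseline_days(self) -> int:
        return (self.baseline_end - self.baseline_start).days + 1

    @property
    def n_eval_days(self) -> int:
        return (self.eval_end - self.eval_start).days + 1


@dataclass
class TrendSeries:
    """One (country, keyword) daily relative-search-volume series.

    ``dates`` must be consecutive calendar days; ``values`` lie in [0, 100].
    """

    country: str
    keyword: str
    dates: pd.DatetimeIndex
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise TrendsValidationError("dates and values differ in length")
        if len(self.dates) == 0:
            raise TrendsValidationError("empty series")
        _check_consecutive(self.dates)
        bad = (self.values < 0) | (self.values > 100) | ~np.isfinite(self.values)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise TrendsValidationError(
                f"value {self.values[i]} on {self.dates[i].date()} outside [0, 100]"
            )

    def __len__(self) -> int:
        return len(self.values)

    def slice(self, start: dt.date, end: dt.date) -> np.ndarray:
        """Values for the inclusive date range ``start``..``end``."""
        lo, hi = pd.Timestamp(start), pd.Timestamp(end)
        if lo < self.dates[0] or hi > self.dates[-1]:
            raise TrendsValidationError(
                f"series {self.country}/{self.keyword} covers "
                f"{self.dates[0].date()}..{self.dates[-1].date()}, "
                f"not {start}..{end}"
            )
        mask = (self.dates >= lo) & (self.dates <= hi)
        return self.values[mask]

    def baseline(self, window: WindowSpec) -> np.ndarray:
        return self.slice(window.baseline_start, window.baseline_end)

    def evaluation(self, window: WindowSpec) -> np.ndarray:
        return self.slice(window.eval_start, window.eval_end)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "value": self.values})


def _check_consecutive(dates: pd.DatetimeIndex) -> None:
    if dates.has_duplicates:
        dup = dates[dates.duplicated()][0]
        raise TrendsValidationError(f"duplicate date {dup.date()}")
    deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    if (deltas < 0).any():
        raise TrendsValidationError("dates are not increasing")
    gaps = np.flatnonzero(deltas > 1)
    if gaps.size:
        missing = dates[gaps[0]] + pd.Timedelta(days=1)
        raise TrendsValidationError(f"missing date {missing.date()}")


def _parse_value(token: str, less_than_one: float = 0.5) -> float:
    token = token.strip()
    if token == "<1":  # Trends suppresses small values; interval midpoint
        return less_than_one
    return float(token)


def read_trends_csv(
    path: str | Path,
    dialect: str = "plain",
    country: str = "",
    keyword: str = "",
    less_than_one: float = 0.5,
) -> TrendSeries:
    """Read a daily search-interest series from CSV.

    Parameters
    ----------
    path : file path
    dialect : {"plain", "export"}
        ``plain`` expects a ``date,value`` header.  ``export`` accepts the
        Google Trends UI download: any number of header/blank lines followed
        by a ``Day,<keyword>: (<country>)`` line and daily rows.
    country, keyword : str
        Labels attached to the series; for the export dialect they default
        to what the column header declares.
    less_than_one : float
        Replacement for the suppressed-value token ``"<1"`` (default 0.5,
        the midpoint of the suppressed interval).
    """
    if dialect not in ("plain", "export"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = Path(path).read_text(encoding="utf-8-sig").splitlines()
    rows: list[tuple[dt.date, float]] = []
    in_data = dialect == "plain"
    header_seen = False
    for line in lines:
        line = line.strip()
        if not line:
            continue
        first = line.split(",", 1)[0].strip()
        if not in_data or not header_seen:
            if first.lower() in ("date", "day", "week", "month"):
                header_seen = True
                in_data = True
                if dialect == "export" and "," in line:
                    # header like "Day,insomnia: (Spain)"
                    label = line.split(",", 1)[1]
                    if ":" in label:
                        kw, _, loc = label.partition(":")
                        keyword = keyword or kw.strip()
                        country = country or loc.strip().strip("()")
                    else:
                        keyword = keyword or label.strip()
                continue
            if dialect == "export":
                continue  # skip "Category: ..." style preamble
            header_seen = True  # tolerate headerless plain files
        try:
            date = dt.date.fromisoformat(first)
        except ValueError as exc:
            raise TrendsValidationError(f"cannot parse date {first!r}") from exc
        value = _parse_value(line.split(",", 2)[1], less_than_one)
        rows.append((date, value))
    if not rows:
        raise TrendsValidationError(f"no data rows in {path}")
    dates = pd.DatetimeIndex([pd.Timestamp(d) for d, _ in rows])
    values = np.array([v for _, v in rows], dtype=float)
    return TrendSeries(country=country, keyword=keyword, dates=dates, values=values)


def write_trends_csv(series: TrendSeries, path: str | Path, dialect: str = "plain") -> None:
    """Write a series in either supported dialect (6 significant digits)."""
    out = []
    if dialect == "export":
        out.append("Category: All categories")
        out.append("")
        out.append(f"Day,{series.keyword}: ({series.country})")
    elif dialect == "plain":
        out.append("date,value")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for date, value in zip(series.dates, series.values):
        out.append(f"{date.date().isoformat()},{value:.6g}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# country panels


def validate_panel(panel: pd.DataFrame, n_eval_days: int = 31) -> pd.DataFrame:
    """Check panel invariants; returns the panel with canonical column order.

    Day-count columns must be integers in [0, n_eval_days]; burden columns
    non-negative.  Extra ``days_*`` columns beyond the canonical three are
    allowed (the pipeline produces one per keyword analysed).
    """
    if "country" not in panel.columns:
        raise TrendsValidationError("panel lacks a 'country' column")
    if panel["country"].duplicated().any():
        raise TrendsValidationError("duplicate country rows")
    day_cols = [c for c in panel.columns if c.startswith("days_")]
    for col in day_cols:
        vals = panel[col].to_numpy()
        if ((vals < 0) | (vals > n_eval_days)).any():
            raise TrendsValidationError(
                f"{col} has a count outside [0, {n_eval_days}]"
            )
    for col in BURDEN_COLUMNS:
        if col in panel.columns and (panel[col].to_numpy() < 0).any():
            raise TrendsValidationError(f"{col} has a negative value")
    ordered = [c for c in PANEL_COLUMNS if c in panel.columns]
    ordered += [c for c in panel.columns if c not in ordered]
    return panel[ordered]


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 19-country panel (day counts + COVID-19 burden).

    Columns: country, days_insomnia, days_depression, days_suicide,
    deaths_increase, deaths_cum_mar20, cases_increase, cases_cum_mar20.
    """
    with resources.files("searchsurge.data").joinpath("table1.csv").open("r") as fh:
        panel = pd.read_csv(fh)
    return validate_panel(panel)


def read_panel(path: str | Path, n_eval_days: int = 31) -> pd.DataFrame:
    return validate_panel(pd.read_csv(path), n_eval_days=n_eval_days)


def write_panel(panel: pd.DataFrame, path: str | Path, n_eval_days: int = 31) -> None:
    """Write a validated panel as plain CSV with stable column order."""
    validate_panel(panel, n_eval_days=n_eval_days).to_csv(path, index=False)
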