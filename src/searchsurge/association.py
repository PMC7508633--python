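"""Tie-aware Spearman rank correlation for country panels.

Day-count statistics are small integers with many ties across countries, so
Spearman's rho is computed as the Pearson product-moment correlation of
average (mid-) ranks, and the two-sided p-value from the t approximation
``t = rho * sqrt((n-2) / (1-rho^2))`` on ``n-2`` degrees of freedom — the
standard choice in the presence of ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BURDEN_COLUMNS

__all__ = ["CorrelationResult", "average_ranks", "spearman", "correlate_panel", "grid_to_frame"]


class ConstantVectorError(ValueError):
    """Spearman's rho is undefined when a vector has no variation."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_two_sided: float
    n: int
    x_label: str = "x"
    y_label: str = "y"
    error: str | None = None


def average_ranks(values) -> np.ndarray:
    """Ranks 1..n with tied values sharing the mean of their positions."""
    return stats.rankdata(np.asarray(values, dtype=float), method="average")


def spearman(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Spearman rank-order correlation with a two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError(
            f"rho undefined: {'x' if np.ptp(x) == 0 else 'y'} is constant"
        )
    rx, ry = average_ranks(x), average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_two_sided=p, n=n, x_label=x_label, y_label=y_label)


def correlate_panel(
    panel: pd.DataFrame,
    day_columns: list[str] | None = None,
    burden_columns: list[str] | None = None,
) -> list[CorrelationResult]:
    """The full correlation grid: every day-count column against every
    burden column.  A failing cell (e.g. a constant column) is reported in
    place with its error message; the rest of the grid is still computed.
    """
    if len(panel) < 3:
        raise ValueError("need at least 3 countries")
    if day_columns is None:
        day_columns = [c for c in panel.columns if c.startswith("days_")]
    if burden_columns is None:
        burden_columns = [c for c in BURDEN_COLUMNS if c in panel.columns]
    results = []
    for xc in day_columns:
        for yc in burden_columns:
            try:
                results.append(spearman(panel[xc], panel[yc], x_label=xc, y_label=yc))
            except ConstantVectorError as exc:
                results.append(
                    CorrelationResult(
                        rho=np.nan,
                        p_two_sided=np.nan,
                        n=len(panel),
                        x_label=xc,
                        y_label=yc,
                        error=str(exc),
                    )
                )
    return results


def grid_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Correlation grid as a tidy DataFrame (x_label, y_label, n, rho, p)."""
    return pd.DataFrame(
        [
            {
                "x_label": r.x_label,
                "y_label": r.y_label,
                "n": r.n,
                "rho": r.rho,
                "p": r.p_two_sided,
                "error": r.error or "",
            }
            for r in results
        ]
    )
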