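"""Ensemble statistics and seasonal water-temperature summaries.

Two small toolsets: (1) significance tests on binding-energy ensembles
given only summary statistics (mean, SD, n per group), matching how
such ensembles are reported; (2) windowed statistics over daily
water-temperature records pooled across years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "DailyTempRecord",
    "two_sample_t",
    "cohens_d",
    "read_temperature_csv",
    "seasonal_window_stats",
    "daily_variation",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one ensemble: mean and sample SD (n-1
    denominator, matching the t-test convention) with group size n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be >= 2 for any test")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(float(arr.mean()), float(arr.std(ddof=1)), len(arr))


@dataclass(frozen=True)
class DailyTempRecord:
    """One day of water-temperature extremes (°C)."""

    day: date
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValueError("t_min must not exceed t_max")


def two_sample_t(
    summary_a: GroupSummary,
    summary_b: GroupSummary,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Independent two-sample t-test from summary statistics.

    Returns (t, degrees of freedom, two-tailed p).  ``variant`` selects the
    pooled-variance (classic Student) or Welch form.  Identical groups give
    t = 0, p = 1; two zero-variance groups with equal means are degenerate
    and rejected.
    """
    a, b = summary_a, summary_b
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise ValueError("degenerate test: zero variance and equal means")
        return math.inf, float(a.n + b.n - 2), 0.0
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    elif variant == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t = (b.mean - a.mean) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cohens_d(summary_a: GroupSummary, summary_b: GroupSummary) -> float:
    """Cohen's d effect size, (mean_b - mean_a) / pooled SD with (n-1)
    weights.  Antisymmetric under group exchange."""
    a, b = summary_a, summary_b
    pooled = math.sqrt(
        ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return (b.mean - a.mean) / pooled


def read_temperature_csv(path: str | Path) -> list[DailyTempRecord]:
    """Read a delimited (date, t_min, t_max) series with ISO dates.

    Missing days are simply absent — no imputation.  Column order is
    positional; a header row is detected and skipped.
    """
    frame = pd.read_csv(path)
    records = []
    for _, row in frame.iterrows():
        day = pd.Timestamp(row.iloc[0]).date()
        records.append(DailyTempRecord(day, float(row.iloc[1]), float(row.iloc[2])))
    return records


def _in_window(day: date, start: tuple[int, int], end: tuple[int, int]) -> bool:
    md = (day.month, day.day)
    if start <= end:
        return start <= md <= end
    return md >= start or md <= end  # wraps the year boundary


def seasonal_window_stats(
    series: Sequence[DailyTempRecord],
    window_start: tuple[int, int],
    window_end: tuple[int, int],
) -> dict:
    """Pooled statistics for all records whose month-day falls in the
    inclusive window (which may wrap the year boundary, e.g. Dec 28–Jan 3).

    Returns, separately for highs (t_max) and lows (t_min): count, mean,
    population SD of the pooled samples, and the min–max range.
    """
    selected = [r for r in series if _in_window(r.day, window_start, window_end)]
    if not selected:
        raise ValueError("no records fall inside the requested window")
    out = {}
    for label, values in (
        ("high", np.array([r.t_max for r in selected])),
        ("low", np.array([r.t_min for r in selected])),
    ):
        out[label] = {
            "n": len(values),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=0)),
            "range": (float(values.min()), float(values.max())),
        }
    return out


def daily_variation(
    series: Sequence[DailyTempRecord],
    window_start: tuple[int, int] = (1, 1),
    window_end: tuple[int, int] = (12, 31),
) -> tuple[float, float]:
    """Mean and population SD of the daily spread (t_max - t_min) over the
    selected window."""
    spreads = np.array(
        [
            r.t_max - r.t_min
            for r in series
            if _in_window(r.day, window_start, window_end)
        ]
    )
    if len(spreads) == 0:
        raise ValueError("no records fall inside the requested window")
    return float(spreads.mean()), float(spreads.std(ddof=0))
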