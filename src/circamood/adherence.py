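"""Wearable adherence: 30-day wear-rate series and moving-average /
moving-SD trend lines per subject and per group.

The study period is cut into consecutive 30-day units (720 hours); the
wear rate of each unit is worn hours / 720. Trend lines smooth the
per-unit series with a 6-point sliding window: MA is the window mean,
MSD the window sample SD. A trailing partial unit is dropped rather
than prorated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import wear_rate
from .records import SubjectRecord

UNIT_DAYS = 30
TREND_WINDOW = 6


@dataclass(frozen=True)
class WearRateSeries:
    """Per-unit wear rates with their MA/MSD trend lines."""

    subject_id: str
    points: pd.Series  # index: unit start date, values in [0, 1]
    ma: pd.Series
    msd: pd.Series


def wear_rate_series(subject: SubjectRecord,
                     start: Optional[pd.Timestamp] = None,
                     end: Optional[pd.Timestamp] = None,
                     unit_days: int = UNIT_DAYS) -> pd.Series:
    """Wear rate per consecutive ``unit_days`` block of the study period."""
    period = subject.study_period()
    start = pd.Timestamp(start) if start is not None else period[0]
    end = pd.Timestamp(end) if end is not None else period[1]
    unit = pd.Timedelta(days=unit_days)
    stream = subject.streams.get("heart_rate")
    starts, rates = [], []
    cursor = start
    while cursor + unit <= end:
        rates.append(wear_rate(stream, (cursor, cursor + unit)).rate)
        starts.append(cursor)
        cursor += unit
    return pd.Series(rates, index=pd.DatetimeIndex(starts), dtype=float)


def moving_stats(series: pd.Series,
                 window: int = TREND_WINDOW) -> tuple[pd.Series, pd.Series]:
    """Sliding-window mean (MA) and sample SD (MSD) of a series.

    Returns series of length ``len(series) - window + 1``; a series
    shorter than the window yields empty trends with a warning.
    """
    if len(series) < window:
        warnings.warn(f"series of length {len(series)} shorter than "
                      f"window {window}; empty trend", stacklevel=2)
        empty = pd.Series(dtype=float)
        return empty, empty
    rolled = series.rolling(window)
    ma = rolled.mean().iloc[window - 1:]
    msd = rolled.std(ddof=1).iloc[window - 1:]
    return ma, msd


def subject_trends(subject: SubjectRecord,
                   unit_days: int = UNIT_DAYS,
                   window: int = TREND_WINDOW) -> WearRateSeries:
    points = wear_rate_series(subject, unit_days=unit_days)
    ma, msd = moving_stats(points, window)
    return WearRateSeries(subject.subject_id, points, ma, msd)


def group_trend(trends: Sequence[WearRateSeries]) -> pd.DataFrame:
    """Pointwise mean of individual MA and MSD lines, aligned by unit
    index. Unequal lengths are aligned on the common prefix (warned)."""
    if not trends:
        raise ValueError("need at least one subject trend")
    lengths = {len(t.ma) for t in trends}
    n = min(lengths)
    if len(lengths) > 1:
        warnings.warn("unequal trend lengths; aligning on common prefix "
                      f"of {n} points", stacklevel=2)
    ma = np.mean([t.ma.to_numpy()[:n] for t in trends], axis=0)
    msd = np.mean([t.msd.to_numpy()[:n] for t in trends], axis=0)
    return pd.DataFrame({"ma": ma, "msd": msd},
                        index=pd.RangeIndex(n, name="unit"))
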