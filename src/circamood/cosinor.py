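"""Single-component cosinor rhythmometry for heart-rate streams.

Fits ``y = M + A*cos(2*pi*(t - phi)/24)`` by least squares through the
linear parameterisation ``y = M + b1*cos(wt) + b2*sin(wt)`` with
``A = sqrt(b1^2 + b2^2)`` and ``phi = atan2(b2, b1)/w``; ``t`` is the
fractional hour of local clock day, so the acrophase ``phi`` is directly
a clock time in ``[0, 24)``.

The score pipeline uses the trailing 48 hours of heart rate and the
circular distance of the acrophase from a fixed midday (12:00) reference
folded into ``[0, 12]`` hours: 0 means the rhythm peaks exactly at
midday, 12 means it peaks at midnight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .records import SensorStream

MIDDAY_REFERENCE_HOUR = 12.0

#: Below this fitted amplitude (beats/min) the acrophase is numerically
#: meaningless; the fit is flagged degenerate and the distance set to 0
#: so a flat-but-regular signal is judged on amplitude alone.
DEGENERATE_AMPLITUDE = 1e-9


@dataclass(frozen=True)
class CosinorFit:
    """Result of one cosinor fit."""

    mesor: float
    amplitude: float
    acrophase: float  # clock hours in [0, 24)
    acrophase_distance: float  # hours in [0, 12] from midday
    window: tuple[pd.Timestamp, pd.Timestamp]
    n_samples: int
    degenerate: bool = False


def circular_distance_from_midday(acrophase_hours: float,
                                  reference: float = MIDDAY_REFERENCE_HOUR) -> float:
    """Circular distance in hours between an acrophase and the midday
    reference, folded to [0, 12]."""
    d = abs(acrophase_hours - reference) % 24.0
    return min(d, 24.0 - d)


def _hour_of_day(index: pd.DatetimeIndex) -> np.ndarray:
    ns = index.values.astype("datetime64[ns]").astype(np.int64)
    day_ns = 24 * 3600 * 10**9
    return (ns % day_ns) / (3600 * 10**9)


def fit_cosinor(
    stream: SensorStream,
    end_time: pd.Timestamp,
    window_hours: float = 48.0,
    period_hours: float = 24.0,
    min_samples: int = 24,
) -> Optional[CosinorFit]:
    """Fit the cosinor to samples in ``[end_time - window, end_time)``.

    Returns ``None`` (fit unavailable) when fewer than ``min_samples``
    samples fall in the window or the samples span less than half the
    window — a fit on a fragment of a day would alias the daily rhythm.
    """
    end_time = pd.Timestamp(end_time)
    start_time = end_time - pd.Timedelta(hours=window_hours)
    win = stream.window(start_time, end_time)
    if len(win) < min_samples:
        return None
    span_hours = (win.index[-1] - win.index[0]).total_seconds() / 3600.0
    if span_hours < window_hours / 2.0:
        return None

    t = _hour_of_day(win.index)
    y = win.to_numpy(dtype=float)
    omega = 2.0 * np.pi / period_hours
    design = np.column_stack([np.ones_like(t), np.cos(omega * t),
                              np.sin(omega * t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    mesor, b1, b2 = coef
    amplitude = float(np.hypot(b1, b2))
    if amplitude < DEGENERATE_AMPLITUDE:
        return CosinorFit(float(mesor), 0.0, 0.0, 0.0,
                          (start_time, end_time), len(win), degenerate=True)
    acrophase = float(np.arctan2(b2, b1) / omega % period_hours)
    distance = circular_distance_from_midday(acrophase)
    return CosinorFit(float(mesor), amplitude, acrophase, distance,
                      (start_time, end_time), len(win))
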