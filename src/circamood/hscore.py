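"""Circadian H-scores, risk indicator, feedback messages and warning alerts.

Four 0-100 "healthiness" scores are computed per subject-day, one per
circadian domain, each a weighted combination of normalised daily
behaviour quantities:

* heart-rate rhythm:  ``CR = 0.5*N(amplitude) + 0.5*(100 - N(acrophase distance))``
* activity:           ``ACT = 0.5*(100 - N(bedtime steps)) + 0.5*N(daytime steps)``
* light exposure:     ``LE = 0.5*(100 - N(bedtime lux)) + 0.5*N(daytime lux)``
* sleep:              ``SL = 0.5*N(efficiency) + 0.25*(100 - N(onset dev))
  + 0.25*(100 - N(offset dev))``

``N`` maps a raw value linearly onto [0, 100] between reference bounds
and clamps. Bounds default to a personal rolling (5th, 95th) percentile
window so the score reflects change relative to the subject's own
recent behaviour; a fixed population config is the fallback while a
subject has too little history.

A warning alert fires on a day when the average of the available scores
falls below 50, or below 60 on two consecutive available days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .records import SleepRecord


# ---------------------------------------------------------------------------
# time zones of the day

@dataclass(frozen=True)
class TimeZones:
    """Bedtime / daytime windows anchored to sunrise and sunset.

    The ideal bedtime is 8 h before sunrise; the bedtime window is the
    8-hour night ``[sunrise - 8h, sunrise)`` that ends on the morning of
    the day being scored, and daytime is ``[sunrise, sunset)`` of that
    day. Defaults are a fixed 06:30 / 18:30 local clock.
    """

    sunrise: dt.time = dt.time(6, 30)
    sunset: dt.time = dt.time(18, 30)

    def __post_init__(self) -> None:
        if self.sunset <= self.sunrise:
            raise ValueError("sunset must follow sunrise")

    @property
    def sunrise_hours(self) -> float:
        return self.sunrise.hour + self.sunrise.minute / 60.0

    @property
    def sunset_hours(self) -> float:
        return self.sunset.hour + self.sunset.minute / 60.0

    @property
    def ideal_bedtime_hours(self) -> float:
        """Clock hour of ideal sleep onset, 8 h before sunrise (may be
        on the previous calendar day, i.e. >= 16)."""
        return (self.sunrise_hours - 8.0) % 24.0

    def ideal_onset(self, date: dt.date) -> pd.Timestamp:
        """Ideal going-to-bed instant for the night ending on ``date``."""
        return self.bedtime_window(date)[0]

    def ideal_offset(self, date: dt.date) -> pd.Timestamp:
        """Ideal wake-up instant on ``date`` (sunrise)."""
        return self.bedtime_window(date)[1]

    def bedtime_window(self, date: dt.date) -> tuple[pd.Timestamp, pd.Timestamp]:
        """[sunrise - 8h, sunrise) ending on the morning of ``date``."""
        end = pd.Timestamp(dt.datetime.combine(date, self.sunrise))
        return end - pd.Timedelta(hours=8), end

    def daytime_window(self, date: dt.date) -> tuple[pd.Timestamp, pd.Timestamp]:
        """[sunrise, sunset) of ``date``."""
        day = pd.Timestamp(date)
        return (day + pd.Timedelta(hours=self.sunrise_hours),
                day + pd.Timedelta(hours=self.sunset_hours))


DEFAULT_ZONES = TimeZones()


# ---------------------------------------------------------------------------
# normalisation

@dataclass(frozen=True)
class NormalizationRef:
    """Reference (low, high) bounds for the 0-100 normalisation N(x)."""

    low: float
    high: float
    provenance: str = "fixed-config"  # or "personal-rolling"

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValueError(f"high ({self.high}) must exceed low ({self.low})")


#: Fallback population bounds, used until a subject accrues enough
#: history for personal bounds. Chosen as plausible clinical ranges for
#: adults wearing a wrist tracker; all N are increasing in x (the score
#: formulas subtract from 100 where larger is worse).
FIXED_BOUNDS: dict[str, NormalizationRef] = {
    "cr_amplitude": NormalizationRef(0.0, 20.0),          # beats/min
    "cr_acrophase_distance": NormalizationRef(0.0, 12.0),  # hours
    "steps_during_bedtime": NormalizationRef(0.0, 600.0),
    "steps_during_daytime": NormalizationRef(0.0, 12000.0),
    "light_exposure_during_bedtime": NormalizationRef(0.0, 100.0),  # lux
    "light_exposure_during_daytime": NormalizationRef(0.0, 1000.0),
    "sleep_efficiency": NormalizationRef(0.5, 1.0),
    "sleep_onset_dev": NormalizationRef(0.0, 240.0),       # minutes
    "sleep_offset_dev": NormalizationRef(0.0, 240.0),
}

PERSONAL_WINDOW_DAYS = 30
PERSONAL_MIN_DAYS = 7
PERSONAL_PERCENTILES = (5.0, 95.0)


def normalize(x: float, ref: NormalizationRef) -> float:
    """Linear map of x onto [0, 100] between ref bounds, clamped."""
    score = 100.0 * (x - ref.low) / (ref.high - ref.low)
    return float(min(100.0, max(0.0, score)))


def personal_refs(
    history: pd.DataFrame,
    date: dt.date,
    window_days: int = PERSONAL_WINDOW_DAYS,
    min_days: int = PERSONAL_MIN_DAYS,
    percentiles: tuple[float, float] = PERSONAL_PERCENTILES,
    fallback: Mapping[str, NormalizationRef] = FIXED_BOUNDS,
) -> dict[str, NormalizationRef]:
    """Per-feature rolling percentile bounds over the trailing window.

    ``history`` is a daily feature frame indexed by date. Features with
    fewer than ``min_days`` finite values in the trailing ``window_days``
    (excluding the focal date itself), or with degenerate percentile
    spread, fall back to the fixed config bounds.
    """
    refs: dict[str, NormalizationRef] = {}
    start = date - dt.timedelta(days=window_days)
    trailing = history.loc[[d for d in history.index
                            if start <= d < date]]
    for feature, fixed in fallback.items():
        refs[feature] = fixed
        if feature in trailing.columns:
            values = trailing[feature].dropna().to_numpy(dtype=float)
            if len(values) >= min_days:
                low, high = np.percentile(values, percentiles)
                if high > low:
                    refs[feature] = NormalizationRef(
                        float(low), float(high), "personal-rolling")
    return refs


# ---------------------------------------------------------------------------
# score formulas

def _is_missing(*values) -> bool:
    return any(v is None or (isinstance(v, float) and np.isnan(v))
               for v in values)


def cr_h_score(amplitude: Optional[float], acrophase_distance: Optional[float],
               refs: Mapping[str, NormalizationRef]) -> Optional[float]:
    """Heart-rate rhythm score: high when the rhythm is strong and peaks
    near midday."""
    if _is_missing(amplitude, acrophase_distance):
        return None
    return (0.5 * normalize(amplitude, refs["cr_amplitude"])
            + 0.5 * (100.0 - normalize(acrophase_distance,
                                       refs["cr_acrophase_distance"])))


def act_h_score(steps_bedtime: Optional[float], steps_daytime: Optional[float],
                refs: Mapping[str, NormalizationRef]) -> Optional[float]:
    """Activity score: high for active days and still nights."""
    if _is_missing(steps_bedtime, steps_daytime):
        return None
    return (0.5 * (100.0 - normalize(steps_bedtime,
                                     refs["steps_during_bedtime"]))
            + 0.5 * normalize(steps_daytime, refs["steps_during_daytime"]))


def le_h_score(light_bedtime: Optional[float], light_daytime: Optional[float],
               refs: Mapping[str, NormalizationRef]) -> Optional[float]:
    """Light-exposure score: high for bright days and dark nights."""
    if _is_missing(light_bedtime, light_daytime):
        return None
    return (0.5 * (100.0 - normalize(light_bedtime,
                                     refs["light_exposure_during_bedtime"]))
            + 0.5 * normalize(light_daytime,
                              refs["light_exposure_during_daytime"]))


def sl_h_score(efficiency: Optional[float], onset_dev: Optional[float],
               offset_dev: Optional[float],
               refs: Mapping[str, NormalizationRef]) -> Optional[float]:
    """Sleep score: efficiency carries half the weight, timing deviations
    a quarter each."""
    if _is_missing(efficiency, onset_dev, offset_dev):
        return None
    return (0.5 * normalize(efficiency, refs["sleep_efficiency"])
            + 0.25 * (100.0 - normalize(onset_dev, refs["sleep_onset_dev"]))
            + 0.25 * (100.0 - normalize(offset_dev, refs["sleep_offset_dev"])))


# ---------------------------------------------------------------------------
# daily aggregation, risk, alerts, messages

@dataclass(frozen=True)
class RiskThresholds:
    """Average-score cutoffs for the risk indicator spectrum.

    Aligned with the 50/60 alert scale: high risk below ``high``,
    moderate below ``low``, low risk otherwise.
    """

    high: float = 60.0
    low: float = 80.0


DEFAULT_RISK = RiskThresholds()

ALERT_BELOW = 50.0
ALERT_BELOW_TWICE = 60.0
ALERT_MESSAGE = "Recently, your life rhythm is irregular."

SCORE_NAMES = ("cr_h", "act_h", "le_h", "sl_h")

#: Feedback catalog: one coaching message per domain, shown when that
#: score drops below the messaging threshold. Wording is the package's
#: own; order is fixed (cr, act, le, sl) for determinism.
MESSAGE_CATALOG = {
    "cr_h": "Your daily heart-rate rhythm is weakening or drifting; keep "
            "regular meal and activity times.",
    "act_h": "Try to be more active during the day and avoid moving about "
             "during bedtime hours.",
    "le_h": "Seek bright light during the day and keep your bedroom dark "
            "at night.",
    "sl_h": "Try to go to bed and wake up at consistent times close to "
            "your ideal sleep schedule.",
}
MESSAGING_THRESHOLD = 60.0


@dataclass(frozen=True)
class DailyHScores:
    """The four H-scores for one subject-day plus their average and risk."""

    date: dt.date
    cr_h: Optional[float]
    act_h: Optional[float]
    le_h: Optional[float]
    sl_h: Optional[float]
    average: Optional[float] = field(default=None)
    risk_level: Optional[str] = field(default=None)

    def available(self) -> dict[str, bool]:
        return {name: getattr(self, name) is not None for name in SCORE_NAMES}

    def scores(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in SCORE_NAMES}


@dataclass(frozen=True)
class Alert:
    date: dt.date
    rule: str  # "below-50" | "below-60-twice"
    message: str = ALERT_MESSAGE


def daily_average(scores: Mapping[str, Optional[float]],
                  risk: RiskThresholds = DEFAULT_RISK,
                  ) -> tuple[Optional[float], Optional[str]]:
    """Mean of the available scores and the risk level of that mean.

    With no available score the day is unavailable: ``(None, None)``.
    """
    present = [v for v in scores.values() if v is not None
               and not (isinstance(v, float) and np.isnan(v))]
    if not present:
        return None, None
    avg = float(np.mean(present))
    if avg < risk.high:
        level = "high"
    elif avg < risk.low:
        level = "moderate"
    else:
        level = "low"
    return avg, level


def score_day(date: dt.date, summary: Mapping[str, float],
              refs: Mapping[str, NormalizationRef],
              risk: RiskThresholds = DEFAULT_RISK) -> DailyHScores:
    """Compute all four H-scores for one day from its behaviour summary."""
    get = summary.get
    cr = cr_h_score(get("cr_amplitude"), get("cr_acrophase_distance"), refs)
    act = act_h_score(get("steps_during_bedtime"),
                      get("steps_during_daytime"), refs)
    le = le_h_score(get("light_exposure_during_bedtime"),
                    get("light_exposure_during_daytime"), refs)
    sl = sl_h_score(get("sleep_efficiency"), get("sleep_onset_dev"),
                    get("sleep_offset_dev"), refs)
    avg, level = daily_average(
        {"cr_h": cr, "act_h": act, "le_h": le, "sl_h": sl}, risk)
    return DailyHScores(date, cr, act, le, sl, avg, level)


def score_days(summaries: pd.DataFrame,
               normalization: str = "personal-rolling",
               refs: Optional[Mapping[str, NormalizationRef]] = None,
               risk: RiskThresholds = DEFAULT_RISK) -> pd.DataFrame:
    """Score every day of a daily-summary frame (indexed by date).

    Returns a frame indexed by date with columns cr_h, act_h, le_h,
    sl_h, average, risk_level (NaN / None when unavailable).
    """
    if normalization not in ("personal-rolling", "fixed-config"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    rows = []
    for date in summaries.index:
        if normalization == "personal-rolling":
            day_refs = personal_refs(summaries, date,
                                     fallback=refs or FIXED_BOUNDS)
        else:
            day_refs = dict(refs or FIXED_BOUNDS)
        scored = score_day(date, summaries.loc[date].to_dict(), day_refs, risk)
        rows.append({"date": date, **scored.scores(),
                     "average": scored.average,
                     "risk_level": scored.risk_level})
    frame = pd.DataFrame(rows).set_index("date")
    return frame.astype({c: float for c in
                         ("cr_h", "act_h", "le_h", "sl_h", "average")})


def evaluate_alerts(averages: pd.Series,
                    below: float = ALERT_BELOW,
                    below_twice: float = ALERT_BELOW_TWICE) -> list[Alert]:
    """Apply the two warning-alert rules to a date-ordered average series.

    Rule 1 fires on any day with average < 50; rule 2 fires on the
    second of two consecutive available days with averages < 60. At
    most one alert per day (rule 1 takes precedence). A missing day
    breaks consecutiveness: no alert is raised from unobserved behaviour.
    """
    alerts: list[Alert] = []
    dates = list(averages.index)
    for i, date in enumerate(dates):
        avg = averages.iloc[i]
        if avg is None or (isinstance(avg, float) and np.isnan(avg)):
            continue
        if avg < below:
            alerts.append(Alert(date, "below-50"))
            continue
        if avg < below_twice and i > 0:
            prev_date, prev = dates[i - 1], averages.iloc[i - 1]
            consecutive = (
                prev is not None
                and not (isinstance(prev, float) and np.isnan(prev))
                and _is_previous_day(prev_date, date)
                and prev < below_twice)
            if consecutive:
                alerts.append(Alert(date, "below-60-twice"))
    return alerts


def _is_previous_day(prev: dt.date, cur: dt.date) -> bool:
    try:
        return (cur - prev) == dt.timedelta(days=1)
    except TypeError:  # integer day indices are accepted too
        return cur - prev == 1


def feedback_messages(scores: DailyHScores,
                      threshold: float = MESSAGING_THRESHOLD) -> list[str]:
    """Coaching messages for every available score below the threshold,
    in fixed catalog order."""
    messages = []
    for name in SCORE_NAMES:
        value = getattr(scores, name)
        if value is not None and value < threshold:
            messages.append(MESSAGE_CATALOG[name])
    return messages
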