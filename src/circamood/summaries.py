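"""Per-day behaviour summaries derived from raw streams and sleep records.

One row per subject-day holding the 13 basic circadian digital-phenotype
quantities: cosinor amplitude and acrophase distance of the trailing
48-h heart-rate rhythm, step totals and mean light by time zone, total
daily steps, sleep efficiency / timing deviations / duration, and mean
heart rate by time zone. Missing inputs yield NaN, never silent zeros:
a fully unworn day has an all-NaN row.

The cosinor is refit each day on the 48 hours preceding the daily
evaluation instant (21:00, the mood-chart hour).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cosinor import fit_cosinor
from .hscore import DEFAULT_ZONES, TimeZones
from .records import SubjectRecord

#: The 13 basic features, a reconstruction of the quantities the scoring
#: formulas and feedback system consume (the exact supplementary list is
#: configurable via the ``features`` argument of the extractor).
BASIC_FEATURES = (
    "cr_amplitude",
    "cr_acrophase_distance",
    "steps_during_daytime",
    "steps_during_bedtime",
    "total_daily_steps",
    "light_exposure_during_daytime",
    "light_exposure_during_bedtime",
    "sleep_efficiency",
    "sleep_onset_dev",
    "sleep_offset_dev",
    "sleep_duration",
    "mean_daytime_heart_rate",
    "mean_bedtime_heart_rate",
)

#: Daily evaluation instant (clock hour): the mood chart is filled at
#: 21:00, so scores and the trailing cosinor window are anchored there.
EVALUATION_HOUR = 21.0


@dataclass(frozen=True)
class DailyBehaviorSummary:
    """The per-day derived quantities feeding the four H-scores."""

    date: dt.date
    steps_during_bedtime: float
    steps_during_daytime: float
    light_exposure_during_bedtime: float
    light_exposure_during_daytime: float
    sleep_efficiency: float
    sleep_onset_dev: float
    sleep_offset_dev: float
    cr_amplitude: float
    cr_acrophase_distance: float


def _zone_labels(index: pd.DatetimeIndex, zones: TimeZones):
    """(day-label, bed-label) arrays: the calendar date each sample's
    daytime/bedtime window belongs to, or NaT outside the zone.

    The bedtime window ends at sunrise of its labelled day, so samples
    after the (midnight-crossing) bedtime start belong to the next day.
    """
    ns = index.values.astype("datetime64[ns]")
    days = ns.astype("datetime64[D]")
    tod = (ns - days).astype("timedelta64[s]").astype(float) / 3600.0

    day_mask = (tod >= zones.sunrise_hours) & (tod < zones.sunset_hours)
    day_label = np.where(day_mask, days, np.datetime64("NaT"))

    bed_start = zones.ideal_bedtime_hours
    if bed_start > zones.sunrise_hours:  # window crosses midnight
        evening = tod >= bed_start
        morning = tod < zones.sunrise_hours
        bed_label = np.full(len(index), np.datetime64("NaT"), dtype="datetime64[D]")
        bed_label[evening] = days[evening] + np.timedelta64(1, "D")
        bed_label[morning] = days[morning]
    else:
        in_bed = (tod >= bed_start) & (tod < zones.sunrise_hours)
        bed_label = np.where(in_bed, days, np.datetime64("NaT"))
    return day_label, bed_label


def _grouped(values: np.ndarray, labels: np.ndarray, dates: pd.Index,
             how: str) -> pd.Series:
    mask = ~pd.isna(labels)
    if not mask.any():
        return pd.Series(np.nan, index=dates)
    frame = pd.Series(values[mask], index=pd.DatetimeIndex(labels[mask]).date)
    grouped = frame.groupby(level=0)
    agg = grouped.sum() if how == "sum" else grouped.mean()
    return agg.reindex(dates)


def daily_summaries(
    subject: SubjectRecord,
    dates: Optional[Sequence[dt.date]] = None,
    zones: TimeZones = DEFAULT_ZONES,
    evaluation_hour: float = EVALUATION_HOUR,
    cosinor_window_hours: float = 48.0,
) -> pd.DataFrame:
    """Compute the daily feature frame for one subject.

    Returns a DataFrame indexed by date with the :data:`BASIC_FEATURES`
    columns. ``dates`` defaults to every calendar day of the observed
    study period.
    """
    if dates is None:
        start, end = subject.study_period()
        n_days = (end - start).days
        dates = [start.date() + dt.timedelta(days=i) for i in range(n_days)]
    dates = pd.Index(dates)

    frame = pd.DataFrame(index=dates, columns=list(BASIC_FEATURES),
                         dtype=float)

    steps = subject.streams.get("steps")
    if steps is not None and len(steps.samples):
        day_label, bed_label = _zone_labels(steps.samples.index, zones)
        values = steps.samples.to_numpy(dtype=float)
        frame["steps_during_daytime"] = _grouped(values, day_label, dates, "sum")
        frame["steps_during_bedtime"] = _grouped(values, bed_label, dates, "sum")
        whole_day = steps.samples.index.values.astype("datetime64[D]")
        frame["total_daily_steps"] = _grouped(values, whole_day, dates, "sum")

    light = subject.streams.get("light")
    if light is not None and len(light.samples):
        day_label, bed_label = _zone_labels(light.samples.index, zones)
        values = light.samples.to_numpy(dtype=float)
        frame["light_exposure_during_daytime"] = _grouped(
            values, day_label, dates, "mean")
        frame["light_exposure_during_bedtime"] = _grouped(
            values, bed_label, dates, "mean")

    hr = subject.streams.get("heart_rate")
    if hr is not None and len(hr.samples):
        day_label, bed_label = _zone_labels(hr.samples.index, zones)
        values = hr.samples.to_numpy(dtype=float)
        frame["mean_daytime_heart_rate"] = _grouped(values, day_label, dates, "mean")
        frame["mean_bedtime_heart_rate"] = _grouped(values, bed_label, dates, "mean")
        for date in dates:
            end_time = pd.Timestamp(date) + pd.Timedelta(hours=evaluation_hour)
            # a day with no wear gets no rhythm features, even though the
            # trailing window could be fit from earlier days alone
            if not len(hr.window(pd.Timestamp(date), end_time)):
                continue
            fit = fit_cosinor(hr, end_time, window_hours=cosinor_window_hours)
            if fit is not None:
                frame.at[date, "cr_amplitude"] = fit.amplitude
                frame.at[date, "cr_acrophase_distance"] = fit.acrophase_distance

    by_date = subject.sleep_by_date()
    for date in dates:
        rec = by_date.get(date)
        if rec is None:
            continue
        frame.at[date, "sleep_efficiency"] = rec.efficiency
        frame.at[date, "sleep_onset_dev"] = abs(
            (rec.onset - zones.ideal_onset(date)).total_seconds()) / 60.0
        frame.at[date, "sleep_offset_dev"] = abs(
            (rec.offset - zones.ideal_offset(date)).total_seconds()) / 60.0
        frame.at[date, "sleep_duration"] = rec.duration_hours

    return frame
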