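"""Synthetic wearable cohorts with known ground truth.

Emulates the data a two-group relapse-monitoring study collects:
minute-level heart rate following a 24-h cosine rhythm with
subject-specific MESOR/amplitude/acrophase plus Gaussian noise,
Poisson step counts and gamma-distributed ambient light with distinct
day/night means, nightly sleep records jittered around the ideal
bed/wake times, daily mood-chart entries, hour-blocked wear gaps, and
per-subject annual mood-episode counts with a configurable true group
rate ratio — so every downstream stage (cosinor fit, H-scores, DGC,
adherence, GLM) has a recoverable target recorded in the ground truth.

Everything is driven by one cohort seed; subject ``i`` uses the derived
seed ``seed + i`` so individual subjects are independently reproducible.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .hscore import DEFAULT_ZONES, TimeZones
from .io import write_subject
from .records import (
    BoundaryError,
    EpisodeRecord,
    MoodEntry,
    SensorStream,
    SleepRecord,
    SubjectRecord,
)

START_DATE = dt.date(2023, 1, 1)
MINUTES_PER_DAY = 1440

EPISODE_TYPE_PROBS = {"depressive": 0.6, "manic": 0.2, "hypomanic": 0.2}


class CohortSpecError(ValueError):
    """A cohort specification field violates its invariant."""


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    Defaults describe the study conditions emulated throughout the
    package: a 10 vs 33 subject two-group cohort observed for a year,
    an adult daytime-peaking heart-rate rhythm (MESOR 70 bpm, amplitude
    10 bpm, acrophase 14:00, noise SD 5 bpm), day-concentrated steps
    and light, half-hour sleep-timing jitter, 85% hourly wear
    probability, 4 control episodes/year and a true intervention rate
    ratio of 0.4 with 30-day mean episode duration.
    """

    n_crm: int = 10
    n_control: int = 33
    days: int = 365
    hr_mesor: float = 70.0
    hr_amplitude: float = 10.0
    hr_acrophase: float = 14.0  # clock hours
    hr_noise_sd: float = 5.0
    hr_mesor_sd: float = 4.0       # between-subject spread
    hr_amplitude_sd: float = 1.5
    hr_acrophase_sd: float = 1.0
    activity_day_rate: float = 10.0   # mean steps/min
    activity_night_rate: float = 0.2
    light_day_lux: float = 300.0
    light_night_lux: float = 5.0
    sleep_onset_jitter_sd: float = 30.0  # minutes
    sleep_offset_jitter_sd: float = 30.0
    sleep_efficiency_mean: float = 0.90
    wear_prob: float = 0.85
    episode_rate_control: float = 4.0  # episodes/year
    true_rate_ratio: float = 0.4
    duration_mean_days: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = ("hr_noise_sd", "hr_mesor_sd", "hr_amplitude_sd",
                  "hr_acrophase_sd", "activity_day_rate",
                  "activity_night_rate", "light_day_lux", "light_night_lux",
                  "sleep_onset_jitter_sd", "sleep_offset_jitter_sd",
                  "episode_rate_control", "hr_amplitude")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise CohortSpecError(f"{name} must be >= 0")
        if self.n_crm < 0 or self.n_control < 0:
            raise CohortSpecError("group sizes must be >= 0")
        if not 0.0 <= self.wear_prob <= 1.0:
            raise CohortSpecError("wear_prob must be in [0, 1]")
        if self.true_rate_ratio <= 0:
            raise CohortSpecError("true_rate_ratio must be > 0")
        if self.duration_mean_days < 1:
            raise CohortSpecError("duration_mean_days must be >= 1")
        if self.days < 13:
            raise CohortSpecError(
                "days must be >= 13 (longest feature window + 1)")
        if not 0 < self.sleep_efficiency_mean <= 1:
            raise CohortSpecError("sleep_efficiency_mean must be in (0, 1]")


@dataclass
class SubjectTruth:
    """Realised generative parameters for one subject."""

    mesor: float
    amplitude: float
    acrophase: float
    alert_days: list[int] = field(default_factory=list)
    step_shift: float = 0.0   # steps/min added to daytime post-alert
    light_shift: float = 0.0  # lux added to daytime post-alert


@dataclass
class GroundTruth:
    """Recovery oracle for a generated cohort."""

    true_rate_ratio: float
    subjects: dict[str, SubjectTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {"true_rate_ratio": self.true_rate_ratio,
                   "subjects": {k: asdict(v) for k, v in self.subjects.items()}}
        return json.dumps(payload, indent=1, sort_keys=True)


def _subject_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(spec.seed + index)


def _minute_index(days: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(START_DATE)
    return pd.date_range(start, periods=days * MINUTES_PER_DAY, freq="min")


def _wear_mask(rng: np.random.Generator, days: int,
               wear_prob: float) -> np.ndarray:
    """Boolean minute mask; whole clock hours are worn or unworn,
    matching the episodic on/off-wrist behaviour of a wrist tracker."""
    hours_worn = rng.random(days * 24) < wear_prob
    return np.repeat(hours_worn, 60)


def _generate_streams(rng: np.random.Generator, spec: CohortSpec,
                      truth: SubjectTruth, subject_id: str,
                      zones: TimeZones) -> dict[str, SensorStream]:
    idx = _minute_index(spec.days)
    tod = (np.arange(len(idx)) % MINUTES_PER_DAY) / 60.0
    day_zone = (tod >= zones.sunrise_hours) & (tod < zones.sunset_hours)

    hr = (truth.mesor
          + truth.amplitude * np.cos(2 * np.pi * (tod - truth.acrophase) / 24.0))
    if spec.hr_noise_sd > 0:
        hr = hr + rng.normal(0.0, spec.hr_noise_sd, len(idx))
    hr = np.clip(hr, 0.0, None)

    step_rate = np.where(day_zone, spec.activity_day_rate,
                         spec.activity_night_rate)
    steps = rng.poisson(step_rate).astype(float)

    light_mean = np.where(day_zone, spec.light_day_lux, spec.light_night_lux)
    # gamma(shape=2) keeps lux nonnegative and right-skewed like real
    # ambient light, with the requested mean
    light = rng.gamma(2.0, light_mean / 2.0)

    mask = _wear_mask(rng, spec.days, spec.wear_prob)
    streams = {}
    for modality, values in (("heart_rate", hr), ("steps", steps),
                             ("light", light)):
        streams[modality] = SensorStream(
            subject_id, modality,
            pd.Series(values[mask], index=idx[mask], dtype=float))
    return streams


def _generate_sleep(rng: np.random.Generator, spec: CohortSpec,
                    zones: TimeZones) -> list[SleepRecord]:
    records = []
    eff_mean = spec.sleep_efficiency_mean
    # beta with concentration 20 around the requested mean
    a, b = 20.0 * eff_mean, 20.0 * (1.0 - eff_mean) + 1e-9
    for d in range(1, spec.days):
        date = START_DATE + dt.timedelta(days=d)
        onset = (zones.ideal_onset(date)
                 + pd.Timedelta(minutes=float(
                     rng.normal(0.0, spec.sleep_onset_jitter_sd))))
        offset = (zones.ideal_offset(date)
                  + pd.Timedelta(minutes=float(
                      rng.normal(0.0, spec.sleep_offset_jitter_sd))))
        if offset <= onset:  # extreme jitter draw; keep the night valid
            offset = onset + pd.Timedelta(hours=4)
        eff = float(np.clip(rng.beta(a, b), 0.0, 1.0))
        records.append(SleepRecord(date, onset, offset, eff))
    return records


def _generate_mood(rng: np.random.Generator, days: int) -> list[MoodEntry]:
    scores = np.clip(np.round(rng.normal(0.0, 1.0, days)), -3, 3).astype(int)
    return [MoodEntry(START_DATE + dt.timedelta(days=d), int(s))
            for d, s in enumerate(scores)]


def _generate_episodes(rng: np.random.Generator, spec: CohortSpec,
                       is_crm: bool) -> list[EpisodeRecord]:
    rate = spec.episode_rate_control * (spec.true_rate_ratio if is_crm else 1.0)
    n = rng.poisson(rate * spec.days / 365.0)
    last_day = spec.days - 1
    episodes: dict[str, list[tuple[int, int]]] = {t: [] for t in
                                                  EPISODE_TYPE_PROBS}
    types = list(EPISODE_TYPE_PROBS)
    probs = list(EPISODE_TYPE_PROBS.values())
    for _ in range(n):
        etype = types[rng.choice(len(types), p=probs)]
        start = int(rng.integers(0, spec.days))
        duration = int(rng.geometric(1.0 / spec.duration_mean_days))
        end = min(start + duration - 1, last_day)
        episodes[etype].append((start, end))
    out: list[EpisodeRecord] = []
    for etype, spans in episodes.items():
        prev_end = -1
        for start, end in sorted(spans):
            start = max(start, prev_end + 1)  # enforce per-type non-overlap
            if start > min(end, last_day):
                continue
            prev_end = end
            out.append(EpisodeRecord(
                etype, START_DATE + dt.timedelta(days=start),
                START_DATE + dt.timedelta(days=end)))
    return sorted(out, key=lambda e: (e.start, e.type))


def _generate_covariates(rng: np.random.Generator) -> dict:
    age = float(np.round(np.clip(rng.normal(28.0, 8.0), 18.0, 65.0), 1))
    onset = float(np.round(np.clip(rng.normal(17.0, 5.0), 8.0, age), 1))
    return {
        "gender": "male" if rng.random() < 0.4 else "female",
        "age": age,
        "diagnosis": ["BD-I", "BD-II", "MDD"][rng.choice(3, p=[0.45, 0.25, 0.30])],
        "first_onset_type": ["depressive", "manic", "hypomanic"][
            rng.choice(3, p=[0.85, 0.10, 0.05])],
        "age_first_onset": onset,
        "age_first_visit": float(np.round(min(onset + rng.exponential(4.0), age), 1)),
        "n_prev_admissions": int(rng.poisson(1.2)),
        "n_prev_depressive": int(rng.poisson(8.0)),
        "n_prev_manic": int(rng.poisson(2.0)),
        "n_prev_hypomanic": int(rng.poisson(5.0)),
    }


def generate_subject(spec: CohortSpec, index: int, group: str,
                     zones: TimeZones = DEFAULT_ZONES,
                     ) -> tuple[SubjectRecord, SubjectTruth]:
    """Generate one subject with the derived seed ``spec.seed + index``."""
    rng = _subject_rng(spec, index)
    subject_id = f"S{index:03d}"
    truth = SubjectTruth(
        mesor=float(rng.normal(spec.hr_mesor, spec.hr_mesor_sd))
        if spec.hr_mesor_sd > 0 else spec.hr_mesor,
        amplitude=float(max(0.5, rng.normal(spec.hr_amplitude,
                                            spec.hr_amplitude_sd)))
        if spec.hr_amplitude_sd > 0 else spec.hr_amplitude,
        acrophase=float(rng.normal(spec.hr_acrophase, spec.hr_acrophase_sd)
                        % 24.0)
        if spec.hr_acrophase_sd > 0 else spec.hr_acrophase,
    )
    streams = _generate_streams(rng, spec, truth, subject_id, zones)
    subject = SubjectRecord(
        subject_id=subject_id, group=group,
        streams=streams,
        sleep=_generate_sleep(rng, spec, zones),
        mood=_generate_mood(rng, spec.days),
        episodes=_generate_episodes(rng, spec, group == "CRM"),
        **_generate_covariates(rng))
    return subject, truth


def generate_cohort(spec: CohortSpec,
                    zones: TimeZones = DEFAULT_ZONES,
                    ) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate the full two-group cohort; reproducible under the seed."""
    spec.validate()
    truth = GroundTruth(true_rate_ratio=spec.true_rate_ratio)
    subjects = []
    for i in range(spec.n_crm + spec.n_control):
        group = "CRM" if i < spec.n_crm else "non-CRM"
        subject, sub_truth = generate_subject(spec, i, group, zones)
        subjects.append(subject)
        truth.subjects[subject.subject_id] = sub_truth
    return subjects, truth


def inject_post_alert_shift(subject: SubjectRecord, alert_day: int,
                            step_shift: float = 0.0,
                            light_shift: float = 0.0,
                            rng: Optional[np.random.Generator] = None,
                            zones: TimeZones = DEFAULT_ZONES,
                            truth: Optional[SubjectTruth] = None,
                            ) -> SubjectRecord:
    """Raise daytime step/light means from ``alert_day + 1`` onward.

    Models the behaviour change an effective alert produces: extra
    Poisson steps at ``step_shift`` per daytime minute and a constant
    ``light_shift`` lux added to daytime light samples. Pre-alert data
    are untouched. Requires ``alert_day +/- 3`` inside the study period
    so the surrounding change statistic is computable.
    """
    if not (np.isfinite(step_shift) and np.isfinite(light_shift)):
        raise ValueError("shift sizes must be finite")
    start, end = subject.study_period()
    n_days = (end - start).days
    if alert_day - 3 < 0 or alert_day + 3 > n_days - 1:
        raise BoundaryError(
            f"alert_day {alert_day} within 3 days of the study boundary "
            f"(period is {n_days} days)")
    if rng is None:
        rng = np.random.default_rng(0)

    cutoff = start + pd.Timedelta(days=alert_day + 1)
    streams = dict(subject.streams)

    def _daytime_after(index: pd.DatetimeIndex) -> np.ndarray:
        ns = index.values.astype("datetime64[ns]")
        days = ns.astype("datetime64[D]")
        tod = (ns - days).astype("timedelta64[s]").astype(float) / 3600.0
        in_day = (tod >= zones.sunrise_hours) & (tod < zones.sunset_hours)
        return in_day & np.asarray(index >= cutoff)

    if step_shift and "steps" in streams:
        s = streams["steps"].samples.copy()
        sel = _daytime_after(s.index)
        s.iloc[sel] = s.iloc[sel] + rng.poisson(step_shift, sel.sum())
        streams["steps"] = SensorStream(subject.subject_id, "steps", s)
    if light_shift and "light" in streams:
        s = streams["light"].samples.copy()
        sel = _daytime_after(s.index)
        s.iloc[sel] = s.iloc[sel] + light_shift
        streams["light"] = SensorStream(subject.subject_id, "light", s)

    if truth is not None:
        truth.alert_days.append(alert_day)
        truth.step_shift = step_shift
        truth.light_shift = light_shift
    return subject.with_streams(streams)


def simulate_episode_counts(n_crm: int, n_control: int, rate_control: float,
                            rate_ratio: float,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Count-level shortcut for GLM calibration studies: annual episode
    counts only, no sensor streams."""
    counts = np.concatenate([
        rng.poisson(rate_control * rate_ratio, n_crm),
        rng.poisson(rate_control, n_control)])
    groups = ["CRM"] * n_crm + ["non-CRM"] * n_control
    return pd.DataFrame({"group": groups,
                         "total_mood_episodes": counts.astype(int)})


def write_cohort(subjects: list[SubjectRecord], truth: GroundTruth,
                 outdir: Path | str) -> Path:
    """Write one directory per subject plus ``ground_truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for subject in subjects:
        write_subject(subject, outdir / subject.subject_id)
    (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
    return outdir
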