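"""Core domain records for wearable digital-phenotype studies.

The containers here mirror what a consumer wrist tracker plus a daily
mood-chart app actually yield: minute-level sensor streams (heart rate,
step counts, ambient light), nightly sleep records, a daily self-rated
mood score on the -3..+3 scale, clinician-confirmed mood-episode
intervals, and baseline clinical covariates.

All timestamps are naive local clock time: every downstream quantity
(bedtime/daytime windows, acrophase distance from midday) is defined on
the local clock, so time-zone arithmetic would only add failure modes.
Dates denote calendar days ``[00:00, 24:00)``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

MODALITIES = ("heart_rate", "steps", "light")

#: Physiologic plausibility bounds for heart rate (beats/min). Samples
#: outside this range are flagged, never dropped: they may indicate
#: device artefacts worth inspecting, but silent deletion would bias
#: wear-time accounting.
HR_PHYSIO_RANGE = (20.0, 250.0)

MOOD_SCALE = (-3, 3)

EPISODE_TYPES = ("depressive", "manic", "hypomanic")

DIAGNOSES = ("MDD", "BD-I", "BD-II")

GROUPS = ("CRM", "non-CRM")


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; carries file and line context."""

    def __init__(self, message: str, file: Optional[str] = None,
                 line: Optional[int] = None):
        self.file = file
        self.line = line
        loc = ""
        if file is not None:
            loc = f" [{file}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class BoundaryError(ValueError):
    """An operation would reach outside the observed study period."""


@dataclass
class SensorStream:
    """Timestamped samples of one modality for one subject.

    ``samples`` is a float Series on a strictly increasing naive
    DatetimeIndex. Units: heart_rate beats/min, steps count/min,
    light lux.
    """

    subject_id: str
    modality: str
    samples: pd.Series
    n_physio_flagged: int = 0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        s = self.samples
        if not isinstance(s.index, pd.DatetimeIndex):
            raise ValidationError("samples must be indexed by timestamps")
        if len(s) and not s.index.is_monotonic_increasing:
            raise ValidationError(
                f"{self.modality}: timestamps must be increasing")
        if len(s) and s.index.has_duplicates:
            raise ValidationError(
                f"{self.modality}: duplicate timestamps")
        if len(s) and (s.to_numpy() < 0).any():
            raise ValidationError(f"{self.modality}: negative values")
        if self.modality == "heart_rate" and len(s):
            lo, hi = HR_PHYSIO_RANGE
            v = s.to_numpy()
            self.n_physio_flagged = int(((v < lo) | (v > hi)).sum())

    def window(self, start: pd.Timestamp, end: pd.Timestamp) -> pd.Series:
        """Samples in the half-open interval [start, end)."""
        idx = self.samples.index
        i = idx.searchsorted(start, side="left")
        j = idx.searchsorted(end, side="left")
        return self.samples.iloc[i:j]


@dataclass(frozen=True)
class SleepRecord:
    """One night of sleep, keyed by the calendar date of waking.

    ``efficiency`` is the fraction of the sleep interval spent asleep
    without awakening.
    """

    date: dt.date
    onset: pd.Timestamp
    offset: pd.Timestamp
    efficiency: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValidationError(
                f"sleep {self.date}: offset must follow onset")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValidationError(
                f"sleep {self.date}: efficiency {self.efficiency} not in [0,1]")

    @property
    def duration_hours(self) -> float:
        return (self.offset - self.onset).total_seconds() / 3600.0


@dataclass(frozen=True)
class MoodEntry:
    """Daily self-rated mood on the -3..+3 chart scale."""

    date: dt.date
    score: int

    def __post_init__(self) -> None:
        lo, hi = MOOD_SCALE
        if not (isinstance(self.score, (int, np.integer)) and lo <= self.score <= hi):
            raise ValidationError(
                f"mood {self.date}: score {self.score} not in {lo}..{hi}")


@dataclass(frozen=True)
class EpisodeRecord:
    """A clinician-confirmed mood episode, recorded as whole calendar days."""

    type: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.type not in EPISODE_TYPES:
            raise ValidationError(f"unknown episode type {self.type!r}")
        if self.end < self.start:
            raise ValidationError(
                f"episode {self.type} ends {self.end} before start {self.start}")

    @property
    def duration_days(self) -> int:
        # whole-day records: a one-day episode has start == end
        return (self.end - self.start).days + 1


def check_episodes_nonoverlapping(episodes: list[EpisodeRecord]) -> None:
    """Raise ValidationError if two same-type episodes overlap."""
    by_type: dict[str, list[EpisodeRecord]] = {}
    for ep in episodes:
        by_type.setdefault(ep.type, []).append(ep)
    for etype, eps in by_type.items():
        eps = sorted(eps, key=lambda e: e.start)
        for a, b in zip(eps, eps[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"overlapping {etype} episodes: "
                    f"{a.start}..{a.end} and {b.start}..{b.end}")


@dataclass(frozen=True)
class WearRate:
    """Worn hours over denominator hours for some period."""

    worn_hours: int
    denominator_hours: float

    @property
    def rate(self) -> float:
        if self.denominator_hours <= 0:
            return 0.0
        return self.worn_hours / self.denominator_hours


@dataclass
class SubjectRecord:
    """One study subject: covariates plus all observed data."""

    subject_id: str
    group: str
    gender: str
    age: float
    diagnosis: str
    first_onset_type: str
    age_first_onset: float
    age_first_visit: float
    n_prev_admissions: int
    n_prev_depressive: int
    n_prev_manic: int
    n_prev_hypomanic: int
    streams: dict[str, SensorStream] = field(default_factory=dict)
    sleep: list[SleepRecord] = field(default_factory=list)
    mood: list[MoodEntry] = field(default_factory=list)
    episodes: list[EpisodeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(f"unknown diagnosis {self.diagnosis!r}")
        for name in ("age", "age_first_onset", "age_first_visit",
                     "n_prev_admissions", "n_prev_depressive",
                     "n_prev_manic", "n_prev_hypomanic"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        check_episodes_nonoverlapping(self.episodes)

    def covariates(self) -> dict:
        return {
            "gender": self.gender,
            "age": self.age,
            "diagnosis": self.diagnosis,
            "first_onset_type": self.first_onset_type,
            "age_first_onset": self.age_first_onset,
            "age_first_visit": self.age_first_visit,
            "n_prev_admissions": self.n_prev_admissions,
            "n_prev_depressive": self.n_prev_depressive,
            "n_prev_manic": self.n_prev_manic,
            "n_prev_hypomanic": self.n_prev_hypomanic,
        }

    def sleep_by_date(self) -> dict[dt.date, SleepRecord]:
        return {r.date: r for r in self.sleep}

    def study_period(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Span of observed sensor data, rounded out to whole days."""
        starts, ends = [], []
        for st in self.streams.values():
            if len(st.samples):
                starts.append(st.samples.index[0])
                ends.append(st.samples.index[-1])
        if not starts:
            raise ValidationError(f"{self.subject_id}: no sensor data")
        start = min(starts).normalize()
        end = (max(ends).normalize() + pd.Timedelta(days=1))
        return start, end

    def with_streams(self, streams: dict[str, SensorStream]) -> "SubjectRecord":
        return replace(self, streams=streams)


def subjects_equal(a: SubjectRecord, b: SubjectRecord) -> bool:
    """Value equality of two subjects, including their sensor streams.

    (Dataclass ``==`` is unusable here because pandas Series equality
    is elementwise.)
    """
    if (a.subject_id, a.group, a.covariates()) != (b.subject_id, b.group,
                                                   b.covariates()):
        return False
    if set(a.streams) != set(b.streams):
        return False
    for modality, stream in a.streams.items():
        other = b.streams[modality].samples
        if not (len(stream.samples) == len(other)
                and stream.samples.index.equals(other.index)
                and np.array_equal(stream.samples.to_numpy(),
                                   other.to_numpy())):
            return False
    return (a.sleep == b.sleep and a.mood == b.mood
            and a.episodes == b.episodes)
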