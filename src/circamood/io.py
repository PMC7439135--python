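"""Reading and writing subject directories, wear-rate computation and the
compliance inclusion filter.

On disk a subject is a directory of plain text files::

    heart_rate.csv  steps.csv  light.csv   # timestamp,value (ISO-8601)
    sleep.csv                              # date,onset,offset,efficiency
    mood.csv                               # date,score
    episodes.csv                           # type,start_date,end_date
    cohort.json                            # group + clinical covariates

Readers tolerate out-of-order sensor rows (sorted with a warning) but
reject anything violating a domain invariant, with file and line context.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import (
    MODALITIES,
    EpisodeRecord,
    MoodEntry,
    ParseError,
    SensorStream,
    SleepRecord,
    SubjectRecord,
    ValidationError,
    WearRate,
)

logger = logging.getLogger(__name__)

STREAM_FILES = {m: f"{m}.csv" for m in MODALITIES}

#: Annual wear-rate threshold below which a subject is excluded.
#: The rule is strict: exactly 60% is retained.
COMPLIANCE_THRESHOLD = 0.60


# ---------------------------------------------------------------------------
# writing

def write_subject(subject: SubjectRecord, path: Path | str) -> Path:
    """Write one subject directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for modality, fname in STREAM_FILES.items():
        stream = subject.streams.get(modality)
        with open(path / fname, "w") as fh:
            fh.write("timestamp,value\n")
            if stream is not None and len(stream.samples):
                stamps = stream.samples.index.strftime("%Y-%m-%dT%H:%M:%S")
                values = [repr(v) for v in stream.samples.to_numpy().tolist()]
                fh.writelines(f"{t},{v}\n" for t, v in zip(stamps, values))
    with open(path / "sleep.csv", "w") as fh:
        fh.write("date,onset,offset,efficiency\n")
        for rec in subject.sleep:
            fh.write(f"{rec.date.isoformat()},{rec.onset.isoformat()},"
                     f"{rec.offset.isoformat()},{rec.efficiency!r}\n")
    with open(path / "mood.csv", "w") as fh:
        fh.write("date,score\n")
        for entry in subject.mood:
            fh.write(f"{entry.date.isoformat()},{entry.score}\n")
    with open(path / "episodes.csv", "w") as fh:
        fh.write("type,start_date,end_date\n")
        for ep in subject.episodes:
            fh.write(f"{ep.type},{ep.start.isoformat()},{ep.end.isoformat()}\n")
    meta = {"subject_id": subject.subject_id, "group": subject.group,
            **subject.covariates()}
    with open(path / "cohort.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# reading

def _parse_timestamp(text: str, file: str, line: int) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(text)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"malformed timestamp {text!r}: {exc}", file, line)
    if ts.tzinfo is not None:
        raise ParseError(f"timestamp {text!r} must be naive local time",
                         file, line)
    return ts


def _parse_date(text: str, file: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise ParseError(f"malformed date {text!r}: {exc}", file, line)


def _read_rows(path: Path, expected_header: Sequence[str]):
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",") != list(expected_header):
            raise ParseError(
                f"expected header {','.join(expected_header)!r}, got {header!r}",
                str(path), 1)
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            parts = raw.split(",")
            if len(parts) != len(expected_header):
                raise ParseError(f"expected {len(expected_header)} fields, "
                                 f"got {len(parts)}", str(path), lineno)
            yield lineno, parts


def read_stream(path: Path | str, subject_id: str, modality: str) -> SensorStream:
    path = Path(path)
    stamps: list[pd.Timestamp] = []
    values: list[float] = []
    for lineno, (ts_text, v_text) in _read_rows(path, ("timestamp", "value")):
        stamps.append(_parse_timestamp(ts_text, str(path), lineno))
        try:
            values.append(float(v_text))
        except ValueError as exc:
            raise ParseError(f"malformed value {v_text!r}: {exc}",
                             str(path), lineno)
    samples = pd.Series(values, index=pd.DatetimeIndex(stamps), dtype=float)
    if len(samples) and not samples.index.is_monotonic_increasing:
        warnings.warn(f"{path}: out-of-order rows, sorting", stacklevel=2)
        samples = samples.sort_index()
    try:
        return SensorStream(subject_id, modality, samples)
    except ValidationError as exc:
        raise ParseError(str(exc), str(path))


def read_subject(path: Path | str) -> SubjectRecord:
    """Read a subject directory back into a :class:`SubjectRecord`."""
    path = Path(path)
    with open(path / "cohort.json") as fh:
        meta = json.load(fh)

    streams = {}
    for modality, fname in STREAM_FILES.items():
        f = path / fname
        if f.exists():
            streams[modality] = read_stream(f, meta["subject_id"], modality)

    sleep = []
    f = path / "sleep.csv"
    if f.exists():
        for lineno, (d, onset, offset, eff) in _read_rows(
                f, ("date", "onset", "offset", "efficiency")):
            try:
                sleep.append(SleepRecord(
                    _parse_date(d, str(f), lineno),
                    _parse_timestamp(onset, str(f), lineno),
                    _parse_timestamp(offset, str(f), lineno),
                    float(eff)))
            except (ValidationError, ValueError) as exc:
                raise ParseError(str(exc), str(f), lineno)

    mood = []
    f = path / "mood.csv"
    if f.exists():
        for lineno, (d, score) in _read_rows(f, ("date", "score")):
            try:
                mood.append(MoodEntry(_parse_date(d, str(f), lineno),
                                      int(score)))
            except (ValidationError, ValueError) as exc:
                raise ParseError(str(exc), str(f), lineno)

    episodes = []
    f = path / "episodes.csv"
    if f.exists():
        for lineno, (etype, start, end) in _read_rows(
                f, ("type", "start_date", "end_date")):
            try:
                episodes.append(EpisodeRecord(etype,
                                              _parse_date(start, str(f), lineno),
                                              _parse_date(end, str(f), lineno)))
            except ValidationError as exc:
                raise ParseError(str(exc), str(f), lineno)

    try:
        return SubjectRecord(
            subject_id=meta["subject_id"], group=meta["group"],
            gender=meta["gender"], age=meta["age"],
            diagnosis=meta["diagnosis"],
            first_onset_type=meta["first_onset_type"],
            age_first_onset=meta["age_first_onset"],
            age_first_visit=meta["age_first_visit"],
            n_prev_admissions=meta["n_prev_admissions"],
            n_prev_depressive=meta["n_prev_depressive"],
            n_prev_manic=meta["n_prev_manic"],
            n_prev_hypomanic=meta["n_prev_hypomanic"],
            streams=streams, sleep=sleep, mood=mood, episodes=episodes)
    except ValidationError as exc:
        raise ParseError(str(exc), str(path))


def read_cohort(path: Path | str) -> list[SubjectRecord]:
    """Read every subject directory under ``path`` (sorted by name)."""
    path = Path(path)
    subjects = []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        if (sub / "cohort.json").exists():
            subjects.append(read_subject(sub))
    return subjects


# ---------------------------------------------------------------------------
# wear rate and compliance

def wear_rate(stream: Optional[SensorStream],
              period: tuple[pd.Timestamp, pd.Timestamp]) -> WearRate:
    """Worn hours over total hours in ``[start, end)``.

    An hour counts as worn iff it contains at least one sample. Heart
    rate is the intended modality: a wrist tracker samples it
    continuously only while on-wrist, so its presence is the cleanest
    wear signal available without a dedicated wear-detection channel.
    """
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    denom = (end - start).total_seconds() / 3600.0
    if denom <= 0:
        raise ValueError("period must be non-empty")
    if stream is None or not len(stream.samples):
        return WearRate(0, denom)
    win = stream.window(start, end)
    worn = win.index.floor("h").nunique()
    return WearRate(int(worn), denom)


def annual_wear_rate(subject: SubjectRecord,
                     start: Optional[pd.Timestamp] = None) -> WearRate:
    """Wear rate over one 365-day year (8760-hour denominator)."""
    if start is None:
        start = subject.study_period()[0]
    start = pd.Timestamp(start)
    return wear_rate(subject.streams.get("heart_rate"),
                     (start, start + pd.Timedelta(days=365)))


def apply_compliance_filter(
    subjects: Iterable[SubjectRecord],
    threshold: float = COMPLIANCE_THRESHOLD,
    start: Optional[pd.Timestamp] = None,
) -> tuple[list[SubjectRecord], list[tuple[str, float]]]:
    """Retain subjects whose annual wear rate is >= ``threshold``.

    The boundary is inclusive: the exclusion rule drops strictly
    sub-threshold subjects only. Returns (included, exclusion log),
    the log holding ``(subject_id, rate)`` for every excluded subject.
    """
    included: list[SubjectRecord] = []
    excluded: list[tuple[str, float]] = []
    for subject in subjects:
        rate = annual_wear_rate(subject, start).rate
        if rate >= threshold:
            included.append(subject)
        else:
            excluded.append((subject.subject_id, rate))
            logger.info("excluding %s: annual wear rate %.3f < %.2f",
                        subject.subject_id, rate, threshold)
    return included, excluded
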