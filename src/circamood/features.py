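"""Digital-phenotype feature vectors: 13 basic daily features extended to
130 by trailing-window summaries, plus a pluggable mood-predictor
interface.

For each basic feature and each trailing window of n in {3, 6, 12} days
(inclusive of the focal day) three summaries are added: the mean, the
sample standard deviation (ddof=1) and the gradient — the OLS slope of
feature value against day index 0..n-1 within the window. That yields
13 + 13*3*3 = 130 named columns. A window summary needs at least two
available days; otherwise the slot is NaN (no imputation). The column
schema is invariant: every vector has exactly 130 feature slots
regardless of missingness.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .hscore import DEFAULT_ZONES, TimeZones
from .records import BoundaryError, SubjectRecord
from .summaries import BASIC_FEATURES, daily_summaries

WINDOWS = (3, 6, 12)
STATS = ("mean", "sd", "gradient")
MIN_WINDOW_DAYS = 2

MOOD_STATES = ("stable", "depressive-risk", "manic-risk")
UNAVAILABLE = "unavailable"


def feature_names(basic: Sequence[str] = BASIC_FEATURES) -> list[str]:
    """The full 130-name schema: basic names then `<basic>_<n>d_<stat>`."""
    names = list(basic)
    for feat in basic:
        for n in WINDOWS:
            for stat in STATS:
                names.append(f"{feat}_{n}d_{stat}")
    return names


def basic_features(subject: SubjectRecord, date: dt.date,
                   zones: TimeZones = DEFAULT_ZONES) -> dict[str, float]:
    """The 13 basic features for one subject-day.

    Raises :class:`BoundaryError` for a date outside the study period.
    """
    start, end = subject.study_period()
    if not (start.date() <= date < end.date() + dt.timedelta(days=1)):
        raise BoundaryError(f"{date} outside study period "
                            f"[{start.date()}, {end.date()})")
    row = daily_summaries(subject, [date], zones=zones).iloc[0]
    return {k: float(row[k]) for k in BASIC_FEATURES}


def _window_slope(values: np.ndarray) -> float:
    """OLS slope of values against position 0..n-1, skipping NaNs."""
    idx = np.arange(len(values), dtype=float)
    mask = np.isfinite(values)
    if mask.sum() < MIN_WINDOW_DAYS:
        return np.nan
    x, y = idx[mask], values[mask]
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    if denom == 0:
        return np.nan
    return float((xc * (y - y.mean())).sum() / denom)


def extend_features(daily: pd.DataFrame,
                    windows: Sequence[int] = WINDOWS,
                    stats: Sequence[str] = STATS) -> pd.DataFrame:
    """Extend a daily basic-feature frame to the full windowed schema.

    ``daily`` is indexed by date with the basic feature columns; each
    window trails and includes the focal date. Returns a frame with
    ``13 * (1 + len(windows)*len(stats))`` columns (130 by default).
    """
    basic = [c for c in daily.columns if c in BASIC_FEATURES]
    extended: dict[str, np.ndarray | list] = {}
    for feat in basic:
        col = daily[feat].to_numpy(dtype=float)
        for n in windows:
            # trailing windows padded with NaN at the start
            padded = np.concatenate([np.full(n - 1, np.nan), col])
            view = np.lib.stride_tricks.sliding_window_view(padded, n)
            finite = np.isfinite(view)
            counts = finite.sum(axis=1)
            enough = counts >= MIN_WINDOW_DAYS
            safe_counts = np.maximum(counts, 1)
            filled = np.where(finite, view, 0.0)
            means = filled.sum(axis=1) / safe_counts
            sq_dev = np.where(finite, (view - means[:, None]) ** 2, 0.0)
            sds = np.sqrt(sq_dev.sum(axis=1)
                          / np.maximum(safe_counts - 1, 1))
            means = np.where(enough, means, np.nan)
            sds = np.where(enough, sds, np.nan)
            if "mean" in stats:
                extended[f"{feat}_{n}d_mean"] = means
            if "sd" in stats:
                extended[f"{feat}_{n}d_sd"] = sds
            if "gradient" in stats:
                extended[f"{feat}_{n}d_gradient"] = [
                    _window_slope(view[i]) if enough[i] else np.nan
                    for i in range(len(view))]
    return pd.concat(
        [daily[basic], pd.DataFrame(extended, index=daily.index)], axis=1)


def extract_features(subject: SubjectRecord,
                     zones: TimeZones = DEFAULT_ZONES) -> pd.DataFrame:
    """Full 130-column feature frame for a subject's study period."""
    return extend_features(daily_summaries(subject, zones=zones))


# ---------------------------------------------------------------------------
# pluggable mood predictor

class MoodPredictor(Protocol):
    """Interface any 3-day-ahead mood-state predictor must satisfy."""

    def fit(self, features: pd.DataFrame, labels: Sequence[str]) -> "MoodPredictor":
        ...

    def predict(self, features: pd.DataFrame) -> list[str]:
        ...


class LogisticBaselinePredictor:
    """A deliberately simple multinomial-logistic baseline.

    Exists so the pipeline can be exercised end to end; it is a demo
    stand-in, not a validated clinical predictor. Rows whose feature
    slots are all missing yield the explicit ``"unavailable"`` label;
    remaining missing values are median-imputed from the training data.
    """

    def __init__(self, max_iter: int = 500, random_state: int = 0):
        self.max_iter = max_iter
        self.random_state = random_state
        self._model = None
        self._medians: Optional[pd.Series] = None

    def fit(self, features: pd.DataFrame, labels: Sequence[str]):
        from sklearn.linear_model import LogisticRegression

        labels = np.asarray(labels, dtype=object)
        usable = features.notna().any(axis=1).to_numpy()
        if not usable.any():
            raise ValueError("no rows with any available features")
        X = features.loc[usable]
        self._medians = X.median()
        X = X.fillna(self._medians).fillna(0.0)
        self._model = LogisticRegression(
            max_iter=self.max_iter, random_state=self.random_state)
        self._model.fit(X.to_numpy(dtype=float), labels[usable])
        return self

    def predict(self, features: pd.DataFrame) -> list[str]:
        if self._model is None:
            raise RuntimeError("predictor must be fit before predicting")
        out = [UNAVAILABLE] * len(features)
        usable = features.notna().any(axis=1).to_numpy()
        if usable.any():
            X = features.loc[usable].fillna(self._medians).fillna(0.0)
            preds = self._model.predict(X.to_numpy(dtype=float))
            j = 0
            for i in range(len(features)):
                if usable[i]:
                    out[i] = str(preds[j])
                    j += 1
        return out


def predict_mood(features: pd.DataFrame, predictor: MoodPredictor) -> list[str]:
    """Run a fitted predictor over feature vectors; abstains (returns
    ``"unavailable"``) for all-missing rows by predictor contract."""
    return predictor.predict(features)
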