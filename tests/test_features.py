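"""Daily summaries, the 130-feature schema, windowed extension oracle
equivalence, and the predictor interface."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from circamood import (
    LogisticBaselinePredictor,
    SensorStream,
    basic_features,
    daily_summaries,
    extend_features,
    feature_names,
    predict_mood,
)
from circamood.features import WINDOWS
from circamood.records import BoundaryError
from circamood.summaries import BASIC_FEATURES


def _daily_frame(values_by_feature, n_days):
    idx = [dt.date(2023, 1, 1) + dt.timedelta(days=i) for i in range(n_days)]
    frame = pd.DataFrame(index=pd.Index(idx), columns=list(BASIC_FEATURES),
                         dtype=float)
    for feat, vals in values_by_feature.items():
        frame[feat] = vals
    return frame


def test_schema_is_130_named_columns():
    names = feature_names()
    assert len(names) == 130
    assert len(set(names)) == 130
    assert names[:13] == list(BASIC_FEATURES)
    assert "cr_amplitude_6d_gradient" in names


def test_extension_always_emits_130_columns(tiny_cohort):
    subjects, _ = tiny_cohort
    daily = daily_summaries(subjects[0])
    extended = extend_features(daily)
    assert list(extended.columns) == feature_names()
    # schema invariant under missingness too
    gappy = daily.copy()
    gappy.iloc[5:9] = np.nan
    assert list(extend_features(gappy).columns) == feature_names()


def test_noiseless_subject_recovers_generator_amplitude(clean_subject):
    spec, subject, truth = clean_subject
    daily = daily_summaries(subject)
    settled = daily["cr_amplitude"].iloc[2:]  # first fits see <48 h
    assert np.allclose(settled, truth.amplitude, atol=1e-6)


def test_daytime_steps_match_independent_summation(clean_subject):
    _, subject, _ = clean_subject
    date = dt.date(2023, 1, 5)
    feats = basic_features(subject, date)
    raw = subject.streams["steps"].samples
    sel = raw[(raw.index >= pd.Timestamp("2023-01-05 06:30")) &
              (raw.index < pd.Timestamp("2023-01-05 18:30"))]
    assert feats["steps_during_daytime"] == sel.sum()


def test_fully_unworn_day_yields_all_missing(clean_subject):
    _, subject, _ = clean_subject
    gap = dt.date(2023, 1, 6)
    lo = pd.Timestamp("2023-01-05 22:30")  # cover bedtime window too
    hi = pd.Timestamp("2023-01-07 00:00")
    streams = {}
    for modality, stream in subject.streams.items():
        s = stream.samples
        keep = (s.index < lo) | (s.index >= hi)
        streams[modality] = SensorStream(subject.subject_id, modality, s[keep])
    import dataclasses
    stripped = dataclasses.replace(
        subject, streams=streams,
        sleep=[r for r in subject.sleep if r.date != gap])
    feats = basic_features(stripped, gap)
    assert all(np.isnan(v) for v in feats.values())


def test_date_outside_period_is_boundary_error(clean_subject):
    _, subject, _ = clean_subject
    with pytest.raises(BoundaryError):
        basic_features(subject, dt.date(2025, 1, 1))


def test_constant_feature_windows():
    frame = _daily_frame({"sleep_efficiency": [0.9] * 12}, 12)
    out = extend_features(frame)
    last = out.iloc[-1]
    for n in WINDOWS:
        assert last[f"sleep_efficiency_{n}d_mean"] == pytest.approx(0.9)
        assert last[f"sleep_efficiency_{n}d_sd"] == pytest.approx(0.0)
        assert last[f"sleep_efficiency_{n}d_gradient"] == pytest.approx(0.0)


def test_three_day_window_arithmetic():
    frame = _daily_frame({"total_daily_steps": [1.0, 2.0, 3.0]}, 3)
    last = extend_features(frame).iloc[-1]
    assert last["total_daily_steps_3d_mean"] == pytest.approx(2.0)
    assert last["total_daily_steps_3d_sd"] == pytest.approx(1.0)
    assert last["total_daily_steps_3d_gradient"] == pytest.approx(1.0)


def test_gradient_of_linear_series_equals_increment():
    frame = _daily_frame({"cr_amplitude": 2.5 * np.arange(15)}, 15)
    out = extend_features(frame)
    for n in WINDOWS:
        col = out[f"cr_amplitude_{n}d_gradient"].iloc[n - 1:]
        assert np.allclose(col, 2.5)


def test_windows_match_brute_force_oracle():
    """Random 20-day series with missing days against per-window
    recomputation from first principles."""
    rng = np.random.default_rng(5)
    values = rng.normal(100.0, 20.0, 20)
    values[rng.choice(20, size=5, replace=False)] = np.nan
    frame = _daily_frame({"total_daily_steps": values}, 20)
    out = extend_features(frame)
    for focal in range(20):
        for n in WINDOWS:
            window = values[max(0, focal - n + 1):focal + 1]
            if focal - n + 1 < 0:
                window = np.concatenate(
                    [np.full(n - focal - 1, np.nan), window])
            avail = np.isfinite(window)
            row = out.iloc[focal]
            if avail.sum() < 2:
                for stat in ("mean", "sd", "gradient"):
                    assert np.isnan(row[f"total_daily_steps_{n}d_{stat}"])
                continue
            y = window[avail]
            x = np.arange(n, dtype=float)[avail]
            slope = np.polyfit(x, y, 1)[0]
            assert row[f"total_daily_steps_{n}d_mean"] == pytest.approx(y.mean())
            assert row[f"total_daily_steps_{n}d_sd"] == pytest.approx(
                y.std(ddof=1))
            assert row[f"total_daily_steps_{n}d_gradient"] == pytest.approx(
                slope)


class TestPredictorInterface:
    def _separable(self, n=60):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({name: rng.normal(size=n)
                          for name in feature_names()[:5]})
        labels = np.where(X.iloc[:, 0] > 0, "depressive-risk", "stable")
        X.iloc[0] = np.nan  # one abstention row
        return X, labels

    def test_baseline_beats_chance_on_separable_labels(self):
        X, labels = self._separable()
        predictor = LogisticBaselinePredictor().fit(X.iloc[1:], labels[1:])
        preds = predict_mood(X.iloc[1:], predictor)
        accuracy = np.mean(np.asarray(preds) == labels[1:])
        assert accuracy > 0.8

    def test_all_missing_row_abstains(self):
        X, labels = self._separable()
        predictor = LogisticBaselinePredictor().fit(X, labels)
        assert predict_mood(X, predictor)[0] == "unavailable"

    def test_constant_predictor_conforms(self):
        class Constant:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return ["stable"] * len(X)

        X, _ = self._separable()
        preds = predict_mood(X, Constant().fit(X, None))
        assert len(preds) == len(X) and set(preds) == {"stable"}

    def test_unfitted_predictor_is_usage_error(self):
        X, _ = self._separable()
        with pytest.raises(RuntimeError):
            LogisticBaselinePredictor().predict(X)
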