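"""H-score formulas, normalisation, risk levels, feedback messages and
the warning-alert rules (including a 27-case brute-force oracle)."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circamood import (
    DailyHScores,
    NormalizationRef,
    act_h_score,
    cr_h_score,
    daily_average,
    evaluate_alerts,
    feedback_messages,
    le_h_score,
    normalize,
    sl_h_score,
)
from circamood.hscore import FIXED_BOUNDS, MESSAGE_CATALOG, personal_refs

from conftest import date_series

#: Identity references: N(x) == x on [0, 100], so formula arithmetic can
#: be asserted directly.
IDENTITY = {name: NormalizationRef(0.0, 100.0) for name in FIXED_BOUNDS}


class TestNormalize:
    ref = NormalizationRef(10.0, 30.0)

    @pytest.mark.parametrize("x,expected", [
        (10.0, 0.0), (30.0, 100.0), (20.0, 50.0),   # low, high, midpoint
        (-5.0, 0.0), (50.0, 100.0),                  # clamped
    ])
    def test_linear_map_with_clamping(self, x, expected):
        assert normalize(x, self.ref) == expected

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            NormalizationRef(5.0, 5.0)


@pytest.mark.parametrize("fn,args,expected", [
    (cr_h_score, (100.0, 0.0), 100.0),
    (cr_h_score, (0.0, 100.0), 0.0),
    (cr_h_score, (80.0, 20.0), 80.0),
    (act_h_score, (0.0, 100.0), 100.0),
    (act_h_score, (100.0, 0.0), 0.0),
    (act_h_score, (40.0, 40.0), 50.0),
    (le_h_score, (0.0, 100.0), 100.0),
    (le_h_score, (100.0, 0.0), 0.0),
    (le_h_score, (40.0, 40.0), 50.0),
    (sl_h_score, (100.0, 0.0, 0.0), 100.0),
    (sl_h_score, (60.0, 40.0, 40.0), 60.0),
])
def test_formula_arithmetic(fn, args, expected):
    assert fn(*args, IDENTITY) == pytest.approx(expected)


def test_missing_inputs_yield_unavailable_score():
    assert sl_h_score(None, 10.0, 10.0, IDENTITY) is None
    assert sl_h_score(np.nan, 10.0, 10.0, IDENTITY) is None
    assert cr_h_score(None, 2.0, IDENTITY) is None


class TestDailyAverage:
    def test_all_perfect(self):
        avg, level = daily_average(
            {"cr_h": 100.0, "act_h": 100.0, "le_h": 100.0, "sl_h": 100.0})
        assert (avg, level) == (100.0, "low")

    def test_risk_thresholds(self):
        assert daily_average({"cr_h": 40.0, "act_h": 50.0,
                              "le_h": 60.0, "sl_h": 50.0}) == (50.0, "high")
        assert daily_average({"cr_h": 70.0, "act_h": 70.0,
                              "le_h": 70.0, "sl_h": 70.0})[1] == "moderate"
        assert daily_average({"cr_h": 85.0, "act_h": 85.0,
                              "le_h": 85.0, "sl_h": 85.0})[1] == "low"

    def test_mean_over_available_only(self):
        avg, _ = daily_average({"cr_h": 80.0, "act_h": None,
                                "le_h": 60.0, "sl_h": None})
        assert avg == 70.0

    def test_all_unavailable(self):
        assert daily_average({k: None for k in
                              ("cr_h", "act_h", "le_h", "sl_h")}) == (None, None)


class TestAlertRules:
    @pytest.mark.parametrize("values,expected_days,expected_rules", [
        ([49.0], [0], ["below-50"]),
        ([61.0, 59.0, 59.0], [2], ["below-60-twice"]),
        ([61.0, 59.0, 61.0, 59.0], [], []),
        ([49.0, 49.0], [0, 1], ["below-50", "below-50"]),
    ])
    def test_rule_examples(self, values, expected_days, expected_rules):
        start = dt.date(2023, 1, 1)
        alerts = evaluate_alerts(date_series(values))
        assert [(a.date - start).days for a in alerts] == expected_days
        assert [a.rule for a in alerts] == expected_rules

    def test_missing_day_breaks_consecutiveness(self):
        series = date_series([59.0, np.nan, 59.0])
        assert evaluate_alerts(series) == []

    def test_matches_brute_force_truth_table(self):
        """All 27 average patterns on {45, 55, 65}^3 against an
        independent enumeration of the two printed rules."""
        for pattern in itertools.product((45.0, 55.0, 65.0), repeat=3):
            series = date_series(pattern)
            got = {((a.date - dt.date(2023, 1, 1)).days, a.rule)
                   for a in evaluate_alerts(series)}
            expected = set()
            for day, avg in enumerate(pattern):
                if avg < 50:
                    expected.add((day, "below-50"))
                elif avg < 60 and day > 0 and pattern[day - 1] < 60 \
                        and not pattern[day] < 50:
                    expected.add((day, "below-60-twice"))
            assert got == expected, pattern

    def test_at_most_one_alert_per_day(self):
        # a sub-50 day following a sub-60 day satisfies both rules
        alerts = evaluate_alerts(date_series([59.0, 49.0]))
        assert len(alerts) == 1 and alerts[0].rule == "below-50"


class TestFeedbackMessages:
    def _scores(self, **kw):
        base = dict(cr_h=80.0, act_h=80.0, le_h=80.0, sl_h=80.0)
        base.update(kw)
        return DailyHScores(dt.date(2023, 1, 1), **base)

    def test_no_message_when_all_healthy(self):
        assert feedback_messages(self._scores()) == []

    def test_low_activity_triggers_activity_message(self):
        msgs = feedback_messages(self._scores(act_h=40.0))
        assert msgs == [MESSAGE_CATALOG["act_h"]]

    def test_two_low_scores_give_two_messages_in_catalog_order(self):
        msgs = feedback_messages(self._scores(sl_h=30.0, cr_h=30.0))
        assert msgs == [MESSAGE_CATALOG["cr_h"], MESSAGE_CATALOG["sl_h"]]


@settings(max_examples=300, derandomize=True)
@given(st.lists(st.floats(min_value=-1e4, max_value=1e4,
                          allow_nan=False), min_size=7, max_size=7))
def test_scores_always_bounded(values):
    a, b, c, d, e, f, g = values
    for score in (cr_h_score(a, b, FIXED_BOUNDS),
                  act_h_score(b, c, FIXED_BOUNDS),
                  le_h_score(d, e, FIXED_BOUNDS),
                  sl_h_score(f, g, a, FIXED_BOUNDS)):
        assert 0.0 <= score <= 100.0


def test_monotone_directions():
    """Each score moves the documented way when one input moves."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        amp, dist = rng.uniform(0, 25), rng.uniform(0, 12)
        bed, day = rng.uniform(0, 800), rng.uniform(0, 15000)
        eff = rng.uniform(0.4, 1.0)
        onset, offset = rng.uniform(0, 300, 2)
        delta = rng.uniform(0.1, 5.0)

        assert cr_h_score(amp + delta, dist, FIXED_BOUNDS) >= \
            cr_h_score(amp, dist, FIXED_BOUNDS)
        assert cr_h_score(amp, dist + delta / 2, FIXED_BOUNDS) <= \
            cr_h_score(amp, dist, FIXED_BOUNDS)
        assert act_h_score(bed + delta * 10, day, FIXED_BOUNDS) <= \
            act_h_score(bed, day, FIXED_BOUNDS)
        assert act_h_score(bed, day + delta * 10, FIXED_BOUNDS) >= \
            act_h_score(bed, day, FIXED_BOUNDS)
        assert le_h_score(bed + delta, day, FIXED_BOUNDS) <= \
            le_h_score(bed, day, FIXED_BOUNDS)
        assert le_h_score(bed, day + delta, FIXED_BOUNDS) >= \
            le_h_score(bed, day, FIXED_BOUNDS)
        assert sl_h_score(min(eff + 0.01, 1.0), onset, offset,
                          FIXED_BOUNDS) >= \
            sl_h_score(eff, onset, offset, FIXED_BOUNDS)
        assert sl_h_score(eff, onset + delta, offset, FIXED_BOUNDS) <= \
            sl_h_score(eff, onset, offset, FIXED_BOUNDS)
        assert sl_h_score(eff, onset, offset + delta, FIXED_BOUNDS) <= \
            sl_h_score(eff, onset, offset, FIXED_BOUNDS)


class TestPersonalRefs:
    def test_falls_back_with_short_history(self):
        history = pd.DataFrame({"cr_amplitude": [5.0] * 3},
                               index=[dt.date(2023, 1, d) for d in (1, 2, 3)])
        refs = personal_refs(history, dt.date(2023, 1, 4))
        assert refs["cr_amplitude"].provenance == "fixed-config"

    def test_uses_trailing_percentiles_with_enough_history(self):
        dates = [dt.date(2023, 1, 1) + dt.timedelta(days=i)
                 for i in range(20)]
        history = pd.DataFrame(
            {"cr_amplitude": np.linspace(2.0, 12.0, 20)}, index=dates)
        refs = personal_refs(history, dates[-1] + dt.timedelta(days=1))
        ref = refs["cr_amplitude"]
        assert ref.provenance == "personal-rolling"
        lo, hi = np.percentile(np.linspace(2.0, 12.0, 20), (5, 95))
        assert ref.low == pytest.approx(lo)
        assert ref.high == pytest.approx(hi)

    def test_focal_date_excluded_from_window(self):
        dates = [dt.date(2023, 1, 1) + dt.timedelta(days=i)
                 for i in range(10)]
        history = pd.DataFrame({"cr_amplitude": [1.0] * 9 + [100.0]},
                               index=dates)
        refs = personal_refs(history, dates[-1])
        # the focal-day outlier must not influence its own bounds
        assert refs["cr_amplitude"].provenance == "fixed-config"  # zero spread
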