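"""The delta-of-gradient-change statistic: slope arithmetic, omission
rules, invariances, oracle equivalence and the group tests."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circamood import (
    compare_groups,
    dgc,
    dgc_samples,
    evaluate_alerts,
    pseudo_alert_times,
    trend_gradient,
)
from circamood.behavior import DGCSample, benjamini_hochberg, subject_medians

from conftest import date_series


def _int_series(values):
    return pd.Series(list(values), index=range(len(values)), dtype=float)


class TestTrendGradient:
    @pytest.mark.parametrize("values,slope", [
        ((5, 5, 5, 5), 0.0),
        ((0, 1, 2, 3), 1.0),
        ((0, 3, 1, 2), 0.4),   # closed-form OLS on an irregular window
        ((2, 1), -1.0),
    ])
    def test_ols_slope(self, values, slope):
        assert trend_gradient(values) == pytest.approx(slope)

    def test_single_point_unavailable(self):
        with pytest.raises(ValueError):
            trend_gradient([1.0])


class TestDGC:
    def test_constant_series_is_zero(self):
        s = dgc(_int_series([3.0] * 9), 4)
        assert s.dgc == pytest.approx(0.0)

    def test_globally_linear_series_cancels(self):
        s = dgc(_int_series(np.arange(9) * 2.0 + 1.0), 4)
        assert s.dgc == pytest.approx(0.0)

    def test_flat_then_rising_is_plus_one(self):
        s = dgc(_int_series([5, 5, 5, 5, 6, 7, 8]), 3)
        assert s.dgc == pytest.approx(1.0)
        assert s.x_before == (5, 5, 5, 5)
        assert s.x_after == (5, 6, 7, 8)  # windows share the alert day

    def test_missing_point_omits_sample(self):
        values = np.arange(9, dtype=float)
        values[6] = np.nan
        assert dgc(_int_series(values), 4) is None

    def test_boundary_alert_omitted(self):
        series = _int_series(np.arange(10))
        assert dgc(series, 1) is None
        assert dgc(series, 8) is None
        assert dgc(series, 3) is not None

    def test_invariant_to_additive_constant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=9)
        base = dgc(_int_series(values), 4).dgc
        shifted = dgc(_int_series(values + 123.4), 4).dgc
        assert shifted == pytest.approx(base)

    def test_invariant_under_time_reversal(self):
        # reversal swaps the before/after roles and negates both
        # slopes, so the two sign flips cancel exactly
        rng = np.random.default_rng(1)
        values = rng.normal(size=7)
        forward = dgc(_int_series(values), 3).dgc
        backward = dgc(_int_series(values[::-1]), 3).dgc
        assert backward == pytest.approx(forward)

    def test_antisymmetric_under_value_negation(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=7)
        assert dgc(_int_series(-values), 3).dgc == pytest.approx(
            -dgc(_int_series(values), 3).dgc)

    def test_equals_two_slope_oracle_on_random_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            values = rng.normal(0, rng.uniform(0.5, 10), 7)
            got = dgc(_int_series(values), 3).dgc
            expected = (np.polyfit(np.arange(4), values[3:], 1)[0]
                        - np.polyfit(np.arange(4), values[:4], 1)[0])
            assert got == pytest.approx(expected, abs=1e-10)


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
                min_size=7, max_size=7))
def test_dgc_matches_definition(values):
    sample = dgc(_int_series(values), 3)
    assert sample.dgc == pytest.approx(
        trend_gradient(values[3:]) - trend_gradient(values[:4]), abs=1e-8)


class TestPseudoAlerts:
    def test_same_series_gives_same_time_points(self):
        series = date_series([65, 49, 59, 59, 65, 45])
        delivered = [a.date for a in evaluate_alerts(series)]
        assert pseudo_alert_times(series) == delivered

    def test_never_below_sixty_is_empty(self):
        assert pseudo_alert_times(date_series([65, 70, 61, 80])) == []

    def test_one_injected_sub_fifty_day(self):
        series = date_series([70, 70, 44, 70, 70])
        times = pseudo_alert_times(series)
        assert times == [dt.date(2023, 1, 3)]


class TestGroupComparison:
    def _samples(self, sid, values):
        return [DGCSample(sid, "f", i, (0,) * 4, (0,) * 4, v)
                for i, v in enumerate(values)]

    def test_identical_groups_show_no_difference(self):
        crm = [s for i in range(5)
               for s in self._samples(f"c{i}", [0.1 * i])]
        ctrl = [s for i in range(5)
                for s in self._samples(f"n{i}", [0.1 * i])]
        result = compare_groups(crm, ctrl)
        assert result.ks_statistic == 0.0
        assert result.mw_p > 0.5

    def test_per_subject_median_reduction(self):
        samples = self._samples("a", [1.0, 5.0, 2.0])
        assert subject_medians(samples) == {"a": 2.0}

    def test_empty_group_flagged_not_raised(self):
        result = compare_groups([], self._samples("n0", [0.5]))
        assert not result.computable

    def test_detects_injected_positive_shift(self):
        """CRM subjects get a rising post-alert trend; the group median
        DGC must exceed the control's in every seeded replicate."""
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            crm, ctrl = [], []
            for i in range(10):
                noise = rng.normal(0, 1, 9)
                shifted = noise.copy()
                shifted[5:] += 2.0 * np.arange(1, 5)  # slope +2 = 2 SD/day
                crm.extend(dgc_samples(_int_series(shifted), [4], f"c{i}"))
                ctrl.extend(dgc_samples(
                    _int_series(rng.normal(0, 1, 9)), [4], f"n{i}"))
            result = compare_groups(crm, ctrl)
            assert (np.median(result.crm_medians)
                    > np.median(result.control_medians))

    def test_null_rejection_rate_is_plausible(self):
        """Coarse type-I check (the fine calibration lives in the
        acceptance suite)."""
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(100):
            crm = [DGCSample(f"c{i}", "f", 0, (0,) * 4, (0,) * 4,
                             rng.normal()) for i in range(15)]
            ctrl = [DGCSample(f"n{i}", "f", 0, (0,) * 4, (0,) * 4,
                              rng.normal()) for i in range(15)]
            if compare_groups(crm, ctrl).mw_p < 0.05:
                rejections += 1
        assert rejections <= 12


def test_benjamini_hochberg_step_up():
    decisions = benjamini_hochberg(
        {"a": 0.001, "b": 0.02, "c": 0.04, "d": 0.9}, alpha=0.05)
    assert decisions["a"] and not decisions["d"]
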