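"""Threshold, event-detection and annual-index tests, incl. the run oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from urbanheat import (PeriodWindow, annual_indices, annual_indices_table,
                       baseline_threshold, detect_events,
                       period_mean_indices)
from urbanheat.indices import Threshold

from conftest import make_series


def oracle_events(values, threshold, min_days):
    """Exhaustive scan for maximal strict-exceedance runs of length >= min."""
    n = len(values)
    runs = []
    for i in range(n):
        for j in range(i, n):
            if all(values[k] > threshold for k in range(i, j + 1)):
                left_ok = i == 0 or values[i - 1] <= threshold
                right_ok = j == n - 1 or values[j + 1] <= threshold
                if left_ok and right_ok and j - i + 1 >= min_days:
                    runs.append((i, j - i + 1))
    return runs


def thr(value, city="cityA", var="tasmax", q=0.95):
    return Threshold(city, var, q, value,
                     PeriodWindow("baseline", 2001, 2001))


class TestBaselineThreshold:
    def test_linear_interpolation_quantile(self):
        # 365 sorted values 0..364: position (n-1)*q = 364*0.95 = 345.8,
        # so the type-7 quantile interpolates to exactly 345.8
        vals = np.arange(365.0)
        rng = np.random.default_rng(0)
        rng.shuffle(vals)
        series = make_series(vals)
        win = PeriodWindow("baseline", 2001, 2001)
        t = baseline_threshold(series, win, 0.95)
        assert t.value == pytest.approx(345.8)

    def test_constant_series(self):
        series = make_series(np.full(365, 25.0))
        t = baseline_threshold(series, PeriodWindow("b", 2001, 2001), 0.95)
        assert t.value == 25.0

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(20, 5, 365)
        win = PeriodWindow("b", 2001, 2001)
        t1 = baseline_threshold(make_series(vals), win, 0.9)
        t2 = baseline_threshold(make_series(vals[::-1].copy()), win, 0.9)
        assert t1.value == t2.value

    def test_uncovered_window_rejected_naming_years(self):
        series = make_series(np.zeros(365))
        with pytest.raises(ValueError, match="2002"):
            baseline_threshold(series, PeriodWindow("b", 2001, 2002), 0.95)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2])
    def test_invalid_quantile(self, q):
        with pytest.raises(ValueError):
            baseline_threshold(make_series(np.zeros(365)),
                               PeriodWindow("b", 2001, 2001), q)


class TestDetectEvents:
    def test_short_run_not_an_event(self):
        s = make_series([31, 32, 33, 29, 31, 31, 29])
        events = detect_events(s, thr(30.0), 3)
        assert len(events) == 1
        assert events[0].duration == 3
        assert events[0].start_date == "2001-01-01"
        np.testing.assert_array_equal(events[0].temps, [31, 32, 33])

    def test_equality_does_not_exceed(self):
        s = make_series([30.0, 30.0, 30.0, 30.0])
        assert detect_events(s, thr(30.0), 3) == []

    def test_long_run_is_one_event(self):
        s = make_series([35.0] * 10 + [10.0])
        events = detect_events(s, thr(30.0), 3)
        assert [e.duration for e in events] == [10]

    def test_city_mismatch_rejected(self):
        s = make_series([31.0, 31.0, 31.0])
        with pytest.raises(ValueError, match="city"):
            detect_events(s, thr(30.0, city="other"), 3)

    def test_variable_mismatch_rejected(self):
        s = make_series([31.0, 31.0, 31.0])
        with pytest.raises(ValueError, match="variable"):
            detect_events(s, thr(30.0, var="tasmin"), 3)

    def test_appending_cool_days_changes_no_event(self):
        base = [31, 32, 33, 20, 34, 35, 36, 37]
        e1 = detect_events(make_series(base), thr(30.0), 3)
        e2 = detect_events(make_series(base + [10.0] * 5), thr(30.0), 3)
        assert [(e.start_date, e.duration) for e in e1] == \
               [(e.start_date, e.duration) for e in e2]

    def test_matches_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            vals = rng.normal(30, 4, size=60)
            t = float(rng.uniform(26, 36))
            md = int(rng.integers(1, 5))
            got = [(e.start_index, e.duration)
                   for e in detect_events(make_series(vals), thr(t), md)]
            assert got == oracle_events(vals, t, md)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(vals=st.lists(st.integers(min_value=0, max_value=4),
                         min_size=1, max_size=40),
           threshold=st.integers(min_value=0, max_value=4),
           min_days=st.integers(min_value=1, max_value=4))
    def test_oracle_property(self, vals, threshold, min_days):
        vals = [float(v) for v in vals]
        got = [(e.start_index, e.duration)
               for e in detect_events(make_series(vals),
                                      thr(float(threshold)), min_days)]
        assert got == oracle_events(vals, threshold, min_days)

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(30, 4, 365)
        s = make_series(vals)
        lo = annual_indices(detect_events(s, thr(30.0), 3), s, 2001)
        hi = annual_indices(detect_events(s, thr(33.0), 3), s, 2001)
        for name in ("hwn", "hwtd", "hwld"):
            assert hi[name] <= lo[name]
        if hi["hwtd"] > 0:
            assert hi["hht"] <= lo["hht"]


class TestAnnualIndices:
    def test_two_event_worked_example(self):
        vals = np.full(365, 20.0)
        vals[10:13] = [31, 32, 33]
        vals[100:104] = [31, 31, 32, 34]
        s = make_series(vals)
        events = detect_events(s, thr(30.0), 3)
        rec = annual_indices(events, s, 2001)
        assert rec["hwn"] == 2
        assert rec["hwtd"] == 7
        assert rec["hwld"] == 4
        assert rec["hwmt"] == pytest.approx(32.0)
        assert rec["hht"] == 34.0

    def test_event_free_year_missing_intensities(self):
        s = make_series(np.full(365, 20.0))
        rec = annual_indices([], s, 2001)
        assert (rec["hwn"], rec["hwtd"], rec["hwld"]) == (0, 0, 0)
        assert np.isnan(rec["hwmt"]) and np.isnan(rec["hht"])

    def test_single_event_hwld_equals_hwtd(self):
        vals = np.full(365, 20.0)
        vals[50:55] = 35.0
        s = make_series(vals)
        rec = annual_indices(detect_events(s, thr(30.0), 3), s, 2001)
        assert rec["hwld"] == rec["hwtd"] == 5

    def test_year_outside_coverage_rejected(self):
        s = make_series(np.zeros(365))
        with pytest.raises(ValueError, match="1999"):
            annual_indices([], s, 1999)

    def test_new_year_straddling_event_not_double_counted(self):
        vals = np.full(2 * 365, 20.0)
        vals[363:368] = 35.0  # 30-31 Dec 2001 + 1-3 Jan 2002
        s = make_series(vals)
        events = detect_events(s, thr(30.0), 3)
        assert len(events) == 1 and events[0].duration == 5
        r1 = annual_indices(events, s, 2001)
        r2 = annual_indices(events, s, 2002)
        assert r1["hwn"] == 1 and r2["hwn"] == 0  # start-year attribution
        assert r1["hwtd"] == 2 and r2["hwtd"] == 3
        assert r1["hwld"] == 2 and r2["hwld"] == 3


class TestPeriodMeans:
    def _records(self, rows):
        cols = ["city_id", "model_id", "scenario", "diurnal_var", "year",
                "hwn", "hwtd", "hwld", "hwmt", "hht"]
        return pd.DataFrame(rows, columns=cols)

    def test_arithmetic_mean(self):
        rows = [["a", "m", "historical", "tasmax", y, h, 0, 0, np.nan, np.nan]
                for y, h in zip((2001, 2002, 2003), (2, 3, 4))]
        out = period_mean_indices(self._records(rows),
                                  PeriodWindow("b", 2001, 2003))
        assert out["hwn"].iloc[0] == pytest.approx(3.0)

    def test_intensity_mean_over_event_years_only(self):
        rows = [["a", "m", "historical", "tasmax", 2001, 1, 3, 3, 31.0, 32.0],
                ["a", "m", "historical", "tasmax", 2002, 0, 0, 0, np.nan,
                 np.nan],
                ["a", "m", "historical", "tasmax", 2003, 1, 4, 4, 33.0, 35.0]]
        out = period_mean_indices(self._records(rows),
                                  PeriodWindow("b", 2001, 2003))
        assert out["hwmt"].iloc[0] == pytest.approx(32.0)
        assert out["n_intensity_years"].iloc[0] == 2

    def test_all_event_free_years(self):
        rows = [["a", "m", "historical", "tasmax", y, 0, 0, 0, np.nan, np.nan]
                for y in (2001, 2002)]
        out = period_mean_indices(self._records(rows),
                                  PeriodWindow("b", 2001, 2002))
        assert np.isnan(out["hwmt"].iloc[0])
        assert out["n_intensity_years"].iloc[0] == 0

    def test_missing_year_rejected(self):
        rows = [["a", "m", "historical", "tasmax", 2001, 1, 3, 3, 31.0, 32.0]]
        with pytest.raises(ValueError, match="2002"):
            period_mean_indices(self._records(rows),
                                PeriodWindow("b", 2001, 2002))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            period_mean_indices(self._records([]), PeriodWindow("b", 1, 1))


def test_percentile_cap_on_synthetic_baseline():
    """Mean baseline HWTD cannot exceed the 5% exceedance budget by much."""
    from urbanheat import SyntheticSpec, generate_truth
    spec = SyntheticSpec(rng_seed=3)
    win = PeriodWindow("baseline", 1985, 2014)
    tmax, _ = generate_truth(spec, 0, "historical", win)
    t = baseline_threshold(tmax, win, 0.95)
    tab = annual_indices_table(tmax, t, 3)
    assert tab["hwtd"].mean() / 365 <= 0.05 + 0.005
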