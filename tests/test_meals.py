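from datetime import date

import numpy as np
import pandas as pd
import pytest

from funcmon.core import ComponentUnavailableError
from funcmon.meals import (
    MealPrepParams,
    build_meal_profile,
    detect_change_c2,
    meal_prep_time_daily,
    merge_intervals,
    spearman_rho,
)

from conftest import make_events

KITCHEN = ["power_kettle", "pir_kitchen", "door_fridge"]


def power_reading(ts, watts, sensor="power_kettle"):
    return (ts, sensor, "power", watts, "kitchen")


def pir_mark(ts):
    return (ts, "pir_kitchen", "pir", 1, "kitchen")


def occupancy_oracle(power_runs, marks, merge_gap_s):
    """Second-resolution occupancy count, independent of the interval algebra.

    power_runs: list of (start, end) pandas Timestamps; marks: timestamps.
    A second is occupied if inside a run, or if a mark chains to a run
    within merge_gap, or if it falls in a gap <= merge_gap between
    occupied stretches.
    """
    pieces = [(a, b) for a, b in power_runs] + [(t, t) for t in marks]
    pieces.sort()
    merged = []
    for a, b in pieces:
        if merged and (a - merged[-1][1]).total_seconds() <= merge_gap_s:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # count only stretches containing at least one power run
    total = 0.0
    for a, b in merged:
        if any(not (rb < a or ra > b) for ra, rb in power_runs):
            total += (b - a).total_seconds()
    return total / 60.0


class TestMealPrepTime:
    def test_no_events_is_zero(self):
        assert meal_prep_time_daily(make_events([]), KITCHEN) == 0.0

    def test_single_interval(self):
        rows = [power_reading(t, 1500) for t in pd.date_range("2014-07-01 12:00", "2014-07-01 12:29", freq="60s")]
        rows.append(power_reading("2014-07-01 12:30", 0))
        minutes = meal_prep_time_daily(make_events(rows), KITCHEN)
        assert minutes == pytest.approx(30.0)

    def test_overlapping_appliances_union(self):
        rows = [power_reading(t, 1500, "power_kettle")
                for t in pd.date_range("2014-07-01 12:00", "2014-07-01 12:19", freq="60s")]
        rows.append(power_reading("2014-07-01 12:20", 0, "power_kettle"))
        rows += [(t, "power_stove", "power", 1200, "kitchen")
                 for t in pd.date_range("2014-07-01 12:10", "2014-07-01 12:39", freq="60s")]
        rows.append(("2014-07-01 12:40", "power_stove", "power", 0, "kitchen"))
        minutes = meal_prep_time_daily(make_events(rows), KITCHEN + ["power_stove"])
        assert minutes == pytest.approx(40.0)

    def test_pir_marks_alone_add_no_time(self):
        rows = [pir_mark("2014-07-01 09:00"), pir_mark("2014-07-01 09:05")]
        assert meal_prep_time_daily(make_events(rows), KITCHEN) == 0.0

    def test_no_kitchen_sensors_is_unavailable_not_zero(self):
        with pytest.raises(ComponentUnavailableError):
            meal_prep_time_daily(make_events([]), [])

    def test_matches_minute_occupancy_oracle(self, rng):
        params = MealPrepParams(standby_watts=5, close_gap_s=60, merge_gap_s=600)
        for _ in range(100):
            base = pd.Timestamp("2014-07-01 06:00")
            rows, runs, marks = [], [], []
            for _ in range(rng.integers(1, 4)):
                start = base + pd.Timedelta(minutes=float(rng.uniform(0, 600)))
                n = int(rng.integers(2, 30))
                stamps = pd.date_range(start, periods=n, freq="60s")
                rows += [power_reading(t, 1000) for t in stamps]
                rows.append(power_reading(stamps[-1] + pd.Timedelta(seconds=60), 0))
                runs.append((stamps[0], stamps[-1] + pd.Timedelta(seconds=60)))
            for _ in range(int(rng.integers(0, 5))):
                t = base + pd.Timedelta(minutes=float(rng.uniform(0, 700)))
                rows.append(pir_mark(t))
                marks.append(t)
            got = meal_prep_time_daily(make_events(rows), KITCHEN, params)
            want = occupancy_oracle(runs, marks, params.merge_gap_s)
            assert got == pytest.approx(want), (runs, marks)

    def test_merge_intervals_gap_rule(self):
        a = (pd.Timestamp("2014-07-01 12:00"), pd.Timestamp("2014-07-01 12:10"))
        b = (pd.Timestamp("2014-07-01 12:15"), pd.Timestamp("2014-07-01 12:20"))
        assert len(merge_intervals([a, b], merge_gap_s=600)) == 1
        assert len(merge_intervals([a, b], merge_gap_s=60)) == 2


class TestSpearman:
    def test_monotone_pair(self):
        assert spearman_rho([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_antitone_pair(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_sequence_undefined(self):
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_matches_rank_formula(self, rng):
        # brute force: Pearson correlation of the rank vectors
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            rx = np.argsort(np.argsort(x))
            ry = np.argsort(np.argsort(y))
            want = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(want)


def profile_from_means(means, n_days=30, wiggle=0.0, seed=0):
    rng = np.random.default_rng(seed)
    daily, period_of_day = {}, {}
    d0 = date(2014, 7, 1)
    day = 0
    for k, m in enumerate(means):
        for _ in range(n_days):
            dd = d0.fromordinal(d0.toordinal() + day)
            daily[dd] = max(0.0, m + rng.normal(0, wiggle))
            period_of_day[dd] = k
            day += 1
    return build_meal_profile(daily, period_of_day)


class TestWeightChangeDetection:
    def test_identical_periods_do_not_flag(self):
        prof = profile_from_means([70.0, 70.0])
        assert detect_change_c2(prof, (0, 1)).flag == 0

    def test_large_relative_change_flags(self):
        prof = profile_from_means([70.0, 50.0])
        out = detect_change_c2(prof, (0, 1))
        assert out.flag == 1
        assert out.icf_items == frozenset({"b530"})
        assert out.direction.value == "unknown"

    def test_symmetric_under_sign_of_change(self):
        up = profile_from_means([70.0, 90.0])
        down = profile_from_means([90.0, 70.0])
        assert detect_change_c2(up, (0, 1)).flag == 1
        assert detect_change_c2(down, (0, 1)).flag == 1

    def test_unavailable_profile_excluded(self):
        prof = profile_from_means([70.0, 50.0])
        prof.available = False
        assert detect_change_c2(prof, (0, 1)).available is False

    def test_sparse_period_is_unavailable(self):
        prof = profile_from_means([70.0, 50.0], n_days=3)
        assert detect_change_c2(prof, (0, 1)).available is False
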