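from datetime import date

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from funcmon.core import HouseholdLayout, SensorKind, SensorSpec
from funcmon.environment import (
    ActivityProbabilityMap,
    BaselineMap,
    CONTROL_SLOPE,
    EnvTrend,
    INTERVENTION_SLOPE,
    build_probability_map,
    build_transition_graph,
    classify_day,
    detect_change_c3,
    f_control,
    f_env,
    f_intervention,
    fit_trend,
    percent_difference,
    slope_for_period,
    total_activity,
    total_variation,
    update_baseline,
)

from conftest import make_events

SENSORS = ("s_a", "s_b", "s_c")


def random_day(rng, sensors=SENSORS, n=120, weights=None):
    rows = []
    for _ in range(n):
        s = rng.choice(sensors, p=weights)
        h = int(rng.integers(0, 24))
        rows.append(
            (pd.Timestamp("2014-07-01") + pd.Timedelta(hours=h, minutes=int(rng.integers(60))),
             s, "pir", 1, "room")
        )
    return make_events(rows)


def map_from_counts(counts, sensors=SENSORS):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    probs = counts / total if total else counts
    return ActivityProbabilityMap(probs=probs, sensors=sensors, n_events=int(total))


class TestProbabilityMap:
    def test_event_free_day_gives_zero_map(self):
        m = build_probability_map(make_events([]), SENSORS)
        assert m.n_events == 0 and not m.probs.any()

    def test_point_mass(self):
        ev = make_events(
            [("2014-07-01 09:15", "s_b", "pir", 1, "room")] * 4
        )
        m = build_probability_map(ev, SENSORS)
        assert m.probs[1, 9] == 1.0
        assert m.probs.sum() == 1.0

    def test_matches_hour_bucket_oracle(self, rng):
        for _ in range(100):
            ev = random_day(rng, n=int(rng.integers(1, 150)))
            m = build_probability_map(ev, SENSORS)
            counts = np.zeros((3, 24))
            for _, row in ev.iterrows():
                counts[SENSORS.index(row["sensor_id"]), row["timestamp"].hour] += 1
            np.testing.assert_allclose(m.probs, counts / counts.sum())

    def test_normalizes_to_one_with_events(self, rng):
        m = build_probability_map(random_day(rng), SENSORS)
        assert m.probs.sum() == pytest.approx(1.0)

    def test_per_sensor_normalization(self, rng):
        m = build_probability_map(random_day(rng), SENSORS, normalization="per_sensor")
        rows = m.probs.sum(axis=1)
        assert all(r == pytest.approx(1.0) or r == 0.0 for r in rows)


class TestDriftDetection:
    def baseline(self, rng, n_days=7, n=200):
        return BaselineMap.from_days(
            [build_probability_map(random_day(rng, n=n), SENSORS) for _ in range(n_days)]
        )

    def test_day_equal_to_baseline_is_normal(self, rng):
        b = self.baseline(rng)
        day = ActivityProbabilityMap(probs=b.probs, sensors=SENSORS, n_events=200)
        cls = classify_day(day, b, alpha=0.05, n_resamples=500, rng=rng)
        assert cls.label == "normal"
        assert cls.p_value > 0.5

    def test_disjoint_hours_abnormal(self, rng):
        # baseline mass in hours 0-11, day mass in hours 12-23
        base_counts = np.zeros((3, 24)); base_counts[:, 0:12] = 10
        day_counts = np.zeros((3, 24)); day_counts[:, 12:24] = 10
        b = BaselineMap.from_days([map_from_counts(base_counts)] * 7)
        cls = classify_day(map_from_counts(day_counts), b, 0.05, 10000, rng)
        assert cls.label == "abnormal"
        assert cls.p_value < 0.001
        assert cls.tv_distance == pytest.approx(1.0)

    def test_alpha_zero_never_rejects(self, rng):
        b = self.baseline(rng)
        day = build_probability_map(random_day(rng, n=10), SENSORS)
        cls = classify_day(day, b, alpha=0.0, n_resamples=200, rng=rng)
        assert cls.label == "normal"

    def test_empty_day_is_abnormal(self, rng):
        b = self.baseline(rng)
        day = build_probability_map(make_events([]), SENSORS)
        assert classify_day(day, b, rng=rng).label == "abnormal"

    def test_uninitialized_baseline_rejected(self, rng):
        b = BaselineMap()
        day = build_probability_map(random_day(rng), SENSORS)
        with pytest.raises(ValueError):
            classify_day(day, b, rng=rng)

    def test_seeded_classification_is_deterministic(self, rng):
        b = self.baseline(rng)
        day = build_probability_map(random_day(rng), SENSORS)
        c1 = classify_day(day, b, rng=np.random.default_rng(5))
        c2 = classify_day(day, b, rng=np.random.default_rng(5))
        assert c1 == c2


class TestBaselineUpdate:
    def test_abnormal_day_leaves_baseline_unchanged(self, rng):
        b = BaselineMap.from_days([build_probability_map(random_day(rng), SENSORS) for _ in range(7)])
        day = build_probability_map(random_day(rng), SENSORS)
        cls = classify_day(day, b, alpha=0.0, n_resamples=100, rng=rng)
        # force the abnormal branch
        from funcmon.environment import DayClassification
        b2 = update_baseline(b, day, DayClassification("abnormal", 0.0, 0.5))
        np.testing.assert_array_equal(b.probs, b2.probs)

    def test_identical_days_are_a_fixed_point(self, rng):
        m = build_probability_map(random_day(rng), SENSORS)
        b = BaselineMap.from_days([m] * 7)
        from funcmon.environment import DayClassification
        b2 = update_baseline(b, m, DayClassification("normal", 1.0, 0.0))
        np.testing.assert_allclose(b.probs, b2.probs)

    def test_mixed_window_equals_mean_of_retained_maps(self, rng):
        maps = [build_probability_map(random_day(rng), SENSORS) for _ in range(9)]
        b = BaselineMap.from_days(maps[:7])
        from funcmon.environment import DayClassification
        normal = DayClassification("normal", 1.0, 0.0)
        b = update_baseline(b, maps[7], normal)
        b = update_baseline(b, maps[8], normal)
        expected = np.mean([m.probs for m in maps[2:9]], axis=0)
        np.testing.assert_allclose(b.probs, expected)


def pir(ts, room):
    return (ts, f"pir_{room}", "pir", 1, room)


class TestTransitionGraph:
    def test_single_room_day_has_no_edges(self, small_layout):
        ev = make_events([pir(f"2014-07-01 10:0{i}", "kitchen") for i in range(5)])
        g = build_transition_graph(ev, small_layout)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == set(small_layout.rooms)

    def test_back_and_forth_counts_both_directions(self, small_layout):
        ev = make_events(
            [pir("2014-07-01 10:00", "kitchen"),
             pir("2014-07-01 10:01", "hallway"),
             pir("2014-07-01 10:02", "kitchen")]
        )
        g = build_transition_graph(ev, small_layout)
        assert g["kitchen"]["hallway"]["weight"] == 1
        assert g["hallway"]["kitchen"]["weight"] == 1
        assert total_activity(g) == 2

    def test_gap_rule_suppresses_slow_transitions(self, small_layout):
        ev = make_events(
            [pir("2014-07-01 10:00", "kitchen"), pir("2014-07-01 10:20", "hallway")]
        )
        g = build_transition_graph(ev, small_layout, max_gap_s=300)
        assert g.number_of_edges() == 0

    def test_total_weight_matches_pair_scan_oracle(self, small_layout, rng):
        rooms = ["kitchen", "hallway"]
        for _ in range(100):
            n = int(rng.integers(2, 60))
            stamps = sorted(
                pd.Timestamp("2014-07-01")
                + pd.Timedelta(seconds=float(s))
                for s in rng.uniform(0, 86000, size=n)
            )
            seq = [rooms[i] for i in rng.integers(0, 2, size=n)]
            ev = make_events([pir(t, r) for t, r in zip(stamps, seq)])
            g = build_transition_graph(ev, small_layout, max_gap_s=300)
            want = sum(
                1
                for i in range(1, n)
                if seq[i] != seq[i - 1]
                and (stamps[i] - stamps[i - 1]).total_seconds() <= 300
            )
            assert total_activity(g) == want


class TestTrend:
    def test_percent_difference_cases(self):
        assert percent_difference(50, 50) == 0.0
        assert percent_difference(75, 50) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            percent_difference(10, 0)

    def test_exact_line_recovered(self):
        x = np.arange(300, dtype=float)
        y = f_control(x)
        slope, intercept = fit_trend(x, y)
        assert slope == pytest.approx(CONTROL_SLOPE, rel=1e-9)
        assert intercept == pytest.approx(0.1340, rel=1e-9)

    def test_constant_diffs_give_zero_slope(self):
        slope, _ = fit_trend([0, 1, 2, 3], [0.2, 0.2, 0.2, 0.2])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_trend([5, 5, 5], [1, 2, 3])

    def test_noisy_slope_recovery(self):
        """Mean recovered slope over 50 seeded runs lands within 20% of the
        planted magnitude (n=300 days, sigma=0.05)."""
        planted = CONTROL_SLOPE
        x = np.arange(300, dtype=float)
        slopes = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = planted * x + 0.1340 + rng.normal(0, 0.05, size=300)
            slopes.append(fit_trend(x, y)[0])
        assert np.mean(slopes) == pytest.approx(planted, rel=0.2)

    def test_slope_source_priority(self):
        x = np.arange(40, dtype=float)
        y = 0.002 * x
        assert slope_for_period(x, y, group="control") == pytest.approx(0.002)
        assert slope_for_period(x[:10], y[:10], group="control") == CONTROL_SLOPE
        assert slope_for_period(x[:10], y[:10], group=None) == 0.0


class TestEnvScore:
    def test_zero_inputs_give_zero(self):
        assert f_env(0.0, 0, 30) == 0.0

    def test_intervention_slope_alone(self):
        assert f_env(INTERVENTION_SLOPE, 0, 30) == pytest.approx(4.9948e-5)

    def test_control_slope_with_abnormal_days(self):
        assert f_env(CONTROL_SLOPE, 12, 30) == pytest.approx(0.40086, abs=5e-6)

    def test_monotone_in_abnormal_days_and_slope(self):
        vals = [f_env(0.0, c, 30) for c in range(31)]
        assert vals == sorted(vals)
        assert f_env(-0.2, 5, 30) >= f_env(-0.1, 5, 30)

    def test_invalid_period_rejected(self):
        with pytest.raises(ValueError):
            f_env(0.0, 0, 0)
        with pytest.raises(ValueError):
            f_env(0.0, -1, 30)

    def test_group_reference_lines(self):
        assert f_control(0) == pytest.approx(0.1340)
        assert f_intervention(0) == pytest.approx(-1.0610e-2)
        assert abs(CONTROL_SLOPE) / abs(INTERVENTION_SLOPE) >= 10


class TestComponent3Output:
    def test_fires_above_threshold_with_attribution(self):
        out = detect_change_c3(EnvTrend(slope=CONTROL_SLOPE, abnormal_days=12, period_days=30))
        assert out.flag == 1
        assert out.icf_items == frozenset({"e115", "e245"})

    def test_small_score_does_not_fire(self):
        out = detect_change_c3(EnvTrend(slope=0.0, abnormal_days=2, period_days=30))
        assert out.flag == 0 and out.icf_items == frozenset()

    def test_zero_threshold_fires_on_any_signal(self):
        out = detect_change_c3(
            EnvTrend(slope=0.0, abnormal_days=1, period_days=30, threshold=0.0)
        )
        assert out.flag == 1
        assert out.icf_items == frozenset({"e115"})
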