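"""Component 3 — ICF items e115 and e245 from domestic sensor routines.

Two models watch the home routine:

* e115 (Products and technology for personal use): an unsupervised
  concept-drift detector on **activity probability maps** — for each day
  a sensors x 24 matrix of the probability that an event of a sensor
  falls into an hour-of-day bin. Each new day is compared to a personal
  baseline (mean map of the 7 most recent normal days) with a
  permutation test on the total-variation distance; days whose
  same-distribution probability falls below ``alpha`` are abnormal. Only
  normal days update the baseline, so the detector adapts to slow
  behaviour change but holds its reference through an anomaly.

* e245 (Time-related changes): a **room-transition graph** — a weighted
  directed graph whose vertices are rooms and whose edge weights count
  motion-sensor transitions between rooms in one day. The daily total
  weight is the activity measure; its percent difference to a baseline
  is tracked over the study and a line is fitted, giving the activity
  trend slope s (per day).

Both models combine into the environmental score

    f_env = |s| + c / p

with c the abnormal-day count in the period of p days. The component's
output is 1 when f_env exceeds a threshold (0.3 by default). When no
slope information is available s is 0; group-level reference slopes are
provided for residents enrolled in (``intervention``) or outside
(``control``) an exercise programme.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import ComponentOutput, Direction, HouseholdLayout, SensorKind

#: Group-level activity-trend lines (percent difference per day since T0).
CONTROL_SLOPE = -8.5829e-4
CONTROL_INTERCEPT = 0.1340
INTERVENTION_SLOPE = -4.9948e-5
INTERVENTION_INTERCEPT = -1.0610e-2

GROUP_SLOPES = {"control": CONTROL_SLOPE, "intervention": INTERVENTION_SLOPE}

#: Default f_env alarm threshold.
DEFAULT_ENV_THRESHOLD = 0.3

#: Days in the baseline window.
BASELINE_WINDOW = 7


def f_control(x: float) -> float:
    """Group activity-trend line of the control (no exercise) group."""
    return CONTROL_SLOPE * x + CONTROL_INTERCEPT


def f_intervention(x: float) -> float:
    """Group activity-trend line of the exercise-programme group."""
    return INTERVENTION_SLOPE * x + INTERVENTION_INTERCEPT


@dataclass(frozen=True)
class ActivityProbabilityMap:
    """Per-day sensors x 24 hour-of-day event probability matrix."""

    probs: np.ndarray
    sensors: tuple
    n_events: int
    normalization: str = "per_map"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (len(self.sensors), 24):
            raise ValueError(f"probs must be ({len(self.sensors)}, 24), got {probs.shape}")
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "sensors", tuple(self.sensors))

    @property
    def counts(self) -> np.ndarray:
        """Approximate event counts per cell (exact under per-map normalization)."""
        return self.probs * self.n_events


def build_probability_map(
    day_events: pd.DataFrame,
    sensors: Sequence[str],
    normalization: str = "per_map",
) -> ActivityProbabilityMap:
    """Bucket one day's events by (sensor, hour) and normalise to probabilities.

    ``per_map`` (default) divides by the day's total event count so all
    cells sum to 1 (a joint distribution over sensor and hour);
    ``per_sensor`` normalises each sensor row separately. An event-free
    day yields the all-zero map.
    """
    sensors = tuple(sensors)
    index = {s: i for i, s in enumerate(sensors)}
    counts = np.zeros((len(sensors), 24), dtype=float)
    if len(day_events):
        hours = pd.to_datetime(day_events["timestamp"]).dt.hour.to_numpy()
        for sid, h in zip(day_events["sensor_id"].to_numpy(), hours):
            if sid in index:
                counts[index[sid], h] += 1
    total = counts.sum()
    if normalization == "per_map":
        probs = counts / total if total > 0 else counts
    elif normalization == "per_sensor":
        row = counts.sum(axis=1, keepdims=True)
        probs = np.divide(counts, row, out=np.zeros_like(counts), where=row > 0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return ActivityProbabilityMap(
        probs=probs, sensors=sensors, n_events=int(total), normalization=normalization
    )


@dataclass
class BaselineMap:
    """Rolling mean of the probability maps of recent normal days."""

    window: deque = field(default_factory=lambda: deque(maxlen=BASELINE_WINDOW))

    @classmethod
    def from_days(cls, maps: Sequence[ActivityProbabilityMap]) -> "BaselineMap":
        if len(maps) < BASELINE_WINDOW:
            raise ValueError(f"baseline needs >= {BASELINE_WINDOW} days, got {len(maps)}")
        b = cls()
        for m in maps[-BASELINE_WINDOW:]:
            b.window.append(m)
        return b

    @property
    def initialized(self) -> bool:
        return len(self.window) >= BASELINE_WINDOW

    @property
    def probs(self) -> np.ndarray:
        return np.mean([m.probs for m in self.window], axis=0)

    @property
    def sensors(self) -> tuple:
        return self.window[0].sensors

    @property
    def mean_events(self) -> float:
        return float(np.mean([m.n_events for m in self.window]))

    def dispersion(self) -> float:
        """Pearson overdispersion of the window's day counts vs multinomial.

        Daily event streams cluster (movement comes in bouts, appliance
        readings in blocks), so per-cell counts spread wider than a
        multinomial at the same totals. The mean Pearson chi-square per
        degree of freedom over the window's days estimates that variance
        inflation; 1.0 means multinomial-like days. Floored at 1 so a
        quieter-than-multinomial window never sharpens the test.
        """
        probs = self.probs.ravel()
        mask = probs > 0
        if mask.sum() < 2:
            return 1.0
        ratios = []
        for m in self.window:
            n = m.n_events
            if n == 0:
                continue
            expected = n * probs[mask]
            observed = m.probs.ravel()[mask] * n
            ratios.append(float(((observed - expected) ** 2 / expected).sum()) / (mask.sum() - 1))
        if not ratios:
            return 1.0
        # days are compared against the window's own mean, which absorbs
        # 1/k of the variance; rescale as in a sample-variance df correction
        k = len(ratios)
        correction = k / (k - 1) if k > 1 else 1.0
        return max(1.0, float(np.mean(ratios)) * correction)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two (flattened) distributions."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


@dataclass(frozen=True)
class DayClassification:
    label: str  # "normal" | "abnormal"
    p_value: float
    tv_distance: float

    @property
    def is_abnormal(self) -> bool:
        return self.label == "abnormal"


def classify_day(
    day_map: ActivityProbabilityMap,
    baseline: BaselineMap,
    alpha: float = 0.05,
    n_resamples: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> DayClassification:
    """Test whether a day's activity map comes from the baseline distribution.

    The statistic is the total-variation distance between the day map and
    the baseline map. The null distribution is built by resampling, from
    the pooled day+baseline event distribution, both a synthetic day (at
    the observed day's event count) and a synthetic 7-day baseline (at
    the baseline's event counts), so the reference's own sampling noise
    is part of the null. Event counts are deflated by the baseline
    window's Pearson overdispersion (see :meth:`BaselineMap.dispersion`)
    so that the bursty within-day structure of real streams widens the
    null accordingly. The similarity probability is the fraction of
    resampled distances at least as large as the observed one; the day is
    ABNORMAL when that probability falls below ``alpha``.

    A day without any events is classified abnormal outright (p=0): total
    inactivity is a drastic departure from any non-empty baseline.
    """
    if not baseline.initialized:
        raise ValueError("baseline not initialized (needs 7 days)")
    if day_map.probs.shape != baseline.probs.shape:
        raise ValueError("day map and baseline shapes differ")
    rng = rng or np.random.default_rng()

    base_probs = baseline.probs
    tv_obs = total_variation(day_map.probs, base_probs)
    n_day = day_map.n_events
    if n_day == 0:
        return DayClassification("abnormal", 0.0, tv_obs)

    n_base = max(1, int(round(baseline.mean_events)))
    k = len(baseline.window)
    pooled = day_map.probs * n_day + base_probs * (k * n_base)
    pooled = (pooled / pooled.sum()).ravel()

    phi = baseline.dispersion()
    n_day_eff = max(1, int(round(n_day / phi)))
    n_base_eff = max(1, int(round(k * n_base / phi)))
    day_draws = rng.multinomial(n_day_eff, pooled, size=n_resamples) / n_day_eff
    base_draws = rng.multinomial(n_base_eff, pooled, size=n_resamples) / n_base_eff
    tv_null = 0.5 * np.abs(day_draws - base_draws).sum(axis=1)
    p_value = (1.0 + np.count_nonzero(tv_null >= tv_obs)) / (n_resamples + 1.0)
    label = "abnormal" if p_value < alpha else "normal"
    return DayClassification(label, float(p_value), tv_obs)


def update_baseline(
    baseline: BaselineMap,
    day_map: ActivityProbabilityMap,
    classification: DayClassification,
) -> BaselineMap:
    """Admit a normal day into the rolling window; abnormal days are ignored."""
    if classification.is_abnormal:
        return baseline
    new = BaselineMap(window=deque(baseline.window, maxlen=BASELINE_WINDOW))
    new.window.append(day_map)
    return new


def build_transition_graph(
    day_events: pd.DataFrame,
    layout: HouseholdLayout,
    max_gap_s: float = 300.0,
) -> nx.DiGraph:
    """Room-transition graph of one day from motion-sensor events.

    Consecutive PIR events in different rooms within ``max_gap_s``
    increment the directed edge between their rooms; same-room pairs and
    pairs separated by longer gaps (returns after long absences) count
    nothing. All layout rooms appear as vertices.
    """
    g = nx.DiGraph()
    g.add_nodes_from(sorted(layout.rooms))
    pir = day_events[day_events["kind"] == SensorKind.PIR.value]
    if len(pir) < 2:
        return g
    pir = pir.sort_values("timestamp", kind="stable")
    ts = pir["timestamp"].to_numpy()
    rooms = pir["room"].to_numpy()
    gap = np.timedelta64(int(max_gap_s * 1e9), "ns")
    for i in range(1, len(pir)):
        if rooms[i] != rooms[i - 1] and (ts[i] - ts[i - 1]) <= gap:
            a, b = rooms[i - 1], rooms[i]
            g.add_edge(a, b, weight=g.get_edge_data(a, b, {"weight": 0})["weight"] + 1)
    return g


def total_activity(graph: nx.DiGraph) -> int:
    """Daily activity measure: total transition count (sum of edge weights)."""
    return int(sum(w for _, _, w in graph.edges.data("weight")))


def percent_difference(day_activity: float, baseline_activity: float) -> float:
    """Relative difference of a day's activity to the baseline activity."""
    if baseline_activity <= 0:
        raise ValueError("baseline activity must be > 0 (undefined otherwise)")
    return (day_activity - baseline_activity) / baseline_activity


def fit_trend(x_days: Sequence[float], percent_diffs: Sequence[float]) -> "tuple[float, float]":
    """Ordinary least-squares line through (days since T0, percent diff).

    Returns ``(slope, intercept)``; slope is in percent-difference units
    per day.
    """
    x = np.asarray(x_days, dtype=float)
    y = np.asarray(percent_diffs, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values")
    slope, intercept = np.polyfit(x, y, deg=1)
    return float(slope), float(intercept)


def f_env(s: float, c: int, p: int) -> float:
    """Environmental-factors score |s| + c/p."""
    if p <= 0:
        raise ValueError("period length p must be > 0")
    if c < 0 or c > p:
        raise ValueError("abnormal-day count c must satisfy 0 <= c <= p")
    return abs(s) + c / p


@dataclass(frozen=True)
class EnvTrend:
    """Per-period inputs and value of the environmental score."""

    slope: float
    abnormal_days: int
    period_days: int
    intercept: float = 0.0
    threshold: float = DEFAULT_ENV_THRESHOLD
    percent_diffs: tuple = ()
    x_days: tuple = ()

    @property
    def value(self) -> float:
        return f_env(self.slope, self.abnormal_days, self.period_days)


def slope_for_period(
    x_days: Sequence[float],
    percent_diffs: Sequence[float],
    group: Optional[str] = None,
    min_days: int = 30,
) -> float:
    """Slope source priority: personal fit, then group line, then 0.

    A personal slope is fitted once >= ``min_days`` daily differences
    exist; otherwise the group reference slope is used when the resident's
    group is known; otherwise no slope information is available and s=0.
    """
    x = np.asarray(x_days, dtype=float)
    if x.size >= min_days and np.unique(x).size >= 2:
        return fit_trend(x, percent_diffs)[0]
    if group is not None:
        if group not in GROUP_SLOPES:
            raise ValueError(f"unknown group {group!r}")
        return GROUP_SLOPES[group]
    return 0.0


def detect_change_c3(
    trend: EnvTrend,
    *,
    period: tuple = (0, 1),
) -> ComponentOutput:
    """Flag an environmental change when f_env exceeds the threshold.

    Attribution: e115 when abnormal days contributed (c > 0), e245 when
    the slope contributed (|s| > 0); both when both. Direction is always
    unknown (a changed routine carries no sign).
    """
    flag = 1 if trend.value > trend.threshold else 0
    items: set = set()
    if flag:
        if trend.abnormal_days > 0:
            items.add("e115")
        if abs(trend.slope) > 0:
            items.add("e245")
    return ComponentOutput(
        component=3,
        flag=flag,
        icf_items=frozenset(items),
        direction=Direction.UNKNOWN,
        period=period,
    )
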