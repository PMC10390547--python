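"""Component 2 — ICF item b530 Weight maintenance functions.

Body-weight change is monitored indirectly through the time spent
preparing meals, computed from power-consumption plugs on kitchen
appliances together with kitchen motion/door activity. Daily
preparation minutes are the length of the union of active intervals: a
power reading above the appliance's standby draw opens an interval,
which closes after the draw stays below threshold for ``close_gap``;
kitchen PIR/door events extend a nearby interval; intervals closer than
``merge_gap`` merge into one preparation session.

The component flags a change (output 1) when the mean daily preparation
time of a period differs from a reference period by more than a relative
threshold ``delta``. The sign of the underlying weight change cannot be
inferred, so the direction is always unknown. For residents who do not
prepare meals themselves the component is unavailable and is excluded
from the fusion metric rather than reported as "no change".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ComponentOutput,
    ComponentUnavailableError,
    Direction,
    HouseholdLayout,
    SensorKind,
)


@dataclass(frozen=True)
class MealPrepParams:
    """Tunables of the meal-preparation time estimator.

    standby_watts
        Per-appliance standby draw; readings above it count as active.
    close_gap_s
        An active interval ends this long after its last above-standby
        reading (or earlier, at the first below-standby reading).
    merge_gap_s
        Active intervals separated by at most this gap merge into one
        preparation session.
    min_days
        Minimum days of data per period for a period mean to count.
    delta
        Relative change in mean daily preparation minutes that flags a
        body-weight change.
    """

    standby_watts: float = 5.0
    close_gap_s: float = 60.0
    merge_gap_s: float = 600.0
    min_days: int = 7
    delta: float = 0.15


def _power_intervals(
    sensor_events: pd.DataFrame, standby_watts: float, close_gap_s: float
) -> "list[tuple[pd.Timestamp, pd.Timestamp]]":
    """Active intervals of one power plug from its reading sequence."""
    ts = sensor_events["timestamp"].to_numpy()
    val = sensor_events["value"].to_numpy(dtype=float)
    close_gap = pd.Timedelta(seconds=close_gap_s)
    intervals = []
    start = None
    last_above = None
    for t, v in zip(ts, val):
        t = pd.Timestamp(t)
        if v > standby_watts:
            if start is None:
                start = t
            last_above = t
        elif start is not None:
            intervals.append((start, min(last_above + close_gap, t)))
            start = None
    if start is not None:
        intervals.append((start, last_above + close_gap))
    return intervals


def merge_intervals(
    intervals: Sequence[tuple], merge_gap_s: float = 0.0
) -> "list[tuple[pd.Timestamp, pd.Timestamp]]":
    """Union of intervals, merging any separated by at most ``merge_gap_s``."""
    if not intervals:
        return []
    gap = pd.Timedelta(seconds=merge_gap_s)
    ordered = sorted((pd.Timestamp(a), pd.Timestamp(b)) for a, b in intervals)
    merged = [list(ordered[0])]
    for a, b in ordered[1:]:
        if a - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def meal_prep_time_daily(
    day_events: pd.DataFrame,
    kitchen_sensors: Sequence[str],
    params: Optional[MealPrepParams] = None,
) -> float:
    """Minutes spent preparing meals on one day.

    Power plugs among ``kitchen_sensors`` contribute active intervals;
    kitchen PIR/door events are instantaneous activity marks that extend
    a session when they fall within ``merge_gap_s`` of one. Marks with no
    appliance activity nearby contribute no time on their own.
    """
    params = params or MealPrepParams()
    kitchen_sensors = list(kitchen_sensors)
    if not kitchen_sensors:
        raise ComponentUnavailableError("no kitchen sensors configured")
    ev = day_events[day_events["sensor_id"].isin(kitchen_sensors)]
    if len(ev) == 0:
        return 0.0

    power_iv: list = []
    for sid, grp in ev[ev["kind"] == SensorKind.POWER.value].groupby("sensor_id"):
        power_iv.extend(
            _power_intervals(grp, params.standby_watts, params.close_gap_s)
        )
    if not power_iv:
        return 0.0
    marks = ev.loc[ev["kind"] != SensorKind.POWER.value, "timestamp"]

    pieces = [(a, b, True) for a, b in power_iv] + [
        (pd.Timestamp(t), pd.Timestamp(t), False) for t in marks
    ]
    gap = pd.Timedelta(seconds=params.merge_gap_s)
    pieces.sort(key=lambda p: (p[0], p[1]))
    sessions = []  # [start, end, has_power]
    for a, b, is_power in pieces:
        if sessions and a - sessions[-1][1] <= gap:
            sessions[-1][1] = max(sessions[-1][1], b)
            sessions[-1][2] = sessions[-1][2] or is_power
        else:
            sessions.append([a, b, is_power])
    total = sum(
        (end - start).total_seconds() for start, end, has_power in sessions if has_power
    )
    return total / 60.0


@dataclass
class MealPrepProfile:
    """Daily preparation minutes and per-period means for one resident."""

    daily_minutes: pd.Series  # index: calendar date
    available: bool = True
    period_of_day: Optional[Mapping[date, int]] = None

    def period_mean(self, period: int, min_days: int = 1) -> Optional[float]:
        """Mean daily minutes in one assessment period; None if too sparse."""
        if self.period_of_day is None:
            raise ValueError("profile has no period assignment")
        days = [d for d, p in self.period_of_day.items() if p == period]
        vals = self.daily_minutes.reindex(days).dropna()
        if len(vals) < min_days:
            return None
        return float(vals.mean())


def build_meal_profile(
    daily_minutes: Mapping[date, float],
    period_of_day: Mapping[date, int],
    available: bool = True,
) -> MealPrepProfile:
    s = pd.Series(dict(daily_minutes), dtype=float).sort_index()
    if ((s < 0) | (s > 1440)).any():
        raise ValueError("daily minutes must be within [0, 1440]")
    return MealPrepProfile(daily_minutes=s, available=available, period_of_day=dict(period_of_day))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation; NaN when either sequence is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def detect_change_c2(
    profile: MealPrepProfile,
    period_pair: tuple,
    params: Optional[MealPrepParams] = None,
) -> ComponentOutput:
    """Flag a body-weight change from meal-preparation time.

    Compares the mean daily preparation minutes of the two periods in
    ``period_pair``; the flag is 1 iff the relative change exceeds
    ``params.delta`` in absolute value. Direction is always unknown.
    """
    params = params or MealPrepParams()
    ref_period, cur_period = period_pair
    if not profile.available:
        return ComponentOutput(component=2, flag=0, period=period_pair, available=False)
    ref = profile.period_mean(ref_period, params.min_days)
    cur = profile.period_mean(cur_period, params.min_days)
    if ref is None or cur is None:
        return ComponentOutput(component=2, flag=0, period=period_pair, available=False)
    if ref == 0.0:
        changed = cur > 0.0
    else:
        changed = abs(cur - ref) / ref >= params.delta
    if not changed:
        return ComponentOutput(component=2, flag=0, period=period_pair)
    return ComponentOutput(
        component=2,
        flag=1,
        icf_items=frozenset({"b530"}),
        direction=Direction.UNKNOWN,
        period=period_pair,
    )
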