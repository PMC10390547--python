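"""Synthetic household generator with plantable functional-status drifts.

Generates, for one simulated resident, everything the monitoring
pipeline consumes: a domestic sensor event stream, wearable IMU windows,
and a monthly assessment series — together with the planted ground truth
needed for recovery tests.

Generative model (the weakest assumptions under which the pipeline's
statistics are well defined):

* each non-movement sensor fires as an inhomogeneous Poisson process
  with an hour-of-day rate profile;
* movement is a Markov chain over rooms driven by an hourly movement
  rate; each move emits a PIR event in the room moved to, so the daily
  room-transition graph has the chain's transition statistics;
* meals are two kitchen sessions per day (kettle + stove power draw with
  periodic readings, kitchen motion marks) whose durations set the daily
  preparation time;
* monthly body weight is coupled to the previous month's mean daily
  preparation time (0.2 kg per daily minute by default). The coupling is
  deterministic by default so the monthly weight series is an exact
  monotone function of preparation time, reproducing the near-perfect
  rank correlation the component relies on;
* a mobility level per month fixes the TUG time and SPPB points and the
  gait amplitude of the IMU windows.

Injectable drifts: gradual activity decline (plants a percent-difference
trend slope), abrupt routine shift (plants abnormal days), appliance
disuse, weight loss (5%-in-3-months malnutrition pattern), and mobility
deterioration (TUG band shift with SPPB drop).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AssessmentRecord,
    HouseholdLayout,
    ImuWindow,
    SensorKind,
    SensorSpec,
    empty_events,
    EVENT_COLUMNS,
)
from .activities import (
    SPPB_AMPLITUDE_BASE,
    SPPB_AMPLITUDE_STEP,
    TUG_AMPLITUDE_LADDER,
)
from .environment import CONTROL_SLOPE
from .icf import tug_seconds_to_category

ROOMS = ("kitchen", "living_room", "bedroom", "bathroom", "hallway")

DRIFT_KINDS = (
    "activity_decline",
    "routine_shift",
    "appliance_disuse",
    "weight_loss",
    "mobility_decline",
)


def default_layout() -> HouseholdLayout:
    """A one-person flat: five rooms, PIR everywhere, kitchen appliances."""
    sensors = {
        "pir_kitchen": SensorSpec(SensorKind.PIR, "kitchen"),
        "pir_living_room": SensorSpec(SensorKind.PIR, "living_room"),
        "pir_bedroom": SensorSpec(SensorKind.PIR, "bedroom"),
        "pir_bathroom": SensorSpec(SensorKind.PIR, "bathroom"),
        "pir_hallway": SensorSpec(SensorKind.PIR, "hallway"),
        "door_front": SensorSpec(SensorKind.DOOR_CONTACT, "hallway"),
        "door_fridge": SensorSpec(SensorKind.DOOR_CONTACT, "kitchen"),
        "power_kettle": SensorSpec(SensorKind.POWER, "kitchen"),
        "power_stove": SensorSpec(SensorKind.POWER, "kitchen"),
        "bed_sensor": SensorSpec(SensorKind.CONCUSSION, "bedroom"),
        "key_switch": SensorSpec(SensorKind.KEY_SWITCH, "hallway"),
    }
    adjacency = set()
    for room in ("kitchen", "living_room", "bedroom", "bathroom"):
        adjacency.add(("hallway", room))
        adjacency.add((room, "hallway"))
    adjacency.add(("kitchen", "living_room"))
    adjacency.add(("living_room", "kitchen"))
    return HouseholdLayout(rooms=frozenset(ROOMS), sensors=sensors, adjacency=adjacency)


def default_movement_rate() -> np.ndarray:
    """Moves per hour over the day: quiet nights, busy mornings/evenings."""
    rate = np.zeros(24)
    rate[0:6] = 0.5
    rate[6] = 4.0
    rate[7:10] = 10.0
    rate[10:17] = 8.0
    rate[17:22] = 10.0
    rate[22] = 4.0
    rate[23] = 1.0
    return rate


def default_transition_matrix() -> np.ndarray:
    """Row-stochastic room-to-room matrix (rows/cols ordered as ROOMS).

    The diagonal is within-room movement (PIR retrigger without a room
    transition); off-diagonal mass follows the flat's adjacency through
    the hallway.
    """
    idx = {r: i for i, r in enumerate(ROOMS)}
    m = np.zeros((5, 5))
    stay = 0.50
    for room in ROOMS:
        i = idx[room]
        m[i, i] = stay
        if room == "hallway":
            for other, w in (("kitchen", 0.15), ("living_room", 0.15),
                             ("bedroom", 0.10), ("bathroom", 0.10)):
                m[i, idx[other]] = w
        else:
            m[i, idx["hallway"]] = 0.35
            if room == "kitchen":
                m[i, idx["living_room"]] = 0.15
            elif room == "living_room":
                m[i, idx["kitchen"]] = 0.15
            else:
                m[i, idx["hallway"]] = 0.50
    return m / m.sum(axis=1, keepdims=True)


def default_sensor_rates() -> "dict[str, np.ndarray]":
    """Hourly Poisson rates of the non-movement, non-appliance sensors."""
    front = np.zeros(24)
    front[9:12] = 0.3
    front[14:18] = 0.3
    fridge = np.zeros(24)
    fridge[7:9] = 1.0
    fridge[12:14] = 0.8
    fridge[17:20] = 1.0
    bed = np.zeros(24)
    bed[22:24] = 1.0
    bed[0:6] = 0.4
    key = np.zeros(24)
    key[9:18] = 0.05
    return {
        "door_front": front,
        "door_fridge": fridge,
        "bed_sensor": bed,
        "key_switch": key,
    }


@dataclass(frozen=True)
class MealModel:
    sessions_hours: tuple = (8, 18)
    duration_mean_min: float = 35.0
    duration_sd_min: float = 5.0
    kettle_minutes: float = 8.0
    kettle_watts: float = 1800.0
    stove_watts: float = 1500.0
    kettle_sample_s: float = 15.0
    stove_sample_s: float = 60.0
    pir_mark_s: float = 180.0


@dataclass(frozen=True)
class WeightModel:
    base_kg: float = 70.0
    kg_per_minute: float = 0.2
    noise_sd_kg: float = 0.0


@dataclass(frozen=True)
class MobilityModel:
    tug_seconds: float = 24.0
    sppb: int = 6
    hgs_base_kg: float = 14.0


@dataclass(frozen=True)
class ImuModel:
    windows_per_month: int = 40
    sample_rate_hz: int = 100
    window_s: float = 1.0
    gait_freq_hz: float = 1.8
    axis_noise_g: float = 0.03


@dataclass(frozen=True)
class DriftSpec:
    """One planted drift; fields beyond ``kind``/``onset_day`` are per-kind.

    magnitude: slope per day (activity_decline), hour offset
    (routine_shift), weight fraction (weight_loss), TUG seconds added
    (mobility_decline); unused for appliance_disuse.
    """

    kind: str
    onset_day: int
    magnitude: float = 0.0
    end_day: Optional[int] = None
    span_days: int = 60
    sensor_id: Optional[str] = None
    sppb_drop: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DRIFT_KINDS:
            raise ValueError(f"unknown drift kind {self.kind!r}")
        if self.kind == "appliance_disuse" and not self.sensor_id:
            raise ValueError("appliance_disuse needs sensor_id")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of one simulated household."""

    seed: int = 0
    duration_days: int = 310
    assessment_interval_days: int = 31
    start_date: date = date(2014, 7, 1)
    layout: HouseholdLayout = field(default_factory=default_layout)
    movement_rate: np.ndarray = field(default_factory=default_movement_rate)
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    sensor_rates: dict = field(default_factory=default_sensor_rates)
    meals: MealModel = field(default_factory=MealModel)
    weight: WeightModel = field(default_factory=WeightModel)
    mobility: MobilityModel = field(default_factory=MobilityModel)
    imu: ImuModel = field(default_factory=ImuModel)
    drifts: tuple = ()
    prepares_meals: bool = True
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.duration_days < 14:
            raise ValueError("duration_days must be >= 14")
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (len(ROOMS), len(ROOMS)) or (tm < 0).any():
            raise ValueError("transition matrix must be non-negative 5x5")
        if not np.allclose(tm.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        object.__setattr__(self, "transition_matrix", tm)
        mr = np.asarray(self.movement_rate, dtype=float)
        if mr.shape != (24,) or (mr < 0).any():
            raise ValueError("movement_rate must be 24 non-negative hourly rates")
        object.__setattr__(self, "movement_rate", mr)
        object.__setattr__(self, "drifts", tuple(self.drifts))

    @property
    def n_months(self) -> int:
        return self.duration_days // self.assessment_interval_days


@dataclass
class SimulationResult:
    """Simulator output bundle: streams, assessments and planted truth."""

    events: pd.DataFrame
    imu_windows: "list[ImuWindow]"
    assessments: "list[AssessmentRecord]"
    truth: dict
    config: ScenarioConfig


def _drift(config: ScenarioConfig, kind: str) -> Optional[DriftSpec]:
    for d in config.drifts:
        if d.kind == kind:
            return d
    return None


def _activity_scale(config: ScenarioConfig, day: int) -> float:
    d = _drift(config, "activity_decline")
    if d is None or day < d.onset_day:
        return 1.0
    return max(0.05, 1.0 + d.magnitude * (day - d.onset_day))


def _prep_scale(config: ScenarioConfig, day: int) -> float:
    d = _drift(config, "weight_loss")
    if d is None or day < d.onset_day:
        return 1.0
    delta_kg = d.magnitude * config.weight.base_kg
    delta_min = delta_kg / config.weight.kg_per_minute
    base_daily = len(config.meals.sessions_hours) * config.meals.duration_mean_min
    frac = min(1.0, (day - d.onset_day) / max(1, d.span_days))
    return max(0.1, 1.0 - frac * delta_min / base_daily)


def _mobility_for_month(config: ScenarioConfig, month: int) -> "tuple[float, int]":
    tug = config.mobility.tug_seconds
    sppb = config.mobility.sppb
    d = _drift(config, "mobility_decline")
    if d is not None and month * config.assessment_interval_days >= d.onset_day:
        tug += d.magnitude
        sppb = max(0, sppb - d.sppb_drop)
    return tug, sppb


def simulate_household(config: ScenarioConfig) -> SimulationResult:
    """Generate the full sensor/IMU/assessment bundle for one scenario.

    Reproducible: the same config (including seed) yields identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    tm = config.transition_matrix
    room_index = {r: i for i, r in enumerate(ROOMS)}
    pir_of_room = {
        spec.room: sid
        for sid, spec in layout.sensors.items()
        if spec.kind == SensorKind.PIR
    }

    rows: list = []
    daily_prep_truth: dict = {}
    current_room = "bedroom"

    def add(ts: datetime, sid: str, value: float) -> None:
        spec = layout.sensors[sid]
        rows.append((ts, sid, spec.kind.value, float(value), spec.room))

    for day in range(config.duration_days):
        day_date = config.start_date + timedelta(days=day)
        midnight = datetime.combine(day_date, datetime.min.time())
        scale = _activity_scale(config, day)

        # movement: Markov chain over rooms, PIR event per move
        for hour in range(24):
            lam = config.movement_rate[hour] * scale
            n = rng.poisson(lam)
            if n == 0:
                continue
            offsets = np.sort(rng.uniform(0, 3600, size=n))
            for off in offsets:
                i = room_index[current_room]
                current_room = ROOMS[rng.choice(len(ROOMS), p=tm[i])]
                add(midnight + timedelta(seconds=float(off) + hour * 3600,),
                    pir_of_room[current_room], 1)

        # other home sensors: inhomogeneous Poisson per hour
        for sid, profile in config.sensor_rates.items():
            if sid not in layout.sensors:
                continue
            for hour in range(24):
                n = rng.poisson(profile[hour] * scale)
                for off in rng.uniform(0, 3600, size=n):
                    add(midnight + timedelta(seconds=float(off) + hour * 3600), sid, 1)

        # meal sessions: kettle + stove power draw, kitchen motion marks
        prep_minutes = 0.0
        if config.prepares_meals:
            m = config.meals
            pscale = _prep_scale(config, day)
            for sess_hour in m.sessions_hours:
                # sessions sit inside their hour (start ~hh:10) so the hour
                # histogram is stable day to day; the drift detector's null
                # assumes no systematic mass swap across bin edges
                start_s = sess_hour * 3600 + 600 + rng.normal(0, 180)
                dur_min = max(5.0, rng.normal(m.duration_mean_min, m.duration_sd_min))
                dur_min *= pscale
                start = midnight + timedelta(seconds=float(start_s))
                end = start + timedelta(minutes=dur_min)
                kettle_end = min(end, start + timedelta(minutes=m.kettle_minutes))
                t = start
                while t < kettle_end:
                    add(t, "power_kettle", m.kettle_watts)
                    t += timedelta(seconds=m.kettle_sample_s)
                add(kettle_end, "power_kettle", 0.0)
                t = start
                while t < end:
                    add(t, "power_stove", m.stove_watts)
                    t += timedelta(seconds=m.stove_sample_s)
                add(end, "power_stove", 0.0)
                t = start
                while t < end:
                    add(t, pir_of_room["kitchen"], 1)
                    t += timedelta(seconds=m.pir_mark_s)
                prep_minutes += dur_min
        daily_prep_truth[day_date] = prep_minutes

    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    events["timestamp"] = pd.to_datetime(events["timestamp"])
    events = events.sort_values("timestamp", kind="stable").reset_index(drop=True)

    # post-hoc stream drifts
    abnormal_days: list = []
    shift = _drift(config, "routine_shift")
    if shift is not None:
        events, ann = inject_drift(events, shift, start_date=config.start_date)
        abnormal_days = ann["affected_days"]
    disuse = _drift(config, "appliance_disuse")
    disused_days: list = []
    if disuse is not None:
        events, ann = inject_drift(events, disuse, start_date=config.start_date)
        disused_days = ann["affected_days"]

    # monthly assessments and IMU windows
    n_months = config.n_months
    interval = config.assessment_interval_days
    monthly_prep = []
    for month in range(n_months):
        days = [config.start_date + timedelta(days=d)
                for d in range(month * interval, (month + 1) * interval)]
        monthly_prep.append(float(np.mean([daily_prep_truth[d] for d in days])))

    tug_by_month, sppb_by_month = [], []
    for month in range(n_months):
        tug, sppb = _mobility_for_month(config, month)
        tug_by_month.append(tug)
        sppb_by_month.append(sppb)

    assessments = []
    weights = []
    for k in range(n_months + 1):
        t_day = min(k * interval, config.duration_days)
        prep_ref = monthly_prep[k - 1] if k >= 1 else (
            len(config.meals.sessions_hours) * config.meals.duration_mean_min
        )
        nominal = len(config.meals.sessions_hours) * config.meals.duration_mean_min
        w = config.weight.base_kg + config.weight.kg_per_minute * (prep_ref - nominal)
        if config.weight.noise_sd_kg > 0:
            w += rng.normal(0, config.weight.noise_sd_kg)
        weights.append(w)
        month = min(k, n_months - 1)
        tug, sppb = tug_by_month[month], sppb_by_month[month]
        assessments.append(
            AssessmentRecord(
                time_point=k,
                date=config.start_date + timedelta(days=t_day),
                sppb=sppb,
                tug_seconds=round(tug, 2),
                weight_kg=round(w, 2),
                hgs_kg=round(config.mobility.hgs_base_kg + 0.3 * sppb, 1),
            )
        )

    imu_windows = simulate_imu_windows(config, tug_by_month, sppb_by_month, rng)

    act = _drift(config, "activity_decline")
    wl = _drift(config, "weight_loss")
    truth = {
        "planted_slope": act.magnitude if act is not None else 0.0,
        "abnormal_days": sorted(abnormal_days),
        "disused_days": sorted(disused_days),
        "monthly_prep_minutes": monthly_prep,
        "daily_prep_minutes": {d.isoformat(): v for d, v in daily_prep_truth.items()},
        "weights_kg": [round(w, 4) for w in weights],
        "tug_seconds_by_month": tug_by_month,
        "tug_category_by_month": [tug_seconds_to_category(t) for t in tug_by_month],
        "sppb_by_month": sppb_by_month,
        "planted_weight_change_frac": wl.magnitude if wl is not None else 0.0,
        "drift_kinds": [d.kind for d in config.drifts],
    }
    return SimulationResult(
        events=events,
        imu_windows=imu_windows,
        assessments=assessments,
        truth=truth,
        config=config,
    )


def simulate_imu_windows(
    config: ScenarioConfig,
    tug_by_month: Sequence[float],
    sppb_by_month: Sequence[int],
    rng: np.random.Generator,
) -> "list[ImuWindow]":
    """Gait-like windows whose amplitudes encode the monthly mobility level."""
    imu = config.imu
    n = int(imu.sample_rate_hz * imu.window_s)
    t = np.arange(n) / imu.sample_rate_hz
    interval = config.assessment_interval_days
    windows = []
    for month in range(config.n_months):
        cat = tug_seconds_to_category(tug_by_month[month])
        a_tug = TUG_AMPLITUDE_LADDER[cat]
        a_sppb = SPPB_AMPLITUDE_BASE + SPPB_AMPLITUDE_STEP * sppb_by_month[month]
        for w in range(imu.windows_per_month):
            day = month * interval + (w % interval)
            start = datetime.combine(
                config.start_date + timedelta(days=day), datetime.min.time()
            ) + timedelta(hours=10, minutes=int(w // interval) * 7)
            phase = rng.uniform(0, 2 * np.pi)
            noise = lambda s: rng.normal(0, s, size=(n, 3))

            def triaxial(vertical: np.ndarray, s: float) -> np.ndarray:
                arr = noise(s)
                arr[:, 2] += vertical
                return arr

            acc_low = triaxial(1.0 + a_tug * np.sin(2 * np.pi * imu.gait_freq_hz * t + phase),
                               imu.axis_noise_g)
            acc_wide = triaxial(1.0 + a_sppb * np.sin(2 * np.pi * imu.gait_freq_hz * t + phase),
                                imu.axis_noise_g / 3)
            gyro = triaxial(0.5 * a_tug * np.sin(2 * np.pi * imu.gait_freq_hz * t + phase),
                            0.02)
            mag = noise(0.01) + np.array([0.2, 0.0, 0.4])
            windows.append(
                ImuWindow(
                    start=start,
                    duration=imu.window_s,
                    samples={
                        "acc_low": acc_low,
                        "acc_wide": acc_wide,
                        "gyro": gyro,
                        "mag": mag,
                    },
                )
            )
    return windows


def inject_drift(
    events: pd.DataFrame,
    drift: DriftSpec,
    *,
    start_date: Optional[date] = None,
    rng: Optional[np.random.Generator] = None,
) -> "tuple[pd.DataFrame, dict]":
    """Apply a stream-level drift to an event log.

    Supported on streams: ``routine_shift`` (event hours offset by
    ``magnitude`` hours, wrapping within the day), ``appliance_disuse``
    (the sensor's events vanish), ``activity_decline`` (p-thinning with
    keep probability declining by ``|magnitude|`` per day past onset).
    Mobility deterioration and weight loss act on the generator's
    assessment/meal synthesis, not on an existing stream. Returns the
    modified stream and a ground-truth annotation of affected days.
    """
    if drift.kind not in ("routine_shift", "appliance_disuse", "activity_decline"):
        raise ValueError(f"drift kind {drift.kind!r} is not a stream drift")
    if len(events) == 0:
        return events.copy(), {"affected_days": []}
    ts = pd.to_datetime(events["timestamp"])
    t0 = start_date or ts.min().date()
    day_index = (ts.dt.normalize() - pd.Timestamp(t0)).dt.days
    end = drift.end_day if drift.end_day is not None else int(day_index.max()) + 1
    in_window = (day_index >= drift.onset_day) & (day_index < end)

    out = events.copy()
    if drift.kind == "routine_shift":
        offset = int(drift.magnitude)
        if offset % 24 != 0 and in_window.any():
            shifted = ts[in_window]
            new_hour = (shifted.dt.hour + offset) % 24
            out.loc[in_window, "timestamp"] = (
                shifted.dt.normalize()
                + pd.to_timedelta(new_hour, unit="h")
                + pd.to_timedelta(shifted.dt.minute, unit="m")
                + pd.to_timedelta(shifted.dt.second, unit="s")
                + pd.to_timedelta(shifted.dt.microsecond, unit="us")
            )
        affected = in_window if offset % 24 != 0 else in_window & False
    elif drift.kind == "appliance_disuse":
        drop = in_window & (events["sensor_id"] == drift.sensor_id)
        out = out[~drop]
        affected = in_window
    else:  # activity_decline via p-thinning
        rng = rng or np.random.default_rng(0)
        keep_p = np.clip(1.0 + drift.magnitude * (day_index - drift.onset_day), 0.05, 1.0)
        keep = rng.uniform(size=len(out)) <= np.where(in_window, keep_p, 1.0)
        out = out[keep]
        affected = in_window & (abs(drift.magnitude) > 0)

    days = sorted(set(day_index[affected]))
    out = out.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return out, {"affected_days": [int(d) for d in days]}


# ---------------------------------------------------------------------------
# scenario presets

PRESET_NAMES = (
    "drift-free",
    "control-decline",
    "routine-shift",
    "appliance-disuse",
    "malnutrition",
    "fluctuation",
    "mobility-decline",
)


def make_scenario(preset: str, seed: int = 0, duration_days: int = 310) -> ScenarioConfig:
    """Build a preset scenario; all presets share the default household.

    * drift-free: stationary routine, stable mobility and weight.
    * control-decline: gradual activity decline at the control group's
      reference slope plus a 12-day routine shift in the final month.
    * routine-shift: the daily routine moves 6 hours from day 155 on.
    * appliance-disuse: the kettle stops being used from day 155 on.
    * malnutrition: 5% body-weight loss expressed over ~2 months of
      shrinking meal preparation starting day 93.
    * fluctuation: a sub-1-kg weight wobble (0.8 kg) on the same schedule.
    * mobility-decline: TUG worsens by 13 s (category 2 -> 3) and SPPB
      drops 3 points from month 5.
    """
    base = dict(seed=seed, duration_days=duration_days)
    if preset == "drift-free":
        return ScenarioConfig(**base)
    if preset == "control-decline":
        return ScenarioConfig(
            group="control",
            drifts=(
                DriftSpec(kind="activity_decline", onset_day=0, magnitude=CONTROL_SLOPE),
                DriftSpec(
                    kind="routine_shift",
                    onset_day=duration_days - 12,
                    magnitude=6,
                ),
            ),
            **base,
        )
    if preset == "routine-shift":
        return ScenarioConfig(
            drifts=(DriftSpec(kind="routine_shift", onset_day=155, magnitude=6),), **base
        )
    if preset == "appliance-disuse":
        return ScenarioConfig(
            drifts=(
                DriftSpec(kind="appliance_disuse", onset_day=155, sensor_id="power_kettle"),
            ),
            **base,
        )
    if preset == "malnutrition":
        return ScenarioConfig(
            drifts=(
                DriftSpec(kind="weight_loss", onset_day=93, magnitude=0.05, span_days=60),
            ),
            **base,
        )
    if preset == "fluctuation":
        return ScenarioConfig(
            drifts=(
                DriftSpec(
                    kind="weight_loss", onset_day=93, magnitude=0.8 / 70.0, span_days=60
                ),
            ),
            **base,
        )
    if preset == "mobility-decline":
        return ScenarioConfig(
            mobility=MobilityModel(tug_seconds=15.0, sppb=8),
            drifts=(
                DriftSpec(
                    kind="mobility_decline", onset_day=155, magnitude=13.0, sppb_drop=3
                ),
            ),
            **base,
        )
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESET_NAMES}")
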