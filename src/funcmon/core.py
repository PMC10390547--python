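"""Shared domain types, event-stream validation and day segmentation.

The canonical in-memory representation of a sensor event log is a
:class:`pandas.DataFrame` with the columns ``timestamp`` (naive local
wall-clock datetimes), ``sensor_id``, ``kind``, ``value`` and ``room``.
:class:`SensorEvent` is the record-level contract for a single row.

Timestamps carry no timezone arithmetic: a deployment covers a single
home, and all downstream features (hour-of-day activity maps, day
segmentation) are defined on local clock time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

EVENT_COLUMNS = ("timestamp", "sensor_id", "kind", "value", "room")

#: IMU modalities carried by the wearable, in canonical order.
IMU_MODALITIES = ("acc_low", "acc_wide", "gyro", "mag")

#: ICF items the system reports on.
ICF_ITEMS = ("d450", "d460", "b530", "e115", "e245")


class SensorKind(str, Enum):
    """Kinds of home sensors; the kind fixes the value domain."""

    PIR = "pir"
    DOOR_CONTACT = "door_contact"
    POWER = "power"
    CONCUSSION = "concussion"
    KEY_SWITCH = "key_switch"


#: Kinds whose value must be 0 or 1.
BINARY_KINDS = frozenset(
    {SensorKind.PIR, SensorKind.DOOR_CONTACT, SensorKind.CONCUSSION, SensorKind.KEY_SWITCH}
)


class Direction(str, Enum):
    """Direction of a detected functional change."""

    IMPROVEMENT = "improvement"
    DETERIORATION = "deterioration"
    UNKNOWN = "unknown"


class FuncmonError(Exception):
    """Base class for package errors."""


class CorruptInputError(FuncmonError):
    """More than half of an event stream failed validation."""


class ComponentUnavailableError(FuncmonError):
    """A component's required sensors or data are not configured."""


@dataclass(frozen=True)
class SensorEvent:
    """One time-stamped reading from a named home sensor."""

    timestamp: datetime
    sensor_id: str
    kind: SensorKind
    value: float
    room: str

    def __post_init__(self) -> None:
        if pd.isna(self.timestamp):
            raise ValueError("timestamp must be finite")
        kind = SensorKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind in BINARY_KINDS and self.value not in (0, 1):
            raise ValueError(f"{kind.value} value must be 0/1, got {self.value}")
        if kind is SensorKind.POWER and self.value < 0:
            raise ValueError(f"power value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class SensorSpec:
    """Static description of one installed sensor."""

    kind: SensorKind
    room: str


@dataclass(frozen=True)
class HouseholdLayout:
    """Rooms, installed sensors and traversable room adjacency of one home."""

    rooms: frozenset
    sensors: Mapping[str, SensorSpec]
    adjacency: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rooms", frozenset(self.rooms))
        object.__setattr__(self, "sensors", dict(self.sensors))
        object.__setattr__(self, "adjacency", frozenset(tuple(p) for p in self.adjacency))
        for sid, spec in self.sensors.items():
            if spec.room not in self.rooms:
                raise ValueError(f"sensor {sid!r} placed in unknown room {spec.room!r}")
        for a, b in self.adjacency:
            if a == b:
                raise ValueError(f"adjacency must be irreflexive, got ({a!r},{a!r})")
            if a not in self.rooms or b not in self.rooms:
                raise ValueError(f"adjacency references unknown room in ({a!r},{b!r})")

    def sensors_of_kind(self, kind: SensorKind) -> list:
        return [sid for sid, spec in self.sensors.items() if spec.kind == SensorKind(kind)]

    def sensors_in_room(self, room: str) -> list:
        return [sid for sid, spec in self.sensors.items() if spec.room == room]

    @property
    def sensor_ids(self) -> tuple:
        return tuple(sorted(self.sensors))

    @classmethod
    def from_dict(cls, d: Mapping) -> "HouseholdLayout":
        sensors = {
            sid: SensorSpec(kind=SensorKind(s["kind"]), room=s["room"])
            for sid, s in d["sensors"].items()
        }
        return cls(
            rooms=frozenset(d["rooms"]),
            sensors=sensors,
            adjacency=frozenset(tuple(p) for p in d.get("adjacency", [])),
        )

    def to_dict(self) -> dict:
        return {
            "rooms": sorted(self.rooms),
            "sensors": {
                sid: {"kind": spec.kind.value, "room": spec.room}
                for sid, spec in sorted(self.sensors.items())
            },
            "adjacency": sorted(list(p) for p in self.adjacency),
        }


@dataclass(frozen=True)
class ImuWindow:
    """A fixed-duration block of 3-axis samples from the four IMU modalities.

    ``samples`` maps each modality in :data:`IMU_MODALITIES` to an array of
    shape ``(n, 3)``; all modalities are sampled at the same fixed rate, so
    the counts agree.
    """

    start: datetime
    samples: Mapping[str, np.ndarray]
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        samples = {}
        counts = set()
        for mod in IMU_MODALITIES:
            if mod not in self.samples:
                raise ValueError(f"missing modality {mod!r}")
            arr = np.asarray(self.samples[mod], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
                raise ValueError(f"modality {mod!r} must be a non-empty (n, 3) array")
            samples[mod] = arr
            counts.add(arr.shape[0])
        if len(counts) != 1:
            raise ValueError(f"modalities have unequal sample counts: {sorted(counts)}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return next(iter(self.samples.values())).shape[0]


@dataclass(frozen=True)
class AssessmentRecord:
    """One monthly geriatric assessment visit (time points T0..T10)."""

    time_point: int
    date: date
    sppb: Optional[int] = None
    tug_seconds: Optional[float] = None
    weight_kg: Optional[float] = None
    hgs_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sppb is not None and not 0 <= self.sppb <= 12:
            raise ValueError(f"SPPB must be in [0, 12], got {self.sppb}")
        if self.tug_seconds is not None and self.tug_seconds <= 0:
            raise ValueError(f"TUG seconds must be > 0, got {self.tug_seconds}")
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight_kg}")


@dataclass(frozen=True)
class ComponentOutput:
    """Binary change flag of one component with ICF attribution."""

    component: int
    flag: int
    icf_items: frozenset = frozenset()
    direction: Direction = Direction.UNKNOWN
    period: tuple = (0, 1)
    available: bool = True

    def __post_init__(self) -> None:
        if self.component not in (1, 2, 3):
            raise ValueError("component must be 1, 2 or 3")
        if self.flag not in (0, 1):
            raise ValueError("flag must be 0 or 1")
        object.__setattr__(self, "icf_items", frozenset(self.icf_items))
        bad = self.icf_items - set(ICF_ITEMS)
        if bad:
            raise ValueError(f"unknown ICF items {sorted(bad)}")

    def to_dict(self) -> dict:
        return {
            "flag": self.flag,
            "items": sorted(self.icf_items),
            "direction": self.direction.value,
        }


def events_to_frame(events: Iterable[SensorEvent]) -> pd.DataFrame:
    """Pack :class:`SensorEvent` records into the canonical DataFrame."""
    rows = [
        (e.timestamp, e.sensor_id, e.kind.value, float(e.value), e.room) for e in events
    ]
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def empty_events() -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in EVENT_COLUMNS})
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["value"] = df["value"].astype(float)
    return df


def segment_days(events: pd.DataFrame) -> "dict[date, pd.DataFrame]":
    """Split an event stream into calendar days at local midnight.

    Within-day ordering is preserved as given; the union of the output
    frames equals the input (every event lands in exactly one day).
    """
    if len(events) == 0:
        return {}
    ts = pd.to_datetime(events["timestamp"])
    if ts.isna().any():
        bad = list(events.index[ts.isna()])
        raise ValueError(f"unparseable timestamps at index {bad}")
    days = {}
    for day, group in events.groupby(ts.dt.date, sort=True):
        days[day] = group
    return days


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_events`: kept/rejected bookkeeping."""

    n_input: int
    n_kept: int
    n_rejected: int
    n_deduplicated: int = 0
    reasons: Counter = field(default_factory=Counter)
    rejected_index: list = field(default_factory=list)


def validate_events(
    events: pd.DataFrame,
    layout: HouseholdLayout,
    *,
    pir_debounce_s: float = 2.0,
    max_reject_fraction: float = 0.5,
) -> "tuple[pd.DataFrame, ValidationReport]":
    """Validate an event stream against a household layout.

    Rejects events whose sensor is not installed, whose kind disagrees
    with the layout, or whose value violates the kind's domain (binary
    kinds must be 0/1, power must be non-negative). Exact duplicates are
    dropped and PIR retriggers within ``pir_debounce_s`` of the previous
    event of the same sensor collapse to one event. Output is sorted by
    timestamp. The function is idempotent on its own output.

    Raises
    ------
    CorruptInputError
        If more than ``max_reject_fraction`` of the events are rejected.
    """
    n_input = len(events)
    report = ValidationReport(n_input=n_input, n_kept=0, n_rejected=0)
    if n_input == 0:
        return empty_events(), report

    df = events.copy()
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    ok = ts.notna()
    for idx in df.index[~ok]:
        report.reasons["unparseable_timestamp"] += 1
        report.rejected_index.append(idx)
    df = df[ok].copy()
    df["timestamp"] = ts[ok]

    known = df["sensor_id"].map(lambda s: s in layout.sensors)
    for idx in df.index[~known]:
        report.reasons["unknown_sensor"] += 1
        report.rejected_index.append(idx)
    df = df[known]

    if len(df):
        expected_kind = df["sensor_id"].map(lambda s: layout.sensors[s].kind.value)
        kind_ok = df["kind"].astype(str) == expected_kind
        for idx in df.index[~kind_ok]:
            report.reasons["kind_mismatch"] += 1
            report.rejected_index.append(idx)
        df = df[kind_ok]

    if len(df):
        value = pd.to_numeric(df["value"], errors="coerce")
        is_binary = df["kind"].map(lambda k: SensorKind(k) in BINARY_KINDS)
        dom_ok = value.notna() & np.isfinite(value)
        dom_ok &= np.where(is_binary, value.isin([0, 1]), value >= 0)
        for idx in df.index[~dom_ok]:
            report.reasons["value_domain"] += 1
            report.rejected_index.append(idx)
        df = df[dom_ok].copy()
        df["value"] = value[dom_ok]

    report.n_rejected = n_input - len(df)
    if n_input > 0 and report.n_rejected / n_input > max_reject_fraction:
        raise CorruptInputError(
            f"{report.n_rejected}/{n_input} events rejected "
            f"({report.reasons.most_common(3)}); input looks corrupted"
        )

    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)

    # exact duplicates (same sensor, same instant, same value) count once
    before = len(df)
    df = df.drop_duplicates(subset=["timestamp", "sensor_id", "value"], keep="first")

    # PIR retrigger debounce: repeated firings of the same sensor within the
    # debounce gap are one detection, not several
    if pir_debounce_s > 0 and len(df):
        is_pir = df["kind"].astype(str) == SensorKind.PIR.value
        keep = np.ones(len(df), dtype=bool)
        last_fire: dict = {}
        ts_arr = df["timestamp"].to_numpy()
        sid_arr = df["sensor_id"].to_numpy()
        pir_arr = is_pir.to_numpy()
        gap = np.timedelta64(int(pir_debounce_s * 1e9), "ns")
        for i in range(len(df)):
            if not pir_arr[i]:
                continue
            prev = last_fire.get(sid_arr[i])
            if prev is not None and (ts_arr[i] - prev) < gap:
                keep[i] = False
            else:
                last_fire[sid_arr[i]] = ts_arr[i]
        df = df[keep]

    report.n_deduplicated = before - len(df)
    df = df.reset_index(drop=True)
    report.n_kept = len(df)
    return df, report
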