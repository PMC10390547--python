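"""Readers and writers for the on-disk formats.

Everything is plain text: event logs and assessments are CSV, the
household layout and run configuration are YAML, reports and simulation
ground truth are JSON, IMU streams are one CSV per modality
(``imu_<modality>.csv`` with columns timestamp,x,y,z; consecutive rows
are regrouped into fixed-rate windows on read). Round-trips are lossless
for all fields defined here.
"""

from __future__ import annotations

import json
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    AssessmentRecord,
    EVENT_COLUMNS,
    HouseholdLayout,
    IMU_MODALITIES,
    ImuWindow,
)
from .fusion import MonthlyReport


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event log {path} lacks columns {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df[list(EVENT_COLUMNS)]


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, index=False)


def read_layout(path) -> HouseholdLayout:
    with open(path) as fh:
        return HouseholdLayout.from_dict(yaml.safe_load(fh))


def write_layout(layout: HouseholdLayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout.to_dict(), fh, sort_keys=True)


def read_assessments(path) -> "list[AssessmentRecord]":
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        def opt(col, cast):
            v = row.get(col)
            return None if pd.isna(v) else cast(v)

        records.append(
            AssessmentRecord(
                time_point=int(row["time_point"]),
                date=pd.Timestamp(row["date"]).date(),
                sppb=opt("sppb", int),
                tug_seconds=opt("tug_seconds", float),
                weight_kg=opt("weight_kg", float),
                hgs_kg=opt("hgs_kg", float),
            )
        )
    return sorted(records, key=lambda a: a.time_point)


def write_assessments(records: Sequence[AssessmentRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "time_point": a.time_point,
                "date": a.date.isoformat(),
                "sppb": a.sppb,
                "tug_seconds": a.tug_seconds,
                "weight_kg": a.weight_kg,
                "hgs_kg": a.hgs_kg,
            }
            for a in records
        ]
    ).to_csv(path, index=False)


def write_imu(windows: Sequence[ImuWindow], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for mod in IMU_MODALITIES:
        rows = []
        for w in windows:
            n = w.n_samples
            ts = [w.start + pd.Timedelta(seconds=i * w.duration / n) for i in range(n)]
            arr = w.samples[mod]
            for t, (x, y, z) in zip(ts, arr):
                rows.append((t.strftime("%Y-%m-%dT%H:%M:%S.%f"), x, y, z))
        pd.DataFrame(rows, columns=["timestamp", "x", "y", "z"]).to_csv(
            directory / f"imu_{mod}.csv", index=False
        )


def read_imu(directory, samples_per_window: int, window_s: float = 1.0) -> "list[ImuWindow]":
    """Regroup modality CSVs into windows of ``samples_per_window`` rows."""
    directory = Path(directory)
    frames = {}
    for mod in IMU_MODALITIES:
        df = pd.read_csv(directory / f"imu_{mod}.csv")
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        frames[mod] = df
    n_rows = {mod: len(df) for mod, df in frames.items()}
    if len(set(n_rows.values())) != 1:
        raise ValueError(f"modalities have unequal row counts: {n_rows}")
    total = next(iter(n_rows.values()))
    if total % samples_per_window:
        raise ValueError("row count is not a multiple of samples_per_window")
    windows = []
    for i in range(0, total, samples_per_window):
        samples = {
            mod: frames[mod][["x", "y", "z"]].iloc[i : i + samples_per_window].to_numpy()
            for mod in IMU_MODALITIES
        }
        start = frames["acc_low"]["timestamp"].iloc[i].to_pydatetime()
        windows.append(ImuWindow(start=start, duration=window_s, samples=samples))
    return windows


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (datetime, date)):
            return o.isoformat()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_JsonEncoder)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_reports(reports: Sequence[MonthlyReport], path) -> None:
    write_json([r.to_dict() for r in reports], path)
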