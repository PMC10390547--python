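from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from funcmon.core import HouseholdLayout, SensorKind, SensorSpec

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_layout() -> HouseholdLayout:
    """Two-room flat with a PIR per room, a kitchen plug and a door contact."""
    return HouseholdLayout(
        rooms=frozenset({"kitchen", "hallway"}),
        sensors={
            "pir_kitchen": SensorSpec(SensorKind.PIR, "kitchen"),
            "pir_hallway": SensorSpec(SensorKind.PIR, "hallway"),
            "power_kettle": SensorSpec(SensorKind.POWER, "kitchen"),
            "door_front": SensorSpec(SensorKind.DOOR_CONTACT, "hallway"),
        },
        adjacency=frozenset({("kitchen", "hallway"), ("hallway", "kitchen")}),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_events(rows):
    """rows: (timestamp str/datetime, sensor_id, kind, value, room)."""
    df = pd.DataFrame(rows, columns=["timestamp", "sensor_id", "kind", "value", "room"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@pytest.fixture
def events_factory():
    return make_events
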