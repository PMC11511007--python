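import numpy as np
import pandas as pd
import pytest

from inactiscore import EventStream, SensorSpec

#: The 4-sensor worked example: certainties and a morning of events.
TABLE1_CERTAINTIES = {"Sensor-1": 0.6, "Sensor-2": 0.9, "Sensor-3": 0.3, "Sensor-4": 0.8}
TABLE1_EVENTS = [
    ("06:32:00", "Sensor-4"),
    ("06:48:00", "Sensor-1"),
    ("06:53:00", "Sensor-1"),
    ("07:13:00", "Sensor-1"),
    ("07:20:00", "Sensor-2"),
    ("08:13:00", "Sensor-3"),
    ("09:56:00", "Sensor-1"),
]


def build_stream(rows, certainties, span, day="2021-01-04"):
    registry = {sid: SensorSpec(sid, c) for sid, c in certainties.items()}
    frame = pd.DataFrame(
        {
            "timestamp": [pd.Timestamp(f"{day} {t}") for t, _ in rows],
            "sensor_id": [sid for _, sid in rows],
            "origin": "real",
        }
    )
    span = (pd.Timestamp(f"{day} {span[0]}"), pd.Timestamp(f"{day} {span[1]}"))
    return EventStream(registry, frame, span)


@pytest.fixture
def table1_stream():
    """Worked-example stream on a 06:00-10:00 span."""
    return build_stream(TABLE1_EVENTS, TABLE1_CERTAINTIES, ("06:00:00", "10:00:00"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
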