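"""Sensor registry, activity-event streams, and event-log I/O.

The detector consumes a time-ordered stream of binary activity events
(one per sensor activation) over a registry of sensors, each carrying a
certainty ``c ∈ [0, 1]`` — the probability-like weight that an event
from that sensor reflects genuine human activity.  Streams can come from
CASAS-style whitespace-separated motion-sensor logs, from the canonical
CSV written by this package, or from the synthetic generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyStreamError

log = logging.getLogger(__name__)

#: Origin tags for events.
ORIGIN_REAL = "real"
ORIGIN_NOISE = "noise"

_COLUMNS = ["timestamp", "sensor_id", "origin"]


@dataclass(frozen=True)
class SensorSpec:
    """A sensor's identity, certainty and (optional) room label.

    ``certainty`` is the weight c(s) in [0, 1]: 1 means every event from
    this sensor is trusted as genuine activity, 0 means events carry no
    information.
    """

    sensor_id: str
    certainty: float = 1.0
    room: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.certainty <= 1.0:
            raise ConfigurationError(
                f"certainty for sensor {self.sensor_id!r} must be in [0, 1], "
                f"got {self.certainty}"
            )


@dataclass(frozen=True)
class ActivityEvent:
    """A single binary activity event."""

    timestamp: pd.Timestamp
    sensor_id: str
    origin: str = ORIGIN_REAL


def _as_frame(events: pd.DataFrame | Iterable) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        frame = events.loc[:, _COLUMNS].copy()
    else:
        rows = [(e.timestamp, e.sensor_id, e.origin) for e in events]
        frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"]).dt.floor("s")
    frame["sensor_id"] = frame["sensor_id"].astype(str)
    frame["origin"] = frame["origin"].astype(str)
    return frame


@dataclass
class EventStream:
    """A time-ordered activity-event stream over a sensor registry.

    Events are kept in a pandas DataFrame with columns
    ``timestamp`` (second resolution, naive local time), ``sensor_id``
    and ``origin`` (``"real"`` or ``"noise"``).  Events are sorted by
    timestamp; ties keep input order.  ``span`` is the closed interval
    the stream covers and may extend beyond the first/last event.
    """

    registry: dict[str, SensorSpec]
    events: pd.DataFrame
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None

    def __post_init__(self) -> None:
        self.events = _as_frame(self.events)
        if not self.events["timestamp"].is_monotonic_increasing:
            self.events = self.events.sort_values(
                "timestamp", kind="stable", ignore_index=True
            )
        else:
            self.events = self.events.reset_index(drop=True)
        unknown = set(self.events["sensor_id"]) - set(self.registry)
        if unknown:
            raise ConfigurationError(
                f"events reference unregistered sensors: {sorted(unknown)}"
            )
        if self.span is None:
            if len(self.events) == 0:
                raise EmptyStreamError("cannot infer span of an empty stream")
            self.span = (
                self.events["timestamp"].iloc[0],
                self.events["timestamp"].iloc[-1],
            )
        else:
            start, end = pd.Timestamp(self.span[0]), pd.Timestamp(self.span[1])
            if end < start:
                raise ConfigurationError("span end precedes span start")
            self.span = (start, end)
            ts = self.events["timestamp"]
            if len(ts) and (ts.iloc[0] < start or ts.iloc[-1] > end):
                raise ConfigurationError("events fall outside the declared span")

    # -- basics ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        for row in self.events.itertuples(index=False):
            yield ActivityEvent(row.timestamp, row.sensor_id, row.origin)

    @property
    def start(self) -> pd.Timestamp:
        return self.span[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.span[1]

    def certainty(self, sensor_id: str) -> float:
        return self.registry[sensor_id].certainty

    def timestamps_seconds(self, origin: pd.Timestamp | None = None) -> np.ndarray:
        """Event times as integer seconds since ``origin`` (default span start)."""
        origin = self.start if origin is None else pd.Timestamp(origin)
        delta = self.events["timestamp"] - origin
        return (delta // pd.Timedelta(seconds=1)).to_numpy(dtype=np.int64)

    # -- derived streams ------------------------------------------------

    def with_certainties(self, certainties: Mapping[str, float]) -> "EventStream":
        """Return a copy whose registry carries the given certainty values."""
        missing = set(self.registry) - set(certainties)
        if missing:
            raise ConfigurationError(
                f"no certainty provided for sensors: {sorted(missing)}"
            )
        registry = {
            sid: replace(spec, certainty=float(certainties[sid]))
            for sid, spec in self.registry.items()
        }
        return EventStream(registry, self.events, self.span)

    def truncated_before(self, t: pd.Timestamp) -> "EventStream":
        """Keep only events with timestamp strictly before ``t``; span unchanged."""
        t = pd.Timestamp(t)
        keep = self.events[self.events["timestamp"] < t]
        return EventStream(dict(self.registry), keep, self.span)

    def snapped_to_days(self) -> "EventStream":
        """Widen the span to whole calendar days (midnight to midnight).

        The day-aligned grid is what the weekend-aware threshold
        machinery expects; streams read back from CSV lose their
        original span and infer it from the first/last event.
        """
        start = self.start.normalize()
        end = self.end.normalize()
        if end < self.end:
            end += pd.Timedelta(days=1)
        return EventStream(dict(self.registry), self.events, (start, end))

    def merge(self, other: "EventStream") -> "EventStream":
        """Merge two streams over a combined registry (union span)."""
        registry = dict(self.registry)
        for sid, spec in other.registry.items():
            if sid in registry and registry[sid].certainty != spec.certainty:
                raise ConfigurationError(
                    f"conflicting certainties for sensor {sid!r} while merging"
                )
            registry.setdefault(sid, spec)
        events = pd.concat([self.events, other.events], ignore_index=True)
        span = (min(self.start, other.start), max(self.end, other.end))
        return EventStream(registry, events, span)


# -- CASAS dialect ------------------------------------------------------


def read_casas(
    path,
    keep_sensors: Iterable[str],
    on_value: str = "ON",
    certainties: Mapping[str, float] | None = None,
) -> EventStream:
    """Read a CASAS-style whitespace-separated event log.

    Lines look like ``2010-11-04 08:27:59.123 M007 ON``; only events
    whose sensor id is in ``keep_sensors`` and whose value equals
    ``on_value`` are kept (motion-sensor ON events).  Malformed lines
    are skipped with a logged count.  Sensors default to certainty 1
    unless ``certainties`` provides values.
    """
    keep = set(keep_sensors)
    certainties = certainties or {}
    rows: list[tuple[str, str]] = []
    malformed = 0
    dropped_value = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4:
                if line.strip():
                    malformed += 1
                continue
            date, time, sensor, value = parts[0], parts[1], parts[2], parts[3]
            if sensor not in keep:
                continue
            if value != on_value:
                dropped_value += 1
                continue
            try:
                ts = pd.Timestamp(f"{date} {time}")
            except (ValueError, TypeError):
                malformed += 1
                continue
            rows.append((ts, sensor))
    if malformed:
        log.warning("read_casas: skipped %d malformed lines in %s", malformed, path)
    if dropped_value:
        log.info(
            "read_casas: dropped %d events with value != %r", dropped_value, on_value
        )
    if not rows:
        raise EmptyStreamError(
            f"no parseable {on_value}-events for sensors {sorted(keep)} in {path}"
        )
    frame = pd.DataFrame(rows, columns=["timestamp", "sensor_id"])
    frame["origin"] = ORIGIN_REAL
    registry = {
        sid: SensorSpec(sid, float(certainties.get(sid, 1.0))) for sid in keep
    }
    return EventStream(registry, frame)


# -- preprocessing ------------------------------------------------------


def rolling_hour_filter(
    stream: EventStream, min_gap: pd.Timedelta = pd.Timedelta(hours=1)
) -> EventStream:
    """Keep at most one activation per sensor per hour.

    For each sensor independently, an event is kept only if at least
    ``min_gap`` has elapsed since that sensor's last *kept* event (the
    window is half-open: a gap of exactly ``min_gap`` is kept).  The
    first event of each sensor is always kept; relative order is
    preserved.  This suppresses near-continuous motion-sensor triggers
    while a person stays in one room.
    """
    if len(stream) == 0:
        return stream
    min_gap = pd.Timedelta(min_gap)
    ts = stream.events["timestamp"].to_numpy()
    sensors = stream.events["sensor_id"].to_numpy()
    last_kept: dict[str, np.datetime64] = {}
    keep = np.zeros(len(ts), dtype=bool)
    gap = np.timedelta64(int(min_gap.total_seconds()), "s")
    for i in range(len(ts)):
        sid = sensors[i]
        prev = last_kept.get(sid)
        if prev is None or ts[i] - prev >= gap:
            keep[i] = True
            last_kept[sid] = ts[i]
    return EventStream(dict(stream.registry), stream.events[keep], stream.span)


def split_at_gaps(
    stream: EventStream, max_gap: pd.Timedelta = pd.Timedelta(hours=1)
) -> list[EventStream]:
    """Split a stream into contiguous segments at inter-event gaps > ``max_gap``.

    Mirrors the practice of analysing only gap-free sequences of a
    recording; each returned segment spans exactly its own events.
    """
    if len(stream) == 0:
        return []
    max_gap = pd.Timedelta(max_gap)
    ts = stream.events["timestamp"]
    breaks = ts.diff() > max_gap
    segment_ids = breaks.cumsum()
    out = []
    for _, chunk in stream.events.groupby(segment_ids):
        out.append(EventStream(dict(stream.registry), chunk))
    return out


# -- canonical CSV ------------------------------------------------------


def write_canonical_csv(stream: EventStream, path) -> None:
    """Write events as CSV with header ``timestamp,sensor_id,origin``."""
    frame = stream.events.copy()
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    frame.to_csv(path, index=False)


def read_canonical_csv(
    path,
    registry: Mapping[str, SensorSpec] | None = None,
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> EventStream:
    """Read the canonical CSV written by :func:`write_canonical_csv`.

    If no registry is given, one is built from the sensor ids present
    with certainty 1.
    """
    frame = pd.read_csv(path, dtype={"sensor_id": str, "origin": str})
    if len(frame) == 0 and span is None:
        raise EmptyStreamError(f"{path} contains no events and no span was given")
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    if registry is None:
        registry = {sid: SensorSpec(sid) for sid in frame["sensor_id"].unique()}
    return EventStream(dict(registry), frame, span)


def write_registry_csv(registry: Mapping[str, SensorSpec], path) -> None:
    rows = [
        (s.sensor_id, s.certainty, s.room if s.room is not None else "")
        for s in registry.values()
    ]
    pd.DataFrame(rows, columns=["sensor_id", "certainty", "room"]).to_csv(
        path, index=False
    )


def read_registry_csv(path) -> dict[str, SensorSpec]:
    frame = pd.read_csv(path, dtype={"sensor_id": str})
    registry = {}
    for row in frame.itertuples(index=False):
        room = None
        if "room" in frame.columns and isinstance(row.room, str) and row.room:
            room = row.room
        registry[row.sensor_id] = SensorSpec(row.sensor_id, float(row.certainty), room)
    return registry
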