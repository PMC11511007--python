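"""Inactivity Score IS(t) and Duration of Inactivity DI(t).

The classical Duration of Inactivity is the elapsed time since the last
activity event; any event resets it to zero, which makes it brittle
when sensors misfire.  The Inactivity Score replaces the hard reset
with a multiplicative update: on a uniform grid with step Δt,

    IS(t) = (IS(t−Δt) + a) · RF(t, E_t)

where ``a`` is the slope (seconds gained per step, default Δt in
seconds), ``E_t`` is the set of sensors with at least one event in the
step ``(t−Δt, t]``, and the Reduction Factor is

    RF(t, E_t) = ∏_{s ∈ E_t} (1 − c(s) · I(t, s))

with the Sensor Impact

    I(t, s) = (t − l(t, s)) / (γ (1 − c(s)))   if t − l(t, s) < γ (1 − c(s))
            = 1                                otherwise,

``l(t, s)`` being the sensor's previous activation.  A fully certain
sensor (c = 1) drives the factor to zero — a hard reset, recovering
DI(t).  An uncertain sensor only shrinks the score (factor 1 − c), and
a sensor that refires within γ(1 − c) of its previous activation gets a
linearly reduced impact, so a malfunctioning sensor firing constantly
cannot pin the score at zero.  γ is a hyperparameter, default 4 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .events import EventStream

KIND_IS = "IS"
KIND_DI = "DI"
KIND_THRESHOLD = "THRES"


def _seconds(value) -> float:
    """Coerce a duration (seconds number or Timedelta) to float seconds."""
    if isinstance(value, (pd.Timedelta, np.timedelta64)):
        return pd.Timedelta(value).total_seconds()
    return float(value)


@dataclass(frozen=True)
class ScoreConfig:
    """Grid and recursion parameters.

    Parameters
    ----------
    step:
        Grid step Δt in seconds (or a Timedelta). Default 60 s.
    slope_a:
        Seconds the score gains per step. Defaults to ``step`` in
        seconds, so the score is measured on a seconds-equivalent scale.
    gamma:
        Refire horizon γ in seconds (or a Timedelta). Default 4 h.
    """

    step: float = 60.0
    slope_a: float | None = None
    gamma: float = 4 * 3600.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "step", _seconds(self.step))
        object.__setattr__(self, "gamma", _seconds(self.gamma))
        if self.slope_a is None:
            object.__setattr__(self, "slope_a", self.step)
        else:
            object.__setattr__(self, "slope_a", float(self.slope_a))
        if self.step <= 0 or self.slope_a <= 0 or self.gamma <= 0:
            raise ConfigurationError("step, slope_a and gamma must be positive")


@dataclass
class ScoreSeries:
    """A score sampled on a uniform time grid ``start + k · step``."""

    start: pd.Timestamp
    step: float
    values: np.ndarray
    kind: str = KIND_IS

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.step = _seconds(self.step)
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self.values)) * self.step, unit="s"
        )

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=(len(self.values) - 1) * self.step)

    def index_at(self, t: pd.Timestamp, how: str = "floor") -> int:
        """Grid index of time ``t`` (``floor``, ``ceil`` or ``exact``)."""
        rel = (pd.Timestamp(t) - self.start).total_seconds() / self.step
        if how == "floor":
            k = math.floor(rel + 1e-9)
        elif how == "ceil":
            k = math.ceil(rel - 1e-9)
        else:
            k = round(rel)
            if abs(rel - k) > 1e-9:
                raise ValueError(f"{t} is not on the grid")
        if not 0 <= k < len(self.values):
            raise IndexError(f"{t} outside the score grid")
        return int(k)

    def time_at(self, k: int) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=k * self.step)

    def value_at(self, t: pd.Timestamp) -> float:
        return float(self.values[self.index_at(t, how="exact")])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.times, "value": self.values, "kind": self.kind}
        )

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        frame.to_csv(path, index=False)


# -- recursion primitives ----------------------------------------------


def sensor_impact(t, last, certainty: float, gamma: float) -> float:
    """Sensor Impact I(t, s) ∈ (0, 1].

    ``t`` is the current grid time, ``last`` the sensor's previous
    activation (or None if it never fired before).  Timestamps may be
    given as pandas Timestamps or as plain seconds.
    """
    if not 0.0 <= certainty <= 1.0:
        raise ConfigurationError(f"certainty must be in [0, 1], got {certainty}")
    if last is None:
        return 1.0
    if isinstance(t, (pd.Timestamp, np.datetime64)):
        elapsed = (pd.Timestamp(t) - pd.Timestamp(last)).total_seconds()
    else:
        elapsed = float(t) - float(last)
    if elapsed <= 0:
        raise ValueError("last activation must precede the current time")
    horizon = _seconds(gamma) * (1.0 - certainty)
    if elapsed < horizon:
        return elapsed / horizon
    return 1.0


def reduction_factor(
    events_at_step: Iterable[tuple[str, float]], impacts: Sequence[float]
) -> float:
    """Reduction Factor RF(t, E_t) = ∏ (1 − c · I) over the step's sensors.

    ``events_at_step`` holds one ``(sensor_id, certainty)`` entry per
    distinct sensor that fired in the step; ``impacts`` the matching
    Sensor Impact values.  The empty set yields 1 (no reduction).
    """
    entries = list(events_at_step)
    sids = [sid for sid, _ in entries]
    if len(set(sids)) != len(sids):
        raise ValueError("duplicate sensor in a single step's event set")
    if len(entries) != len(impacts):
        raise ValueError("impacts must match events_at_step one-to-one")
    rf = 1.0
    for (_, c), imp in zip(entries, impacts):
        rf *= 1.0 - c * imp
    return rf


# -- series computation -------------------------------------------------


def _grid_length(stream: EventStream, step: float) -> int:
    span_s = (stream.end - stream.start).total_seconds()
    n = int(math.floor(span_s / step + 1e-9)) + 1
    if n < 2:
        raise ConfigurationError("stream span must cover at least one grid step")
    return n


def _events_by_step(stream: EventStream, step: float):
    """Yield (step index k, rows) with k = ceil(rel / step): events in (t_{k−1}, t_k]."""
    rel = stream.timestamps_seconds().astype(float)
    k = np.ceil(rel / step - 1e-9).astype(int)
    k[k < 0] = 0
    return rel, k


def compute_inactivity_score(
    stream: EventStream, config: ScoreConfig | None = None, initial: float = 0.0
) -> ScoreSeries:
    """Compute IS(t) on the stream's grid.

    The recursion runs over every grid point of the span, but only
    event-bearing steps change the slope, so the series is filled
    segment-wise.  Within one step a sensor's multiple firings count
    once (E_t is a set); its stored last-activation time advances to
    the latest firing of the step, and the impact of the step's
    activation is evaluated against the previous activation strictly
    before this step.  Noise-origin events participate exactly like
    real ones: the detector cannot tell them apart.
    """
    config = config or ScoreConfig()
    step, a, gamma = config.step, config.slope_a, config.gamma
    n = _grid_length(stream, step)
    values = np.empty(n, dtype=float)
    values[0] = float(initial)

    rel, kidx = _events_by_step(stream, step)
    sensors = stream.events["sensor_id"].to_numpy()
    certs = {sid: spec.certainty for sid, spec in stream.registry.items()}

    last_act: dict[str, float] = {}  # sensor -> last activation time (rel seconds)
    cur = float(initial)
    prev_k = 0
    i = 0
    n_events = len(rel)
    while i < n_events:
        k = kidx[i]
        # gather this step's firings per sensor
        first_fire: dict[str, float] = {}
        latest_fire: dict[str, float] = {}
        while i < n_events and kidx[i] == k:
            sid = sensors[i]
            t_e = rel[i]
            first_fire.setdefault(sid, t_e)
            latest_fire[sid] = t_e
            i += 1
        if k == 0 or k >= n:
            # events at the very start only update activation memory;
            # events past the last grid point cannot happen (span check)
            for sid, t_e in latest_fire.items():
                last_act[sid] = t_e
            continue
        # linear growth over event-free steps (prev_k, k)
        if k - prev_k > 1:
            values[prev_k + 1 : k] = cur + a * np.arange(1, k - prev_k)
        t_grid = k * step
        rf = 1.0
        for sid in first_fire:
            c = certs[sid]
            prev = last_act.get(sid)
            imp = sensor_impact(t_grid, prev, c, gamma) if prev is not None else 1.0
            rf *= 1.0 - c * imp
        cur = (cur + a * (k - prev_k)) * rf
        values[k] = cur
        prev_k = k
        for sid, t_e in latest_fire.items():
            last_act[sid] = t_e
    if prev_k < n - 1:
        values[prev_k + 1 :] = cur + a * np.arange(1, n - prev_k)
    # guard against negative zeros / tiny negatives from float products
    np.maximum(values, 0.0, out=values)
    return ScoreSeries(stream.start, step, values, KIND_IS)


def compute_duration_of_inactivity(
    stream: EventStream, config: ScoreConfig | None = None
) -> ScoreSeries:
    """Compute the classical DI(t) = t − (latest event time ≤ t), in seconds.

    Before the first event DI grows from 0 at the span start.  Sensor
    certainties are ignored: any event resets the duration.
    """
    config = config or ScoreConfig()
    step = config.step
    n = _grid_length(stream, step)
    grid = np.arange(n, dtype=float) * step

    rel = stream.timestamps_seconds().astype(float)
    values = grid.copy()  # no-event default: elapsed since span start
    if len(rel):
        # for each grid time, index of the latest event with time <= grid time
        idx = np.searchsorted(rel, grid + 1e-9) - 1
        has_prev = idx >= 0
        values[has_prev] = grid[has_prev] - rel[idx[has_prev]]
    np.maximum(values, 0.0, out=values)
    return ScoreSeries(stream.start, step, values, KIND_DI)
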