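"""Synthetic household streams, sensor certainties, and noise sets.

The generator emulates the structure the detector relies on in real
recordings: a circadian (24 h periodic) household activity pattern with
a weekday/weekend distinction, per-sensor activation-frequency
profiles, per-sensor certainty values drawn from truncated normal
distributions (one regime per noise level), and a set of spurious
"noise" events sized (1 − c)·|events| per sensor whose time-of-day
distribution follows the sensor's real activation histogram plus a
small time-independent component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyStreamError
from .events import ORIGIN_NOISE, ORIGIN_REAL, EventStream, SensorSpec

_DAY = 86400


@dataclass(frozen=True)
class NoiseLevelSpec:
    """A certainty-sampling regime: c ~ N(mu, sigma) truncated to [lower, upper]."""

    label: str
    mu: float
    sigma: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ConfigurationError("noise-level bounds must satisfy 0<=lower<=upper<=1")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be non-negative")
        if self.sigma == 0 and not self.lower <= self.mu <= self.upper:
            raise ConfigurationError(
                f"level {self.label}: sigma=0 with mu={self.mu} outside bounds"
            )


#: The four standard noise regimes, from fully certain sensors (N) to
#: heavily degraded ones (H).
NOISE_LEVELS: dict[str, NoiseLevelSpec] = {
    "N": NoiseLevelSpec("N", 1.00, 0.00, 1.0, 1.0),
    "L": NoiseLevelSpec("L", 0.95, 0.02, 0.9, 1.0),
    "M": NoiseLevelSpec("M", 0.90, 0.10, 0.8, 1.0),
    "H": NoiseLevelSpec("H", 0.85, 0.20, 0.6, 1.0),
}

#: Default household-level activity intensity (expected events per hour
#: by hour of day) after one-per-sensor-per-hour filtering: near-silent
#: nights, a morning rise, sustained daytime activity, an evening peak.
DEFAULT_PROFILE = (
    0.05, 0.02, 0.02, 0.02, 0.05, 0.2,
    0.8, 1.5, 1.8, 1.5, 1.2, 1.2,
    1.5, 1.2, 1.0, 1.0, 1.2, 1.5,
    1.8, 1.8, 1.5, 1.0, 0.5, 0.1,
)


@dataclass(frozen=True)
class HouseholdConfig:
    """Parameters of one simulated single-occupant household.

    ``activity_rate_profile`` gives the expected household-level event
    count per hour of day; ``weekend_scale`` multiplies it on Saturdays
    and Sundays (people tend to be home more).  Events are distributed
    over sensors by ``sensor_weights`` (uniform when omitted).  The
    stream starts at midnight of ``start`` and covers ``days`` days.
    """

    n_sensors: int = 5
    days: int = 120
    activity_rate_profile: tuple = DEFAULT_PROFILE
    sensor_weights: tuple | None = None
    weekend_scale: float = 1.2
    start: str = "2021-01-04"  # a Monday
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensors < 1 or self.days < 1:
            raise ConfigurationError("n_sensors and days must be >= 1")
        if len(self.activity_rate_profile) != 24:
            raise ConfigurationError("activity_rate_profile needs 24 hourly rates")
        if any(r < 0 for r in self.activity_rate_profile):
            raise ConfigurationError("hourly rates must be non-negative")
        if self.weekend_scale <= 0:
            raise ConfigurationError("weekend_scale must be positive")
        if self.sensor_weights is not None:
            w = np.asarray(self.sensor_weights, dtype=float)
            if len(w) != self.n_sensors or w.min() < 0 or not np.isclose(w.sum(), 1.0):
                raise ConfigurationError(
                    "sensor_weights must be n_sensors non-negative values summing to 1"
                )


def sample_certainties(n: int, level: NoiseLevelSpec | str, seed) -> np.ndarray:
    """Draw ``n`` certainty values for a noise level by rejection sampling.

    Values are drawn from N(mu, sigma) and accepted only inside
    [lower, upper].  The no-noise level (sigma = 0) returns ``mu``
    without sampling.
    """
    if isinstance(level, str):
        level = NOISE_LEVELS[level]
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if level.sigma == 0:
        return np.full(n, level.mu)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(level.mu, level.sigma, size=max(n - filled, 16))
        keep = draw[(draw >= level.lower) & (draw <= level.upper)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_household_stream(config: HouseholdConfig | None = None) -> EventStream:
    """Simulate a household's activity as an inhomogeneous Poisson stream.

    Each hour of each day contributes Poisson(rate) events at uniform
    times within the hour (floored to whole seconds); each event is
    assigned a sensor by the multinomial ``sensor_weights``.  Sensors
    start with certainty 1; assign sampled certainties afterwards with
    :meth:`EventStream.with_certainties`.
    """
    config = config or HouseholdConfig()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start).normalize()
    sensors = [f"S{i+1:02d}" for i in range(config.n_sensors)]
    weights = (
        np.full(config.n_sensors, 1.0 / config.n_sensors)
        if config.sensor_weights is None
        else np.asarray(config.sensor_weights, dtype=float)
    )
    profile = np.asarray(config.activity_rate_profile, dtype=float)

    times: list[int] = []
    for day in range(config.days):
        scale = (
            config.weekend_scale
            if (start + pd.Timedelta(days=day)).weekday() >= 5
            else 1.0
        )
        counts = rng.poisson(profile * scale)
        for hour, cnt in enumerate(counts):
            if cnt:
                base = day * _DAY + hour * 3600
                times.extend(base + np.floor(rng.uniform(0, 3600, cnt)).astype(int))
    times = np.sort(np.asarray(times, dtype=np.int64))
    sensor_ids = rng.choice(sensors, size=len(times), p=weights)
    span = (start, start + pd.Timedelta(days=config.days))
    frame = pd.DataFrame(
        {
            "timestamp": start + pd.to_timedelta(times, unit="s"),
            "sensor_id": sensor_ids,
            "origin": ORIGIN_REAL,
        }
    )
    registry = {sid: SensorSpec(sid) for sid in sensors}
    if len(frame) == 0:
        import logging

        logging.getLogger(__name__).warning(
            "generate_household_stream: all-zero profile produced an empty stream"
        )
    return EventStream(registry, frame, span)


def generate_noise_events(
    stream: EventStream,
    certainties: dict[str, float] | None = None,
    global_fraction: float = 0.1,
    seed: int = 0,
) -> EventStream:
    """Build the spurious-event set matching a (certainty-annotated) stream.

    For each sensor s with n_s real events and certainty c, exactly
    round((1 − c) · n_s) noise events are created (round half-to-even).
    A (1 − global_fraction) share of their times-of-day follows the
    sensor's empirical hourly activation histogram; the rest is uniform
    over 24 h; days are uniform over the span.  Events are tagged
    ``origin="noise"`` so evaluation code can keep them flowing after a
    simulated emergency — the detector itself never looks at the tag.
    """
    if not 0.0 <= global_fraction <= 1.0:
        raise ConfigurationError("global_fraction must be in [0, 1]")
    if certainties is None:
        certainties = {sid: s.certainty for sid, s in stream.registry.items()}
    missing = {sid for sid in stream.events["sensor_id"].unique()} - set(certainties)
    if missing:
        raise ConfigurationError(f"sensors missing a certainty: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    start = stream.start.normalize()
    n_days = int(np.ceil((stream.end - start) / pd.Timedelta(days=1)))
    span_start_s = int((stream.start - start).total_seconds())
    span_end_s = int((stream.end - start).total_seconds())

    hours = stream.events["timestamp"].dt.hour.to_numpy()
    sensor_col = stream.events["sensor_id"].to_numpy()

    rows_ts: list[int] = []
    rows_sid: list[str] = []
    for sid in sorted(stream.registry):
        mask = sensor_col == sid
        n_s = int(mask.sum())
        c = float(certainties[sid])
        n_noise = int(np.round((1.0 - c) * n_s))
        if n_noise == 0:
            continue
        hist = np.bincount(hours[mask], minlength=24).astype(float)
        hist /= hist.sum()
        from_hist = rng.random(n_noise) >= global_fraction
        hour_draw = np.where(
            from_hist,
            rng.choice(24, size=n_noise, p=hist),
            rng.integers(0, 24, size=n_noise),
        )
        day_draw = rng.integers(0, n_days, size=n_noise)
        sec_draw = rng.integers(0, 3600, size=n_noise)
        ts = day_draw * _DAY + hour_draw * 3600 + sec_draw
        ts = np.clip(ts, span_start_s, span_end_s)  # keep partial boundary days in span
        rows_ts.extend(ts.tolist())
        rows_sid.extend([sid] * n_noise)

    frame = pd.DataFrame(
        {
            "timestamp": start + pd.to_timedelta(rows_ts, unit="s"),
            "sensor_id": rows_sid,
            "origin": ORIGIN_NOISE,
        }
    )
    return EventStream(dict(stream.registry), frame, stream.span)


def make_dataset(
    config: HouseholdConfig | None = None,
    level: NoiseLevelSpec | str = "N",
    global_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[EventStream, EventStream, EventStream]:
    """Generate (real stream with certainties, noise stream, merged stream)."""
    config = config or HouseholdConfig(seed=seed)
    rng = np.random.default_rng(seed)
    real = generate_household_stream(config)
    certs = sample_certainties(config.n_sensors, level, rng)
    real = real.with_certainties(dict(zip(sorted(real.registry), certs)))
    noise = generate_noise_events(
        real, global_fraction=global_fraction, seed=int(rng.integers(0, 2**31 - 1))
    )
    merged = real.merge(noise)
    return real, noise, merged
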