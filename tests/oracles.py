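"""Independent reference computations used to check the implementation.

Everything here recomputes quantities from first principles (greedy
scans, nested loops, non-recursive unrolled sums) without going through
the recursion or the vectorized code paths under test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from inactiscore import EventStream, ScoreConfig, SensorSpec


def greedy_hour_filter(times: list, min_gap_s: float = 3600.0) -> list:
    """Greedy left-to-right scan keeping events spaced >= min_gap (one sensor)."""
    kept = []
    for t in times:
        if not kept or (t - kept[-1]) >= min_gap_s:
            kept.append(t)
    return kept


def di_pointer_walk(event_rel: np.ndarray, n: int, step: float) -> np.ndarray:
    """DI on the grid via an explicit last-event pointer walk."""
    out = np.empty(n)
    ptr = -1
    for k in range(n):
        t = k * step
        while ptr + 1 < len(event_rel) and event_rel[ptr + 1] <= t + 1e-9:
            ptr += 1
        out[k] = t - event_rel[ptr] if ptr >= 0 else t
    return out


def window_max_nested(values: np.ndarray, centers, half_width: int, limit=None):
    """Nested-loop window maxima over [c - hw, c + hw] grid indices."""
    n = len(values) if limit is None else min(len(values), limit)
    out = []
    for c in centers:
        lo, hi = max(c - half_width, 0), min(c + half_width + 1, n)
        if lo < hi:
            out.append(max(values[lo:hi]))
    return np.asarray(out)


def step_reduction_factors(stream: EventStream, config: ScoreConfig) -> dict[int, float]:
    """Reduction factor per event-bearing grid step, from raw events.

    Steps are (t_{k-1}, t_k]; a sensor's impact at step k is evaluated
    against its latest activation strictly before its first firing in
    the step, with t the grid time and the factor 1 - c*I.
    """
    step, gamma = config.step, config.gamma
    rel = stream.timestamps_seconds().astype(float)
    sensors = stream.events["sensor_id"].to_numpy()
    by_sensor: dict[str, list[float]] = {}
    for t, s in zip(rel, sensors):
        by_sensor.setdefault(s, []).append(t)
    ks = np.ceil(rel / step - 1e-9).astype(int)
    rfs: dict[int, float] = {}
    for k in sorted(set(ks)):
        if k <= 0:
            continue
        t_grid = k * step
        rf = 1.0
        in_step = set(sensors[ks == k])
        for sid in in_step:
            c = stream.registry[sid].certainty
            firings = [t for t in by_sensor[sid] if math.ceil(t / step - 1e-9) == k]
            first = min(firings)
            prevs = [t for t in by_sensor[sid] if t < first]
            if not prevs:
                impact = 1.0
            else:
                horizon = gamma * (1.0 - c)
                elapsed = t_grid - max(prevs)
                impact = elapsed / horizon if elapsed < horizon else 1.0
            rf *= 1.0 - c * impact
        rfs[k] = rf
    return rfs


def unrolled_is_at(
    k: int, rfs: dict[int, float], a: float, initial: float = 0.0
) -> float:
    """IS(t_k) by non-recursive unrolling of the product form.

    IS(k) = initial * prod_{j<=k} RF_j + a * sum_{i=1..k} prod_{j=i..k} RF_j,
    with RF_j = 1 on event-free steps, so the sum groups into runs
    between event steps.
    """
    relevant = sorted((j, rf) for j, rf in rfs.items() if 1 <= j <= k)
    total = 0.0
    prod = 1.0
    prev = k
    for j, rf in reversed(relevant):
        total += a * prod * (prev - j)  # i in (j, prev]
        prod *= rf
        total += a * prod  # i == j (the +a at step j is also multiplied by RF_j)
        prev = j - 1
    total += a * prod * prev  # i in [1, prev]
    return total + initial * prod


def random_stream(
    rng: np.random.Generator,
    n_events: int,
    span_seconds: int,
    n_sensors: int = 3,
    certainties=None,
    start: str = "2021-03-01",
) -> EventStream:
    """A random event stream with integer-second timestamps inside the span."""
    start = pd.Timestamp(start)
    offs = np.sort(rng.integers(1, span_seconds, size=n_events))
    sids = [f"S{i}" for i in range(n_sensors)]
    if certainties is None:
        certainties = rng.uniform(0.0, 1.0, size=n_sensors)
    registry = {s: SensorSpec(s, float(c)) for s, c in zip(sids, certainties)}
    frame = pd.DataFrame(
        {
            "timestamp": start + pd.to_timedelta(offs, unit="s"),
            "sensor_id": rng.choice(sids, size=n_events),
            "origin": "real",
        }
    )
    return EventStream(registry, frame, (start, start + pd.Timedelta(seconds=span_seconds)))
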