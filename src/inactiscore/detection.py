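"""Adaptive thresholds over historical scores, and alarm onset detection.

For a query time t the threshold is built from the score's own history:
reference times are the same clock time on each of the past ψ days
(default 70) that matches t's weekend/weekday status; around each
reference the maximum score in a ±β window (default 1 h) is taken;
the overall maximum of those windowed maxima is clipped to the Tukey
upper fence Θ = Q3 + 1.5·IQR of the maxima and scaled by α (default 2):

    thres(t) = min( max(ISmax(t)), Θ(t) ) · α

An alarm onset is a grid point where the score first crosses above the
threshold (IS(t) > thres(t) and IS(t−1) ≤ thres(t−1)).  Thresholds are
undefined — and no alarm is possible — during an initialization period
(default 10 weeks) and whenever fewer than ``min_references`` usable
reference days exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .errors import ConfigurationError, NoReferenceError
from .score import KIND_THRESHOLD, ScoreSeries, _seconds

_DAY = 86400.0


@dataclass(frozen=True)
class DetectorConfig:
    """Threshold/alarm parameters.

    psi_days: reference look-back ψ in days (default 70).
    beta: half-width β of the window around each reference, seconds
        (default 1 h).
    alpha: threshold scaling factor α ≥ 1 (default 2.0).
    init_period: warm-up during which thresholds stay undefined,
        seconds (default 10 weeks).
    min_references: minimum usable reference days for a defined
        threshold (default 5; quartiles on fewer points are
        meaningless).
    percentile_method: interpolation convention passed to
        numpy.percentile (default "linear").
    """

    psi_days: int = 70
    beta: float = 3600.0
    alpha: float = 2.0
    init_period: float = 70 * _DAY
    min_references: int = 5
    percentile_method: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", _seconds(self.beta))
        object.__setattr__(self, "init_period", _seconds(self.init_period))
        if self.psi_days <= 1:
            raise ConfigurationError("psi_days must exceed 1 day")
        if self.beta <= 0 or self.alpha <= 0:
            raise ConfigurationError("beta and alpha must be positive")
        if self.min_references < 1:
            raise ConfigurationError("min_references must be >= 1")
        if self.beta >= _DAY:
            raise ConfigurationError("beta must be below one day")


@dataclass(frozen=True)
class AlarmOnset:
    """First grid point of an excursion of the score above the threshold."""

    timestamp: pd.Timestamp
    score: float
    threshold: float


def _is_weekend(t: pd.Timestamp) -> bool:
    return t.weekday() >= 5


# -- scalar path (one query time) ---------------------------------------


def reference_times(t: pd.Timestamp, psi_days: int) -> list[pd.Timestamp]:
    """Same-clock-time candidates on the past ψ days with matching weekend status.

    One candidate per calendar day d ∈ [t − ψ days, t − 1 day], kept iff
    is_weekend(d) equals is_weekend(t) (weekend = Saturday or Sunday).
    """
    t = pd.Timestamp(t)
    wk = _is_weekend(t)
    out = []
    for d in range(1, psi_days + 1):
        cand = t - pd.Timedelta(days=d)
        if _is_weekend(cand) == wk:
            out.append(cand)
    return out


def window_maxima(
    history: ScoreSeries,
    refs: Sequence[pd.Timestamp],
    beta: float,
    before: pd.Timestamp | None = None,
) -> np.ndarray:
    """Maximum score in the closed grid window [tref − β, tref + β] per reference.

    Windows are clipped at the series boundaries, and — when ``before``
    is given — to grid times strictly before it, so a threshold never
    peeks at scores from its own query time onward.  References whose
    clipped window is empty are dropped.
    """
    if len(refs) == 0:
        raise NoReferenceError("no reference times supplied")
    beta = _seconds(beta)
    step = history.step
    n = len(history)
    hw = int(round(beta / step))
    limit = n
    if before is not None:
        rel = (pd.Timestamp(before) - history.start).total_seconds() / step
        limit = min(n, int(math.ceil(rel - 1e-9)))
    out = []
    for tref in refs:
        center = (pd.Timestamp(tref) - history.start).total_seconds() / step
        lo = int(math.ceil(center - hw - 1e-9))
        hi = int(math.floor(center + hw + 1e-9)) + 1
        lo, hi = max(lo, 0), min(hi, limit)
        if lo < hi:
            out.append(float(np.max(history.values[lo:hi])))
    return np.asarray(out, dtype=float)


def iqr_upper_bound(values, method: str = "linear") -> float:
    """Tukey upper fence Θ = Q3 + 1.5·(Q3 − Q1) of the given maxima."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise NoReferenceError("cannot compute an IQR bound of an empty set")
    q1, q3 = np.percentile(values, [25.0, 75.0], method=method)
    return float(q3 + 1.5 * (q3 - q1))


def compute_threshold(
    history: ScoreSeries, t: pd.Timestamp, config: DetectorConfig | None = None
) -> float:
    """thres(t) = min(max(ISmax), Θ) · α, or NaN when undefined.

    Undefined inside the initialization period and when fewer than
    ``min_references`` reference windows are available.
    """
    config = config or DetectorConfig()
    t = pd.Timestamp(t)
    if (t - history.start).total_seconds() < config.init_period:
        return float("nan")
    refs = reference_times(t, config.psi_days)
    refs = [r for r in refs if r >= history.start]
    if len(refs) < config.min_references:
        return float("nan")
    maxima = window_maxima(history, refs, config.beta, before=t)
    if len(maxima) < config.min_references:
        return float("nan")
    theta = iqr_upper_bound(maxima, config.percentile_method)
    return float(min(float(np.max(maxima)), theta) * config.alpha)


# -- vectorized path (whole series) -------------------------------------


def _day_grid(history: ScoreSeries):
    """Pad the series to whole days from midnight; needs step | 1 day."""
    step = history.step
    if _DAY % step != 0:
        raise ConfigurationError("threshold series needs a step that divides 1 day")
    off = (history.start - history.start.normalize()).total_seconds()
    if off % step != 0:
        raise ConfigurationError("grid must be aligned to the step within the day")
    spd = int(_DAY // step)
    lead = int(off // step)
    return spd, lead


def compute_threshold_series(
    history: ScoreSeries,
    config: DetectorConfig | None = None,
    first: pd.Timestamp | None = None,
    last: pd.Timestamp | None = None,
) -> ScoreSeries:
    """Threshold at every grid point of ``history`` (NaN where undefined).

    Equivalent to calling :func:`compute_threshold` per grid point but
    organised as a (day × time-of-day) matrix of windowed maxima so the
    per-day quartiles vectorize.  ``first``/``last`` restrict the range
    actually computed; everything else is NaN.
    """
    config = config or DetectorConfig()
    step = history.step
    n = len(history)
    spd, lead = _day_grid(history)
    hw = int(round(config.beta / step))
    wmax = maximum_filter1d(
        history.values, size=2 * hw + 1, mode="constant", cval=-np.inf
    )

    n_days = int(math.ceil((lead + n) / spd))
    padded = np.full(n_days * spd, np.nan)
    padded[lead : lead + n] = wmax
    D = padded.reshape(n_days, spd)
    day0 = history.start.normalize()
    weekend = np.array(
        [(day0 + pd.Timedelta(days=d)).weekday() >= 5 for d in range(n_days)]
    )

    out = np.full(n, np.nan)
    i0 = 0 if first is None else history.index_at(pd.Timestamp(first), how="floor")
    i1 = n - 1 if last is None else history.index_at(pd.Timestamp(last), how="ceil")
    init_end = config.init_period / step  # indices < this are undefined
    i0 = max(i0, int(math.ceil(init_end - 1e-9)))

    for d in range((lead + i0) // spd, (lead + i1) // spd + 1):
        lo_q = max(i0, d * spd - lead)
        hi_q = min(i1 + 1, (d + 1) * spd - lead)
        if lo_q >= hi_q:
            continue
        rows = np.arange(max(d - config.psi_days, 0), d)
        rows = rows[weekend[rows] == weekend[d]]
        if len(rows) < config.min_references:
            continue
        cols = np.arange(lo_q + lead - d * spd, hi_q + lead - d * spd)
        R = D[np.ix_(rows, cols)]
        valid = ~np.isnan(R)
        counts = valid.sum(axis=0)
        ok = counts >= config.min_references
        if not ok.any():
            continue
        if valid.all():
            q1, q3 = np.percentile(
                R, [25.0, 75.0], axis=0, method=config.percentile_method
            )
            mx = R.max(axis=0)
        else:
            q1, q3 = np.nanpercentile(
                R, [25.0, 75.0], axis=0, method=config.percentile_method
            )
            mx = np.nanmax(np.where(np.isnan(R), -np.inf, R), axis=0)
        theta = q3 + 1.5 * (q3 - q1)
        thres = np.minimum(mx, theta) * config.alpha
        seg = out[lo_q:hi_q]
        seg[ok] = thres[ok]
    return ScoreSeries(history.start, step, out, KIND_THRESHOLD)


class ThresholdModel:
    """Convenience wrapper binding a score history to a detector config."""

    def __init__(self, history: ScoreSeries, config: DetectorConfig | None = None):
        self.history = history
        self.config = config or DetectorConfig()

    def at(self, t: pd.Timestamp) -> float:
        return compute_threshold(self.history, t, self.config)

    def series(self, first=None, last=None) -> ScoreSeries:
        return compute_threshold_series(self.history, self.config, first, last)


# -- alarms -------------------------------------------------------------


def detect_alarm_onsets(
    scores: ScoreSeries,
    config: DetectorConfig | None = None,
    thresholds: ScoreSeries | None = None,
) -> list[AlarmOnset]:
    """All onsets where the score crosses above its (history-derived) threshold.

    A grid point alarms iff its threshold is defined and exceeded while
    the previous point was not above its own threshold (an undefined
    previous threshold counts as "not in alarm").  Consecutive points
    above threshold therefore contribute a single onset.
    """
    config = config or DetectorConfig()
    if thresholds is None:
        thresholds = compute_threshold_series(scores, config)
    thr = thresholds.values
    above = np.zeros(len(scores), dtype=bool)
    defined = ~np.isnan(thr)
    above[defined] = scores.values[defined] > thr[defined]
    prev_above = np.concatenate(([False], above[:-1]))
    onset_idx = np.nonzero(above & ~prev_above)[0]
    return [
        AlarmOnset(scores.time_at(int(k)), float(scores.values[k]), float(thr[k]))
        for k in onset_idx
    ]
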