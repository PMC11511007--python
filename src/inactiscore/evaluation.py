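"""Evaluation protocols: false-positive counting and detection latency.

Two complementary studies mirror how inactivity detectors are judged:

* **False positives** — run the detector over a stream that contains no
  genuine emergency; every alarm onset after the initialization period
  is a false positive.  Reported absolutely and per post-init day.
* **Detection time** — simulate an emergency at time ``te`` by cutting
  all real activity from ``te`` onward while spurious (noise) events
  keep flowing; the detection time is the first grid point at or after
  ``te`` where the score exceeds its threshold, capped at 7 days.  A
  trial whose score is already above threshold at ``te`` is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import AlarmOnset, DetectorConfig, compute_threshold_series, detect_alarm_onsets
from .errors import ConfigurationError, InsufficientDataError
from .events import EventStream
from .score import ScoreConfig, ScoreSeries, compute_inactivity_score

_DAY = 86400.0

STATUS_DETECTED = "detected"
STATUS_CENSORED = "censored_7d"
STATUS_EXCLUDED = "excluded_in_alarm"

#: Detection-time cap: emergencies not detected within 7 days are censored.
DETECTION_CAP = 7 * _DAY


@dataclass(frozen=True)
class EmergencyTrial:
    """One simulated emergency and its outcome."""

    te: pd.Timestamp
    tdetect: pd.Timestamp | None
    delta: float | None  # seconds from te to detection
    status: str

    def __post_init__(self) -> None:
        if self.status == STATUS_DETECTED:
            assert self.delta is not None and self.delta <= DETECTION_CAP
            assert self.tdetect is not None and self.tdetect >= self.te


@dataclass
class EvalReport:
    """Aggregated evaluation results."""

    fp_onsets: list[AlarmOnset] = field(default_factory=list)
    fp_per_day: float | None = None
    evaluated_days: float | None = None
    trials: list[EmergencyTrial] = field(default_factory=list)
    mean_delta: float | None = None
    median_delta: float | None = None
    n_detected: int = 0
    n_censored: int = 0
    n_excluded: int = 0

    @property
    def fp_count(self) -> int:
        return len(self.fp_onsets)

    def summary(self) -> dict:
        return {
            "fp_count": self.fp_count,
            "fp_per_day": self.fp_per_day,
            "evaluated_days": self.evaluated_days,
            "n_trials": len(self.trials),
            "n_detected": self.n_detected,
            "n_censored": self.n_censored,
            "n_excluded": self.n_excluded,
            "mean_delta_seconds": self.mean_delta,
            "median_delta_seconds": self.median_delta,
        }

    def trials_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "te": tr.te,
                    "tdetect": tr.tdetect,
                    "delta_seconds": tr.delta,
                    "status": tr.status,
                }
                for tr in self.trials
            ]
        )


def _aggregate_trials(report: EvalReport) -> None:
    deltas = [t.delta for t in report.trials if t.status == STATUS_DETECTED]
    report.n_detected = len(deltas)
    report.n_censored = sum(t.status == STATUS_CENSORED for t in report.trials)
    report.n_excluded = sum(t.status == STATUS_EXCLUDED for t in report.trials)
    if deltas:
        report.mean_delta = float(np.mean(deltas))
        report.median_delta = float(np.median(deltas))


# -- false positives ----------------------------------------------------


def count_false_positives(
    stream: EventStream,
    score_config: ScoreConfig | None = None,
    detector_config: DetectorConfig | None = None,
    scores: ScoreSeries | None = None,
) -> EvalReport:
    """Run scoring + detection over the stream and count post-init onsets.

    The input stream contains no genuine emergencies, so every alarm
    onset after the initialization period is a false positive.  The
    rate divides by the post-init span in days.
    """
    score_config = score_config or ScoreConfig()
    detector_config = detector_config or DetectorConfig()
    span_s = (stream.end - stream.start).total_seconds()
    post_init = span_s - detector_config.init_period
    if post_init <= 0:
        raise InsufficientDataError(
            "stream span does not extend beyond the initialization period"
        )
    if scores is None:
        scores = compute_inactivity_score(stream, score_config)
    onsets = detect_alarm_onsets(scores, detector_config)
    report = EvalReport(fp_onsets=onsets)
    report.evaluated_days = post_init / _DAY
    report.fp_per_day = len(onsets) / report.evaluated_days
    return report


# -- simulated emergencies ----------------------------------------------


def simulate_emergency(
    real_stream: EventStream,
    noise_stream: EventStream | None,
    te: pd.Timestamp,
    score_config: ScoreConfig | None = None,
    detector_config: DetectorConfig | None = None,
) -> EmergencyTrial:
    """Simulate one emergency at ``te`` and measure the detection time.

    The detector's input is the real events strictly before ``te``
    merged with the *entire* noise stream (spurious events do not stop
    when the resident does).  Detection is the first grid point
    t ≥ te with IS(t) > thres(t); thresholds come from the same
    (truncated + noise) history.  If the score already exceeds the
    threshold at the grid point at/just before ``te``, the trial is
    excluded; if no detection occurs within 7 days it is censored.
    """
    score_config = score_config or ScoreConfig()
    detector_config = detector_config or DetectorConfig()
    te = pd.Timestamp(te)
    if not (real_stream.start <= te <= real_stream.end):
        raise ConfigurationError("emergency time te lies outside the stream span")

    trial_stream = real_stream.truncated_before(te)
    if noise_stream is not None and len(noise_stream):
        trial_stream = trial_stream.merge(noise_stream)
    scores = compute_inactivity_score(trial_stream, score_config)

    k_at = scores.index_at(te, how="floor")
    k0 = scores.index_at(te, how="ceil")
    cap_idx = min(len(scores) - 1, k0 + int(round(DETECTION_CAP / scores.step)))
    thr = compute_threshold_series(
        scores,
        detector_config,
        first=scores.time_at(k_at),
        last=scores.time_at(cap_idx),
    )

    t_at = thr.values[k_at]
    if not np.isnan(t_at) and scores.values[k_at] > t_at:
        return EmergencyTrial(te, None, None, STATUS_EXCLUDED)

    seg_thr = thr.values[k0 : cap_idx + 1]
    seg_is = scores.values[k0 : cap_idx + 1]
    hit = np.nonzero(~np.isnan(seg_thr) & (seg_is > seg_thr))[0]
    if len(hit) == 0:
        return EmergencyTrial(te, None, None, STATUS_CENSORED)
    k = k0 + int(hit[0])
    tdetect = scores.time_at(k)
    delta = (tdetect - te).total_seconds()
    if delta > DETECTION_CAP:
        return EmergencyTrial(te, None, None, STATUS_CENSORED)
    return EmergencyTrial(te, tdetect, delta, STATUS_DETECTED)


def draw_emergency_times(
    stream: EventStream,
    n_trials: int,
    seed: int,
    init_period: float,
) -> list[pd.Timestamp]:
    """Draw ``n_trials`` emergency onsets uniformly over the post-init span."""
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    lo = init_period
    hi = (stream.end - stream.start).total_seconds()
    if hi <= lo:
        raise InsufficientDataError("no post-initialization span to draw from")
    offsets = np.sort(rng.uniform(lo, hi, size=n_trials))
    return [stream.start + pd.Timedelta(seconds=float(round(o))) for o in offsets]


def run_detection_time_study(
    real_stream: EventStream,
    noise_stream: EventStream | None,
    n_trials: int,
    seed: int,
    score_config: ScoreConfig | None = None,
    detector_config: DetectorConfig | None = None,
    te_times: Sequence[pd.Timestamp] | None = None,
) -> EvalReport:
    """Simulate ``n_trials`` emergencies (independent trials) and aggregate.

    Emergency times are drawn uniformly over the post-init span unless
    an explicit ``te_times`` list is supplied (useful for paired
    comparisons across noise levels).
    """
    detector_config = detector_config or DetectorConfig()
    if te_times is None:
        te_times = draw_emergency_times(
            real_stream, n_trials, seed, detector_config.init_period
        )
    elif n_trials != len(te_times):
        raise ConfigurationError("n_trials must match len(te_times)")
    report = EvalReport()
    for te in te_times:
        report.trials.append(
            simulate_emergency(
                real_stream, noise_stream, te, score_config, detector_config
            )
        )
    _aggregate_trials(report)
    return report


def run_noise_level_study(
    base_stream: EventStream,
    levels: Sequence[str],
    n_trials: int,
    seed: int,
    score_config: ScoreConfig | None = None,
    detector_config: DetectorConfig | None = None,
    global_fraction: float = 0.1,
) -> dict[str, EvalReport]:
    """Full protocol across noise levels on one household stream.

    For each level: sample per-sensor certainties, build the matching
    noise set, count false positives on the merged stream, and run the
    detection-time study.  The emergency times are shared across levels
    (paired design) for variance reduction.
    """
    from .synthetic import NOISE_LEVELS, generate_noise_events, sample_certainties

    detector_config = detector_config or DetectorConfig()
    te_times = draw_emergency_times(
        base_stream, n_trials, seed, detector_config.init_period
    )
    rng = np.random.default_rng(seed + 1)
    sensors = sorted(base_stream.registry)
    out: dict[str, EvalReport] = {}
    for level in levels:
        spec = NOISE_LEVELS[level] if isinstance(level, str) else level
        certs = dict(
            zip(sensors, sample_certainties(len(sensors), spec, rng))
        )
        real = base_stream.with_certainties(certs)
        noise = generate_noise_events(
            real, global_fraction=global_fraction,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        merged = real.merge(noise)
        report = count_false_positives(merged, score_config, detector_config)
        det = run_detection_time_study(
            real, noise, n_trials, seed, score_config, detector_config,
            te_times=te_times,
        )
        report.trials = det.trials
        report.mean_delta = det.mean_delta
        report.median_delta = det.median_delta
        report.n_detected = det.n_detected
        report.n_censored = det.n_censored
        report.n_excluded = det.n_excluded
        out[spec.label] = report
    return out
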