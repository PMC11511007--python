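import math

import numpy as np
import pandas as pd
import pytest

from inactiscore import (
    DetectorConfig,
    NoReferenceError,
    ScoreSeries,
    ThresholdModel,
    compute_threshold,
    compute_threshold_series,
    detect_alarm_onsets,
    iqr_upper_bound,
    reference_times,
    window_maxima,
)

MONDAY = pd.Timestamp("2021-01-04")  # a Monday, midnight


def make_series(values, step=600.0, start=MONDAY):
    return ScoreSeries(start, step, np.asarray(values, dtype=float))


def constant_series(value, days, step=600.0):
    n = int(days * 86400 / step) + 1
    return make_series(np.full(n, float(value)), step)


# -- reference times ----------------------------------------------------


def test_reference_times_weekday_query():
    t = pd.Timestamp("2021-01-20 14:00:00")  # a Wednesday
    refs = reference_times(t, 7)
    assert len(refs) == 5
    assert all(r.weekday() < 5 for r in refs)
    assert all(r.time() == t.time() for r in refs)
    assert pd.Timestamp("2021-01-19 14:00:00") in refs  # Tuesday
    assert pd.Timestamp("2021-01-13 14:00:00") in refs  # previous Wednesday


def test_reference_times_weekend_query():
    t = pd.Timestamp("2021-01-23 09:00:00")  # a Saturday
    refs = reference_times(t, 7)
    assert sorted(refs) == [
        pd.Timestamp("2021-01-16 09:00:00"),  # previous Saturday
        pd.Timestamp("2021-01-17 09:00:00"),  # Sunday
    ]


@pytest.mark.parametrize(
    "t, expected",
    [("2021-06-16 03:00:00", 50), ("2021-06-19 03:00:00", 20)],  # Wed / Sat
)
def test_reference_times_full_window_counts(t, expected):
    """70 days = 10 full weeks: 50 weekday and 20 weekend candidates."""
    refs = reference_times(pd.Timestamp(t), 70)
    # independent calendar count over the same window
    oracle = sum(
        ((pd.Timestamp(t) - pd.Timedelta(days=d)).weekday() >= 5)
        == (pd.Timestamp(t).weekday() >= 5)
        for d in range(1, 71)
    )
    assert len(refs) == expected == oracle


# -- window maxima and the IQR fence ------------------------------------


def test_window_maxima_constant_history():
    hist = constant_series(7.5, days=3)
    refs = [MONDAY + pd.Timedelta(days=1, hours=h) for h in range(5)]
    np.testing.assert_allclose(window_maxima(hist, refs, 3600.0), 7.5)


def test_window_maxima_catches_single_step_spike():
    hist = constant_series(1.0, days=2)
    spike_idx = 100
    hist.values[spike_idx] = 42.0
    tref = hist.time_at(spike_idx + 3)  # spike 3 steps before the reference
    assert window_maxima(hist, [tref], 3600.0)[0] == 42.0


def test_window_maxima_matches_nested_loop_oracle(rng):
    from oracles import window_max_nested

    values = rng.gamma(2.0, 10.0, 2000)
    hist = make_series(values)
    centers = rng.integers(10, 1990, size=10)
    refs = [hist.time_at(int(c)) for c in centers]
    hw = int(3600 / hist.step)
    np.testing.assert_allclose(
        window_maxima(hist, refs, 3600.0),
        window_max_nested(values, centers, hw),
    )


def test_window_maxima_requires_references():
    with pytest.raises(NoReferenceError):
        window_maxima(constant_series(1.0, 1), [], 3600.0)


@pytest.mark.parametrize(
    "values, expected",
    [
        ([5.0] * 6, 5.0),  # degenerate IQR: fence collapses onto the value
        ([1.0, 2.0, 3.0, 4.0], 5.5),  # Q1=1.75, Q3=3.25 under linear interpolation
        ([0.0, 0.0, 0.0, 0.0, 100.0], 0.0),  # outlier fully clipped
    ],
)
def test_iqr_upper_bound(values, expected):
    assert iqr_upper_bound(values) == pytest.approx(expected)


def test_iqr_upper_bound_empty_rejected():
    with pytest.raises(NoReferenceError):
        iqr_upper_bound([])


# -- threshold ----------------------------------------------------------


def test_threshold_constant_history_scales_by_alpha():
    hist = constant_series(123.0, days=85)
    cfg = DetectorConfig(alpha=2.0)
    t = MONDAY + pd.Timedelta(days=80, hours=3)
    assert compute_threshold(hist, t, cfg) == pytest.approx(246.0)


def test_threshold_clips_single_outlier_to_iqr_fence():
    """History of m's with one huge maximum: the fence keeps thres at m*alpha."""
    hist = constant_series(50.0, days=85)
    # place a large spike on one weekday so one reference window sees it
    spike_day = 74  # a Thursday (74 days after a Monday start)
    idx = int((spike_day * 86400 + 3 * 3600) / hist.step)
    hist.values[idx] = 5000.0
    t = MONDAY + pd.Timedelta(days=80, hours=3)
    maxima = window_maxima(hist, reference_times(t, 70), 3600.0, before=t)
    assert maxima.max() == 5000.0 and np.median(maxima) == 50.0
    theta = iqr_upper_bound(maxima)
    assert theta == pytest.approx(50.0)
    assert compute_threshold(hist, t, DetectorConfig()) == pytest.approx(100.0)


def test_threshold_undefined_during_initialization():
    hist = constant_series(10.0, days=85)
    cfg = DetectorConfig()
    assert math.isnan(compute_threshold(hist, MONDAY + pd.Timedelta(days=30), cfg))


def test_threshold_undefined_with_too_few_references():
    hist = constant_series(10.0, days=75)
    cfg = DetectorConfig(init_period=2 * 86400.0, min_references=5)
    # 4 days after start a weekday query has at most 4 same-kind references
    assert math.isnan(compute_threshold(hist, MONDAY + pd.Timedelta(days=4), cfg))


def test_threshold_series_matches_scalar_path(rng):
    hist = make_series(rng.gamma(2.0, 1000.0, int(80 * 86400 / 600) + 1))
    cfg = DetectorConfig()
    series = compute_threshold_series(hist, cfg)
    for k in rng.integers(0, len(hist), size=60):
        scalar = compute_threshold(hist, hist.time_at(int(k)), cfg)
        vec = series.values[k]
        assert math.isnan(scalar) == math.isnan(vec)
        if not math.isnan(scalar):
            assert vec == pytest.approx(scalar, abs=1e-9)


def test_threshold_model_wrapper():
    hist = constant_series(10.0, days=85)
    model = ThresholdModel(hist)
    t = MONDAY + pd.Timedelta(days=80)
    assert model.at(t) == pytest.approx(model.series().value_at(t))


# -- threshold properties -----------------------------------------------


def test_threshold_causality(rng):
    """Scores at or after the query time never influence its threshold."""
    hist = make_series(rng.gamma(2.0, 1000.0, int(75 * 86400 / 600) + 1))
    t = MONDAY + pd.Timedelta(days=72, hours=5)
    full = compute_threshold(hist, t, DetectorConfig())
    cut = hist.index_at(t, "floor")
    mutated = make_series(hist.values.copy())
    mutated.values[cut:] = 1e12
    assert compute_threshold(mutated, t, DetectorConfig()) == pytest.approx(full)


def test_threshold_monotone_in_alpha(rng):
    hist = make_series(rng.gamma(2.0, 1000.0, int(75 * 86400 / 600) + 1))
    t = MONDAY + pd.Timedelta(days=72, hours=9)
    lo = compute_threshold(hist, t, DetectorConfig(alpha=1.0))
    hi = compute_threshold(hist, t, DetectorConfig(alpha=2.0))
    assert hi == pytest.approx(2.0 * lo)
    assert hi >= lo


def test_threshold_never_exceeds_fence_times_alpha(rng):
    hist = make_series(rng.gamma(2.0, 1000.0, int(75 * 86400 / 600) + 1))
    cfg = DetectorConfig()
    for k in rng.integers(0, len(hist), size=30):
        t = hist.time_at(int(k))
        thres = compute_threshold(hist, t, cfg)
        if math.isnan(thres):
            continue
        maxima = window_maxima(hist, reference_times(t, cfg.psi_days), cfg.beta, before=t)
        assert thres <= iqr_upper_bound(maxima) * cfg.alpha + 1e-9


def test_weekend_scores_do_not_leak_into_weekday_thresholds(rng):
    hist = make_series(rng.gamma(2.0, 1000.0, int(80 * 86400 / 600) + 1))
    cfg = DetectorConfig()
    base = compute_threshold_series(hist, cfg)
    mutated = make_series(hist.values.copy())
    times = mutated.times
    # perturb weekend scores only, away from midnight by more than beta
    sel = (times.weekday >= 5) & (times.hour >= 2) & (times.hour <= 21)
    mutated.values[np.asarray(sel)] += 1e6
    changed = compute_threshold_series(mutated, cfg)
    weekday_mid = np.asarray((times.weekday < 5) & (times.hour >= 2) & (times.hour <= 21))
    np.testing.assert_array_equal(
        base.values[weekday_mid], changed.values[weekday_mid]
    )


# -- alarm onsets -------------------------------------------------------


def test_no_onset_when_score_stays_below_threshold():
    hist = constant_series(10.0, days=85)
    assert detect_alarm_onsets(hist, DetectorConfig()) == []


def test_single_onset_for_sustained_excursion():
    hist = constant_series(10.0, days=85)
    step = hist.step
    k0 = int(80 * 86400 / step)
    k1 = k0 + int(3 * 3600 / step)  # 3 h above threshold
    hist.values[k0:k1] = 100.0
    onsets = detect_alarm_onsets(hist, DetectorConfig())
    assert len(onsets) == 1
    assert onsets[0].timestamp == hist.time_at(k0)
    assert onsets[0].score > onsets[0].threshold


def test_designed_crossings_match_two_pass_oracle(rng):
    """Three separated excursions: onsets equal a naive per-point scan."""
    hist = constant_series(20.0, days=85)
    step = hist.step
    cfg = DetectorConfig()
    for day, hour in [(74, 10), (77, 3), (79, 16)]:
        k = int((day * 86400 + hour * 3600) / step)
        hist.values[k : k + 4] = 500.0
    onsets = detect_alarm_onsets(hist, cfg)

    thr = compute_threshold_series(hist, cfg)
    oracle = []
    prev_above = False
    for k in range(len(hist)):
        defined = not math.isnan(thr.values[k])
        above = defined and hist.values[k] > thr.values[k]
        if above and not prev_above:
            oracle.append(k)
        prev_above = above
    assert [hist.index_at(o.timestamp, "exact") for o in onsets] == oracle
    assert len(onsets) == 3
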