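# Methods

This note documents the model implemented by `inactiscore`, the
numerical and design choices that were genuinely open, what the
synthetic-data generator does and does not emulate, and the problem
sizes the test suite and `scripts/acceptance.py` run at.

## Score model

The Inactivity Score is a discrete-time recursion on a uniform grid,
`IS(t) = (IS(t−Δt) + a) · RF(t, E_t)`, with `IS` measured in
"seconds-equivalent" (slope `a` defaults to Δt in seconds, so with no
events `IS` equals elapsed time). The per-sensor factor inside the
Reduction Factor is `1 − c(s)·I(t, s)`:

* `c = 1, I = 1` gives factor 0 — a hard reset, identical to the
  classical Duration of Inactivity. With every certainty at 1 the two
  statistics coincide exactly on the grid (this is a tested identity).
* `c < 1, I = 1` gives factor `1 − c`: an isolated uncertain event
  shrinks the score proportionally to how much it is trusted.
* `I < 1` (a refire within `γ(1 − c)` of the sensor's previous
  activation) moves the factor back toward 1, i.e. *weakens* the
  event's ability to reduce the score. This is what contains a
  malfunctioning sensor: firing every few minutes, its per-event
  factor approaches 1 and the score keeps growing, whereas `DI` would
  stay pinned at zero and make emergencies undetectable.

The multiplicative form means simultaneous activations from several
sensors compound (more independent evidence, deeper reduction).

Conventions that the continuous-time description leaves open, fixed
here:

* **Grid.** Default Δt = 60 s; configurable, and the suite also runs
  at 1 s. `E_t` covers events in the half-open step `(t − Δt, t]`.
  A sensor firing several times within one step counts once; its
  stored last-activation time advances to the latest firing.
* **Last activation `l(t, s)`.** The impact of a step's activation is
  evaluated against the sensor's previous activation *strictly before
  this step's firing*; a first-ever activation has impact 1. Reading
  `l` as the current firing itself would force `I = 0` at every event
  and was rejected as degenerate.
* **Initialization.** `IS(t₀) = 0` at the span start; the evaluation
  protocol's 10-week warm-up absorbs the transient.
* **Noise events.** Spurious events update `l` and reduce the score
  exactly like real ones — the detector cannot distinguish them.
* **Gaps.** The grid runs continuously and the score accumulates
  across recording gaps; `split_at_gaps` (default limit 1 h) is
  provided so gap-ridden recordings can be cut into clean segments
  beforehand.
* **Slope reading.** The slope is `a = Δt` in seconds. Fixing `a` at
  1 s per step would only rescale the score, and since thresholds are
  derived from the same series, alarm behaviour is unchanged.

## Threshold model

`thres(t) = min(max(ISmax(t)), Q3 + 1.5·IQR(ISmax(t))) · α` over the
windowed maxima at matching clock time and weekend status in the past
ψ days. Defaults: ψ = 70 days, β = 1 h, α = 2.0, 10-week
initialization. Choices made here:

* **Percentile convention.** Quartiles use linear interpolation
  between order statistics (numpy's default); the convention is
  exposed in `DetectorConfig.percentile_method` so alternates can be
  tested. The clipping applies `min` to the *overall* maximum, as the
  formula states; clipping each element first coincides with it
  whenever only the largest value exceeds the fence.
* **`min_references` = 5.** Right after the initialization period a
  query may have very few reference days (e.g. the first weekend
  hours); quartiles of 1–2 points are meaningless, so thresholds stay
  undefined until at least 5 reference windows exist. With the
  10-week warm-up, weekday queries already have ~50 references.
* **Undefined thresholds** (during initialization or with too few
  references) are explicit NaNs: no alarm can fire there, and they
  are never coerced to 0 or +∞.
* **Causality.** Thresholds at time t use only scores before t. With
  β < 1 day the reference windows (all ≥ 1 day in the past) cannot
  reach t anyway; the scalar path additionally clips windows at t,
  and β ≥ 1 day is rejected at configuration time.
* **History is not censored for past alarms**: scores during earlier
  alarm excursions remain in the reference history (the IQR fence is
  what limits their pull on the threshold).
* The vectorized implementation arranges windowed maxima in a
  (day × time-of-day) matrix, which requires the step to divide 24 h
  and the grid to be day-aligned; a per-query scalar implementation
  without that restriction doubles as its cross-check in the tests.

Alarm onsets follow the first-crossing rule: a point alarms only if
its predecessor was not above its own threshold, so a sustained
excursion counts once.

## Synthetic data

The generator produces what the detector assumes about real homes:

* a circadian household rhythm (24 hourly Poisson intensities,
  default peaking in the morning and evening, near-silent at night,
  ≈ 22 events/day), scaled by `weekend_scale` (default 1.2) on
  Saturdays/Sundays — so the weekend-aware thresholds have structure
  to learn;
* per-sensor activation shares (multinomial, default uniform over 5
  sensors);
* per-sensor certainties drawn by rejection from the four truncated
  normal regimes N(1.00, 0)[1,1], L(0.95, 0.02)[0.9,1],
  M(0.90, 0.10)[0.8,1], H(0.85, 0.20)[0.6,1];
* a spurious-event set with exactly `round((1−c)·|s|)` events per
  sensor (round half-to-even; the count formula is generally
  non-integer), whose time-of-day follows the sensor's empirical
  hourly activation histogram for a `1 − global_fraction` share and
  is uniform over 24 h for the rest. `global_fraction` defaults to
  0.1: the time-independent component is deliberately a documented
  knob, as its magnitude is not prescribed anywhere. Noise timestamps
  are drawn independently of real events; collisions are allowed.

What it does **not** emulate: multi-resident households, pets with
structured movement, room topology and sensor correlation, seasonal
drift, hardware outages, or certainty drift over time. Passing tests
on this generator therefore show the algorithmic properties
(equivalences, threshold behaviour, noise-robustness directions), not
field performance; headline numbers on real recordings depend on the
household and are expected to differ.

## Evaluation protocol

* **False positives**: the detector runs over the full stream; every
  onset after the 10-week initialization counts (the input contains
  no genuine emergencies). The per-day rate divides by the post-init
  span in days.
* **Simulated emergencies**: at onset `t_e`, real events stop and the
  entire noise set keeps flowing. Detection is the first grid point
  `t ≥ t_e` with `IS(t) > thres(t)`; latency is capped at 7 days
  (censored beyond). A trial whose score already exceeds the
  threshold at the grid point at/just before `t_e` is excluded —
  "already in alarm" is operationalized as that single-point test,
  since alarm-state duration is not defined elsewhere. Trials are
  independent (each re-truncates the stream; no cross-trial state).
* Emergency times are drawn uniformly over the post-init span; when
  noise levels are compared, the same onset times are reused across
  levels (a paired design that removes most Monte-Carlo variance from
  the level-to-level contrast).

## Problem sizes and tolerances

The test suite and acceptance script are sized for a desk run: the
noise-robustness study uses one 120-day, 5-sensor household with 100
simulated emergencies per noise level (3 seed replicates in the test
suite, averaged), the oracle-equivalence check uses 100 random streams
of up to 200 events, and protocol unit tests use a 10-minute grid.
Score-vs-oracle comparisons are exact to 1e−9 (pure float-product
arithmetic). The trend assertions allow 10 minutes of slack on median
detection times and 2 onsets on false-positive counts between adjacent
noise levels — small relative to the observed contrasts (medians move
by hours from no-noise to high-noise) but enough to absorb replicate
jitter in rare-event counts.

## Known limitations

* Certainties are assumed known and constant; estimating or tracking
  them is out of scope.
* The detector is household-global: no room-level scores.
* Naive local timestamps; DST transitions are not modelled.
* Thresholds need ψ days of history before they stabilize; during
  sparse early history the `min_references` guard trades alarm
  availability for threshold sanity.
* The alarm rule reports onsets only; it does not model alarm
  clearing, acknowledgement, or delivery.
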