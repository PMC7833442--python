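# Methods

This note records the models, conventions and numerical choices behind
`afmonitor`, and what the synthetic experiments do and do not demonstrate.

## Synthetic rhythm model

The generator produces beat-to-beat (RR) interval sequences in two regimes.

**NSR.** Interval *i* is `nsr_mean_rr + A·sin(2π t_i / T_resp) + ε`, with
`ε ~ N(0, nsr_sd²)` and the sinusoid evaluated at the beat's onset time.
The single sinusoidal term emulates respiratory sinus arrhythmia — enough
serial structure to make NSR variability "modest and organised" without
claiming physiological realism. Defaults: mean 850 ms, sd 30 ms,
respiratory period 4 s, amplitude 25 ms.

**AF.** A stationary first-order autoregressive process in the interval
domain: `x_i = μ + φ(x_{i−1} − μ) + η`, with `φ = af_lag1_corr = 0.1` and
innovations scaled so the marginal sd equals `af_sd = 120 ms`
(μ = 700 ms). Low lag-1 correlation plus large dispersion is the simplest
model with a tunable irregularity/correlation contrast to NSR — the
"irregularly irregular" fingerprint. This is explicitly a stand-in
distribution: no published AF RR statistics were fitted, and all default
magnitudes are plausible conventions chosen once, not estimates.

Draws below a 250 ms physiological floor are rejected and resampled; the
floor is far (>3.5 sd) from both default means, so the induced mean bias is
negligible (the stationarity test bounds it at three standard errors).

Segments emit beats until cumulative time first reaches the requested
duration, so a segment can overshoot by at most one interval; in a
multi-segment recording each beat is labelled by the segment generating it,
i.e. the realised boundary is the final beat time of the previous segment.
The AR(1) state resets at each boundary (episodes are independent). One
`numpy` generator seeded by `RhythmParams.seed` drives every draw, so a
recording is bit-reproducible from its parameters.

**What this does not model:** ectopic beats, measurement noise and dropout,
circadian trends, rate responses to activity, or any ECG morphology. A
detector that separates these two synthetic regimes has learned a rate +
dispersion + serial-structure contrast; transfer to Holter data is a claim
the synthetic benchmark cannot support and is not made.

## Detector

Architecture: bidirectional LSTM (32 units per direction) over the window's
interval sequence → global max pooling over time, per feature → a single
fully connected unit → sigmoid, yielding one AF probability per window.
Global max pooling makes the window score sensitive to the most AF-like
stretch anywhere in the window, which suits paroxysmal onsets.

The network, BPTT gradients and Adam are implemented in NumPy; the test
suite checks the analytic gradients against central finite differences at
1e-6. Inputs are intervals scaled ms → s (factor 1/1000) with **no**
per-window standardisation: absolute rate is itself informative (AF is
faster on average in the synthetic model), and removing it would discard a
real feature. Windows are scored one at a time at prediction, because BLAS
products round differently for different batch shapes and a window's
probability must not depend on its batch companions (this is what makes
streamed and batch monitoring byte-identical).

Training: binary cross-entropy, Adam (lr 3e-3), minibatch 64, at most 50
epochs with early stopping (patience 8) on a 15 % validation split;
the best-validation-loss weights are restored. All randomness — weight
initialisation, the split, batch shuffling — flows from one seeded
generator, so training is deterministic given (data, seed, config).
Checkpoints are self-describing JSON (format tag, architecture, weights,
training metadata including a data fingerprint).

Windowing: 100-beat windows (~1–2 minutes of data), stride 100 for
training (non-overlapping) and stride 10 for monitoring, which yields a
probability sample every ~7–9 s — comfortably denser than the 30-s alarm
rule. A labelled window takes the majority beat label, with ties resolved
to AF: for a screening tool the conservative direction is toward
sensitivity. Probabilities are stamped at the window's final beat, keeping
the trace causal.

Evaluation: stratified ten-fold cross-validation (folds via
`sklearn.model_selection.StratifiedKFold`; disjoint, exhaustive, sizes
±1) and hold-out evaluation. Reports carry explicit confusion counts;
accuracy, sensitivity, specificity and PPV are recomputed from the counts
on access, so metric/count consistency is structural. The cross-validation
summary pools counts over the ten test folds (micro-average); per-fold
reports are also returned.

The **standard synthetic benchmark** is 200 NSR-only plus 200 AF-only
recordings of 120 beats (one 100-beat window each), per-recording seeds
spawned from one master seed. Recordings are generated at 1.3× the nominal
beat-duration and truncated to exactly 120 beats. Benchmark size was chosen
so the whole train/CV/hold-out harness runs in a couple of minutes on one
CPU while leaving headroom above the 0.95 accuracy bar.

## Alarm rule

An event is a maximal run of trace samples with probability **strictly**
above the threshold (default 0.5 — "above" is read as strict, so exactly
0.5 never counts) spanning at least `min_duration` (default 30 s), duration
measured from the run's first to last sample timestamp (the trace is
sampled; no interpolation rule is assumed, so the 30-s boundary is
unambiguous: a 29-s span is rejected, a 30-s span fires).
`detection_time = run_start + min_duration` is the earliest instant the
rule holds. Inter-sample gaps larger than `max_gap` (default 10 s) break a
run: missing data must never silently count as super-threshold. One event
per maximal run; re-alarming requires the run to end first.

Note that the event *count* is not monotone in the threshold — lowering it
can merge two qualifying runs into one — but events nest: every event at a
higher threshold lies inside an event at any lower threshold. The tests
check the nesting property and freeze a merging counterexample.

Dispatch stamps the alarm message with a simulated dispatch time
(default: the detection time itself) and flags, rather than rejects,
violations of the 300-s latency contract, so a late-delivery scenario can
be represented and audited. The rule's clinical adequacy (is 0.5/30 s
sensitive and specific enough?) is an open question; everything is
configurable for that reason.

## HRV biomarkers

Standard time-domain panel over a half-open region of interest
`[start, end)` on beat times. Conventions, fixed and enforced by an
independently coded direct-formula oracle in the tests:

- SDNN and SDSD use the **population** (1/n) standard deviation;
- RMSSD is the root of the mean squared successive difference;
- NN50 counts |Δ| **strictly** greater than 50 ms;
  pNN50 = 100·NN50/(n−1);
- SD1 = SDSD/√2 (an identity, tested on random inputs);
  SD2 = √(2·SDNN² − SD1²), floored at 0 before the root;
- mean HR = 60000 / mean RR.

No ectopic-beat filtering precedes the statistics (an extension point);
frequency-domain and nonlinear measures beyond Poincaré are out of scope.
The probability colour map assigns each beat the probability of the latest
window ending at or before it (earlier beats are "unscored"), with display
classes low < 0.25 ≤ mid ≤ 0.75 < high — the cut points are display
conventions only.

## Service layer

The registry is one versioned JSON file; each patient gets two channel
files (`RR_interval_data`, `AF_detection_result`) as CSV
(`# epoch=…` comment, `timestamp,value` header, seconds and ms/probability),
written with `repr` float formatting so files are byte-deterministic and
values round-trip exactly. Readers validate — out-of-range rows are
errors naming their line numbers, never clamped. Channel access requires
the record's opaque channel key (an authorization surface, not
cryptography).

A monitor poll recomputes the full probability trace and rewrites the
result channel and alarm log from the complete event list; combined with
per-window scoring this makes incremental polling byte-identical to batch
processing, and a poll with no new complete window writes nothing
(idempotence). Appending RR chunks rewrites the channel from the full
interval sequence for the same reason (floating-point summation is not
associative across chunk boundaries).

Feedback mapping: red strictly requires a physician-recorded
`AF_confirmed` (the hybrid principle — the machine never escalates to red
on its own); orange on an alarm newer than the latest diagnosis or on a
data interruption (> 15 min without beats, configurable); green otherwise.
A rejected diagnosis returns the light to green and monitoring simply
continues. Diagnoses append to a JSONL audit log, stored as potential
future training labels; automated retraining is out of scope.

All timing in tests and scripts is simulated data time; nothing is
wall-clock-dependent.

## Known limitations

- The synthetic AF model is a convention; benchmark metrics say nothing
  about performance on real Holter data (the optional `wfdb` adapter
  exists for users who want to try).
- The alarm rule's parameters are unvalidated clinically and deliberately
  configurable.
- The detector has no calibration step; probabilities are consumed through
  a threshold, not as calibrated risks.
- Single-channel RR only: no ECG morphology, no multi-sensor fusion.
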