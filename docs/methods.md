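# Methods

## Problem and pipeline

A power wheelchair's accelerations are weak and brief compared with
walking or running signatures, and consumer devices differ widely in
sensitivity, noise and sampling. The package therefore separates the
problem into a device-normalizing preprocessing stage, a temporal
classifier, and deterministic rule-based cleanup, followed by bout
accounting. Each stage is exposed both as plain functions over typed
containers and as scikit-learn estimators (`DDRTransformer`,
`BiLSTMMotionClassifier`, `BaselineANNClassifier`, `LabelSmoother`).

## Differential preprocessing

The model of a reading is `α = α_T + α_N` with `α_N` (sensor bias,
environmental interference, gravity projection) nearly constant between
consecutive samples. Forward differences `a′ᵢ = aᵢ₊₁ − aᵢ` therefore pass
the maneuver signal and suppress the noise. Choices that were genuinely
open and how they were fixed:

* **Difference direction and timestamping.** Forward difference, each
  difference stamped at the *later* sample (the value reflects change up
  to that instant). Validated against a published worked example: the nine
  differences of the printed moving-segment column reproduce row by row to
  printed precision (the printed stationary column does not align with its
  own raw column under any consecutive-difference convention and appears
  to come from an offset window; it is not asserted).
* **Irregular sampling.** Differences are taken between consecutive
  samples regardless of the gap; the gap is not a denominator. The
  event-driven sampling model (gaps uniform in `[1/30, 1/13]` s) makes
  rates vary sample to sample, and the method is deliberately insensitive
  to that.
* **Quartiles** use linear interpolation of order statistics (the common
  scientific-software default; the estimator is pinned by an independent
  interpolation oracle in the tests). Bounds are computed once per
  recording, before clipping — this is an offline batch method. Only the
  upper fence `Q₃ + 1.5·IQR` applies, since magnitudes are nonnegative.
  Note the fence is *not* monotone under appending extreme values with
  this estimator (interpolation can cross large jumps); only the ordering
  invariants `q₁ ≤ q₂ ≤ q₃ ≤ upper` are guaranteed.
* **Degenerate normalization.** A constant magnitude sequence maps to all
  zeros: a flat differentiated magnitude means no motion signal, and zero
  is the stationary signature.

## Segment classifier

Segments are 10 consecutive normalized values (~1 s of data), the trailing
remainder discarded (< 1 s precision loss, the same granularity a segment
decision has anyway). Ground-truth labels assign a segment to moving iff
at least half of its covered time overlaps moving intervals, ties going to
moving (favors bout-boundary recall; the choice is otherwise arbitrary).

The network is two bidirectional LSTM layers (32 units per direction), a
20-unit ReLU dense layer, and a per-segment sigmoid. It is implemented
directly in numpy — forward pass, exact backpropagation through time, and
Adam — and the gradients are verified against central finite differences
in the test suite. Parameters that the underlying design left open, with
the values fixed here:

| parameter | default | rationale |
|---|---|---|
| hidden units / direction | 32 | small enough for CPU training in seconds |
| dense units | 20 | matches the published topology |
| loss | per-timestep binary cross-entropy | standard for sequence labeling |
| optimizer, lr | Adam, 1e-3 | robust default |
| training sequence length L | 50 segments | bounded-memory training; prediction runs the full stream in one pass so every segment keeps full context |
| batching | one Adam step per sequence, order reshuffled each epoch (seeded) | full-batch steps made so few updates that accuracy-plateau early stopping could halt a run severely undertrained |
| threshold | 0.5 | implied by the 0/1 output coding |
| max epochs | 2000 | early stopping is the effective control |
| class weighting | none | itineraries are roughly balanced |

**Training protocol.** One recording trains; a second recording's first
25% of segments validates. Early stopping halts after 100 epochs without a
validation-*accuracy* improvement; the parameters kept are from the best
epoch, with accuracy ties broken by validation cross-entropy (accuracy on
~100 segments is quantized to ~1%, so ties are common while the model is
still improving). Training is bitwise-reproducible given `random_state`.

A per-segment feed-forward baseline (`BaselineANNClassifier`, one hidden
layer via scikit-learn's MLP) is included for comparison: without temporal
context its label stream is noisier around bumps and speed changes, which
the transition-count test demonstrates on a disturbance-heavy scenario.

## Smoothing rules

All rules operate on maximal runs of equal labels. "Short" means at most
`short_run_max` segments; the default 3 (~3 s) is long enough to absorb
bump/speed-change artifacts and short enough not to delete real bouts —
the value is configurable, as no numeric threshold is inherent to the
rule definitions. Decisions:

* Spikes/dips are removed only when flanked on both sides by *strictly
  longer* opposite runs; runs touching the stream boundary are never
  rewritten (no evidence about what lies beyond the stream).
* An oscillation region is a maximal block of ≥ 3 consecutive short runs
  adjacent on exactly one side to a long moving run. Its `ceil(2L/3)`
  segments nearest that run become moving, the rest stationary — the
  wheelchair is mostly moving during such a region, and the rule is
  mirrored for rough stops by symmetry of that rationale. Blocks flanked
  by long moving runs on both sides are left to the spike/dip rules.
* Pass order: oscillations → spikes → dips, iterated to a fixpoint (≤ 10
  passes): run-length rules applied first would chew an alternation region
  one run at a time and destroy its 2/3–1/3 geometry. The result is
  idempotent (property-tested on random streams).

## Bouts

Maximal moving runs become bouts spanning first-segment start to
last-segment end, so duration granularity equals the segment span. Bouts
under `min_bout` (default 2 s, configurable) are discarded; published
analyses of this kind report bouts an order of magnitude longer, so the
floor only suppresses residual label noise.

## Synthetic data: what it emulates, what it does not

Each axis reading is `scale × (gravity projection + bias random walk +
white noise [+ movement vibration + transients + jolts])`, sampled on an
event-driven clock with gaps uniform in the device's rate range. The
stationary white-noise sd (0.03 m/s², differences ~0.04) and the movement
vibration sd (0.75, differenced per-axis rms ~1.1) are calibrated to a
published example sequence of raw and differentiated readings; the bias
walk (0.005 m/s² per step) keeps consecutive-sample noise correlation
high, which is precisely the property differencing exploits. Movement
vibration is white noise plus a low-frequency sinusoid of random phase —
no claim is made about real vibration spectra; any model that separates
the variance regimes exercises the method. Styles add a mid-bout
vibration collapse (a dip), a damped 8 Hz jolt while parked (a spike), or
an on/off vibration square wave at bout edges (oscillations).

The device catalog (five profiles: holder phone, tray phone, wrist watch,
quiet phone, noisy phone) spans sensitivity ×0.5–×2, white noise
×0.5–×2, distinct orientations and sampling ranges within 13–30 Hz. These
are plausible placeholders consistent with consumer MEMS accelerometer
noise figures, not measurements of particular hardware.

`generate_trial` lets several profiles observe the *same* physical run
(shared vibration spectrum and jolt directions, device-own clocks and
sensor noise) — the tray-of-phones layout of a cross-device agreement
experiment; `jitter_scenario` varies step durations ±15% per trial the
way a human driver varies an itinerary.

Passing tests on this generator show the pipeline is correct, placement-
and scale-invariant, and robust to the modeled heterogeneity. They do not
show robustness to phenomena the generator omits: non-wheelchair hand or
phone activity, terrain-dependent vibration spectra, temperature drift,
or sensor saturation.

## Benchmark problem sizes

The cross-device benchmark trains on one ~250 s simulated trial (~440
segments) and evaluates 20 jittered runs of a ten-bout itinerary on four
unseen profiles (~800 bout measurements); this desk-scale design mirrors
the layout of the original two-series validation (timer-recorded trials;
a wheel-mounted reference device) while remaining a property-based check,
not a reproduction of hardware results. The packaged fixture tables carry
the original experiments' printed bout durations, from which every
targeted summary statistic is recomputed exactly (percent differences are
means of per-bout percentages; standard deviations use n−1 across the six
phone columns).

## Known limitations

* The classifier distinguishes moving from stationary only; hand or phone
  use unrelated to driving would be misread as movement.
* Whole-recording outlier bounds and MinMax scaling make the pipeline
  batch-only; a streaming variant would need windowed statistics.
* Bout timing inherits segment granularity (~1 s); sub-second bout edges
  are not resolved.
* The numpy LSTM is single-threaded and CPU-oriented; it is sized for
  minutes-long recordings, not days of continuous data.
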