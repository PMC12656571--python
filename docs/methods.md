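# Methods

## Signal model and assumptions

A recording is modeled as a uniformly sampled multichannel series: time of
sample *i* is *i / f*ₛ with *f*ₛ the (nominal) sampling rate. Readers
accept mildly irregular timestamps and linearly resample onto the nominal
grid, since every window↔seconds conversion in the pipeline assumes uniform
spacing. Mid-recording dropouts are represented as masked samples
(`valid_mask`), never deleted rows, so absolute time and annotation
alignment survive gaps; every downstream stage skips windows that touch a
masked sample. Euler angles are taken as-is in degrees (no ±180° unwrap:
abdominal inclination stays far from the wrap point in upright postures;
if a mounting produces wraps, unwrapping belongs in feature engineering,
not in the reader).

Annotations are sparse labeled intervals, breathing or noise; anything not
covered is unlabeled. Unlabeled data are deliberately kept in the window
stream (flagged, excluded from training and metrics) so that qualitative
timelines show classifier behaviour on transition spans.

## Features and normalization

Fourteen channels per time step, in a frozen order: the six raw channels,
their first-order differences, and the Euclidean norms of the Euler and
acceleration 3-vectors. Differences are plain sample-to-sample deltas (not
scaled to units/s); a zero is prepended and the first sample after each gap
is zeroed, so no feature mixes valid and masked samples. Normalization is
per-channel z-scoring with the population (1/n) standard deviation, fitted
on training windows only and applied everywhere else; a zero-variance
channel raises an error naming the channel. The squared Euler magnitude
used by phase detection is kept separate from the (square-rooted) norm
features: extremum timing is invariant under the monotone square, so the
cheaper form is used where only timing matters.

## Windowing and labels

Windows are half-open ranges [start, start + w) advanced by a fixed stride;
the stride grid restarts at the beginning of each maximal gap-free run, so
the per-run window count is exactly ⌊(n − w)/step⌋ + 1. A window inherits a
label when ≥80% of its samples lie in intervals of that label and no sample
lies in the opposite class; everything else stays unlabeled. The purity
floor avoids teaching the network contradictory boundary windows; 80% was
chosen as the smallest majority that still leaves boundary windows (which
genuinely mix classes) unlabeled at the default geometry.

Class weights are the balanced form n_total/(n_classes·nᵢ), computed per
training fold, and satisfy Σ nᵢwᵢ = n_total exactly.

## Classifier

Two valid (unpadded) 1-D convolutions (32 then 64 filters, kernel 5), max
pooling of 2 after each, an LSTM with 64 units emitting its final hidden
state, dropout p = 0.5, a 32-unit ReLU dense layer and a single sigmoid
output. Parameter count is independent of window length: 2,272 + 10,304 +
33,024 + 2,080 + 33 = 47,713. Valid padding was chosen over same padding
(the count is unaffected and edges contribute no artificial context); a
window must be at least 16 samples to survive both conv/pool stages. The
LSTM uses gate order input/forget/candidate/output with the forget bias
initialized to 1; initial weights are Glorot-uniform from a seeded
generator.

The stack, its gradients (including backpropagation through time) and Adam
(lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7) are implemented directly in numpy in
double precision; the test suite checks every analytic gradient against
central finite differences. Training is a pure function of (data, seed):
shuffling and dropout masks come from one seeded generator, so histories
are bit-reproducible. Loss is binary cross-entropy on logits with
per-sample class weights; breathing is the positive class. Epoch count is
fixed (default 30); a validation set, when given, is monitored only —
there is no early stopping. The training history records the weighted
training loss and the unweighted validation loss per epoch.

## Evaluation protocol

Grouped k-fold (default 5): subjects are sorted by descending window count
(ties broken by a seeded shuffle) and dealt round-robin to folds, which
balances fold sizes without ever splitting a subject. Per fold, the
normalization statistics and class weights are fitted on the training
windows only; the fold model is freshly initialized from a per-fold seed.
Metrics use the standard binary definitions with breathing positive;
ratios with zero denominators are reported as absent rather than zero.
A window-size sweep repeats the whole procedure per size and reports
mean ± sd over folds.

## Post-classification segmentation

Probabilities are binarized at 0.5 (ties to breathing), smoothed with a
centered, edge-shrunk 5-window moving average of the *binary* sequence,
re-binarized at 0.5, and runs of ones shorter than 3 windows are zeroed.
Surviving runs merge into segments spanning first window start to last
window start + window duration; a jump in start times larger than the
stride (a gap) always closes a run, so segments cannot span gaps.

Phase detection smooths the squared Euler magnitude with a 0.5 s centered
moving average and finds maxima and minima separately (minimum separation
1.0 s — a physiological half-cycle floor; prominence ≥ 0.1 × the smoothed
signal's within-segment standard deviation), merges them, and enforces
alternation by keeping the more extreme of any same-kind adjacent pair.
By the default polarity, maxima end exhalation and minima end inhalation;
a `polarity="inverted"` flag swaps the roles for sensors mounted with the
opposite sign convention, since the mapping depends on mounting. Partial
phases outside the first/last extremum are discarded; a segment with fewer
than two extrema reports zero breaths and is counted in a report footer
rather than listed. Per segment, the mean cycle duration is defined as the
sum of the mean inhalation and exhalation durations, so the additivity
identity holds exactly.

## Synthetic data: what it emulates, and what it does not

The simulator emulates a two-part wearable protocol: a quiet-standing
breathing block and walking (gait) episodes, separated by unlabeled
transitions, with optional masked gaps. Breathing is a piecewise
raised-cosine cycle — descending over the inhale fraction of the period,
ascending over the rest — so minima end inhalation and maxima end
exhalation, and inhale/exhale durations are genuinely asymmetric
(a symmetric sinusoid could not exercise the phase-duration logic).
Defaults are physiological: mean cycle 4 s (sd 0.3 s between cycles, and
between subjects in cohort mode), inhale fraction 0.6, Euler oscillation
5° on the dominant axis over a 25° baseline. Gait noise is band-limited
Gaussian motion in 1.5–2.5 Hz (the stride band of normal walking) plus
step-like baseline drift, with amplitude (8° / 1.5 m/s²) exceeding the
breathing oscillation; it carries no stable respiratory-band periodicity.
Amplitudes in sensor units are free parameters — no published calibration
exists — and are documented defaults, not fitted values.

This synthetic regime makes the two classes nearly separable once sensor
noise is small. Passing the cohort-level tests therefore demonstrates that
the pipeline is correctly wired (no leakage, learning occurs, segmentation
recovers ground truth), **not** that real-world accuracy matches any
particular figure: real recordings add posture drift, sensor artifacts,
inter-subject waveform diversity and ambiguous transitions that the
simulator intentionally omits (as do biomechanically realistic gait and
gravity/posture coupling).

## Problem sizes and numerical choices

Tests and examples run a 10× scaled-down geometry — 33 Hz sampling,
100-sample (≈3 s) windows, 10-sample (≈0.3 s) stride, cohorts of 4–10
subjects, ≤6 training epochs — chosen so the full numpy training loop
stays fast while preserving the window/stride/breath-cycle proportions of
the full-rate configuration (330 Hz, 2000/100 samples). The
physiological generator defaults are identical at both scales. Tolerances:
phase-recovery checks allow 0.3 s (one stride at full scale); gradient
checks use central differences at 1e-6 with relative tolerance 1e-4;
batched and unbatched inference are required to agree to 1e-12.

## Known limitations

- The classifier is trained and validated per cohort; no pre-trained
  weights ship with the package.
- The noise class aggregates all non-breathing motion; breathing during
  vigorous movement is out of scope.
- Segment boundaries are quantized to the window stride and windows claim
  their full span, so segment edges can overhang the true activity by up
  to one window length on either side.
- Respiratory-rate trending across recordings and apnea detection are not
  implemented.
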