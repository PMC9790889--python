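# Methods

This note documents the models, numerical choices, and limitations of
`fcrnet` in enough detail to reproduce or audit any stage.

## Synthetic sessions

The generator emulates a cued four-class motor-imagery protocol: 72
trials/class, 22 electrodes (standard motor-imagery montage Fz … POz),
250 Hz, a 4 s imagery window, optionally prefixed by 2 s fixation + 1.25 s
cue so that analysis windows quoted relative to trial start (2.5–6 s) can be
indexed.

*Sources.*  One latent oscillator per class: Gaussian noise band-passed
(4th-order Butterworth, zero-phase) to the class band and normalized to unit
variance per trial.  Defaults: classes 0/1 share the mu band (8–12 Hz) and
are separated spatially — mimicking left/right-hand ERD lateralization —
while classes 2/3 share the beta band (20–24 Hz).  On a trial of its own
class the oscillator's standard deviation is multiplied by `class_gain`
(default 2.0, i.e. a 4× variance contrast).  With the fixation/cue prefix
the modulation is applied only inside the imagery window.

*Mixing.*  Sources are mixed into electrodes through a full-column-rank
matrix; the default draws a random orthonormal 22×4 matrix from the session
seed, so the true unmixing directions are simply the mixing columns.  The
generator returns this ground truth on request for parameter-recovery tests.

*Noise and SNR.*  Background noise is white or pink (1/f power shaping).
`snr_db` is defined as **class-band SNR**: the ratio of total source power to
background power *within the source bands*.  A broadband definition would
leave the narrow class bands of a band-limited-source generator almost
background-free (in-band background ≈ 0.3% of total), producing covariance
pencils conditioned ~500:1 in which CSP filters rotate freely inside a
near-empty background subspace — a degenerate regime no real recording
exhibits.  The class-band definition matches how SNR is quoted for
narrowband rhythms and keeps the estimation problem realistic.  The in-band
noise fraction is measured on the realized noise sample (rFFT power in
band), so the requested ratio is exact for each generated session.

*What the generator does not model.*  Volume-conduction forward physics,
ocular/muscular artifacts, non-stationary drift, inter-subject variability.
Passing tests therefore demonstrate algorithmic correctness and sensible
behaviour under controlled spatio-spectral structure, not performance on
real recordings.

## Filter bank and segmentation

Nine contiguous 4 Hz Butterworth band-pass filters (4–40 Hz), order 4,
applied forward-backward by default (zero phase; the effective magnitude
response is the squared single-pass response).  Filters are applied to
epochs, not continuous data; zero-phase filtering of a 4–7 s epoch leaves
negligible transients for these bandwidths.  Time-step windows are
interpreted relative to trial start (so 2.5 s ≈ cue + 0.5 s under the 2 s
fixation convention) and sliced half-open with `start = round(t₀·fs)`,
`length = round((t₁−t₀)·fs)` — interval *lengths* drive downstream shapes,
so a 1 s window is exactly 250 samples at 250 Hz.

## CSP

Per-class covariance is the average of per-trial trace-normalized
covariances (unit trace).  The two-population solution solves the symmetric
definite generalized eigenproblem `R_i W = (R_i+R_j) W D` via
`scipy.linalg.eigh(R_i, R_i+R_j)`, whose B-orthonormal eigenvectors give the
composite normalization `W(R_i+R_j)Wᵀ = I` directly; eigenvalues are sorted
descending with ties left in solver order, and each filter's
largest-magnitude coefficient is made positive, so outputs are
deterministic.  Correctness is checked against an independent route (whiten
the composite by an ordinary symmetric eigendecomposition, then diagonalize
the whitened `R_i`).

*Regularization.*  `solve_csp` applies a token shrinkage
`R ← (1−γ)R + γ·tr(R)/C·I` with γ = 1e−6 to guard against exactly singular
inputs.  The multi-scale bank (`fit_msfbcsp`) defaults to γ = 0.3: a
4 Hz-wide block of a few-second window carries only a few dozen effective
samples per trial (2·bandwidth·duration), so the background eigenvalues of
the composite are tiny and poorly estimated, and the whitening step
amplifies their sampling error into large rotations of the top filters.
Strong shrinkage re-inflates the background floor without displacing
well-separated discriminative components; the intensity sits in the range
regularized-CSP studies select by cross-validation.  Measured on generated
sessions (snr 6–12 dB, 72 trials/class), the top mu-band filter then
recovers the true unmixing direction with |corr| ≥ 0.95 across seeds,
versus ≈ 0.93 at best with weak shrinkage.

Multi-class handling defaults to one-vs-rest (4 contrasts), with pairwise
contrasts available.  Features default to raw variance over time;
log-normalized variance is available.

## Envelopes

Envelope = magnitude of the analytic signal (frequency-domain Hilbert
transform) computed with 10% reflective padding, trimmed afterwards, to tame
edge artifacts.  The envelope band is limited to 4 Hz (zero-phase 4th-order
Butterworth), so any output rate ≥ 8 Hz is alias-free; requests below that
raise.  Resampling to the unified point count uses polyphase filtering with
mean-padding (`resample_poly`), which preserves constants to machine
precision and handles non-integer ratios (e.g. a 3.5 s window → 40 points);
small filter undershoot below zero is clamped since amplitudes are
physically nonnegative.

## Network

All layers are NumPy with hand-written backward passes (finite-difference
checked).  Convolutions are bias-free; batch normalization carries the 2
trainable parameters per feature map — the only reading consistent with the
reference parameter table (512/16/352/32/384/16 for the (22, 288)
configuration).  Average pooling truncates a trailing remainder when the
epoch length is not divisible by pool1·pool2 (e.g. 500 samples → sequence
length 15); the flatten width is F2·⌊⌊T/4⌋/8⌋.

*LSTM.*  The default candidate uses tanh and the hidden state is
`o⊙tanh(c)` (standard).  A literal linear-candidate mode — candidate without
tanh, reusing the input gate's recurrent weights, and `h = o⊙c` — is kept
for fidelity experiments; the literal cell is unbounded and ties two
unrelated gates, so it is not the default.  The CNN-to-LSTM interface treats the
pre-flatten map as a sequence of F2-dimensional feature vectors.

*Fuzzy neural block.*  Rule activations are computed in the log domain
(sum of log-memberships, shifted exponential normalization), so products
over hundreds of dimensions cannot underflow to a 0/0 normalization.  α is
trained by gradient (clipped to ≥ 1e−3 after each optimizer step to keep it
positive); centroids are *not* gradient-trained: they are zero during the
first epoch and refreshed between epochs by fuzzy c-means (fuzzifier m = 2,
seeded data-point initialization, tolerance 1e−6) over the LSTM outputs
collected during the preceding epoch.  Centroid gradients are still
computed, so the block is fully finite-difference checkable.

*Head.*  A dense branch (ELU) and the fuzzy block run in parallel from the
last LSTM hidden state; their outputs are concatenated (sum-merge available
when widths match) and classified by a dense softmax layer.  Disabling the
fuzzy block removes only that branch and shrinks the head — the ablation
configuration.

*Input modes.*  `raw` feeds (channels × samples) epochs; `envelope` feeds
the MSFBCSP envelope tensor flattened to (band·window·component) rows of
unified length.  The network itself only sees a (C, T) rectangle.

*Training.*  Adam (defaults lr 2e−3, β 0.9/0.999), seeded shuffling and
dropout, per-channel standardization with training-fold statistics,
optional zero-phase decimation of the time axis as input conditioning.
Float64 is the default compute precision (exact gradient checks); float32
is used for the larger training runs.  Given a seed, training is bit-level
deterministic on a fixed BLAS.

## Evaluation

Stratified k-fold cross-validation with seeded shuffling; every trial is
tested exactly once.  Kappa is computed both per fold and from the pooled
confusion matrix (`κ = (p_o−p_e)/(1−p_e)`; for balanced K-class marginals
this is `(acc−1/K)/(1−1/K)`); a degenerate single-cell matrix yields 0 with
a warning.  The per-electrode protocol rebuilds the model with C = 1 per
channel, keeping all other hyperparameters (the adaptation is otherwise
unspecified); region means are unweighted averages over the frontal (Fz,
FC3, FC1, FCz, FC2, FC4), central (C5…C6), and parietal (CP3…POz) groups.

## Tuning

Coordinate descent sweeps integer/categorical axes exhaustively, updating
after each axis; accepted scores never decrease, and a failing objective
scores −∞ and is skipped.  Bayesian optimization fits a GP (Matérn 5/2 on
unit-normalized coordinates, expected improvement with ξ = 0.01) and picks
the EI maximizer over a 512-point seeded candidate set per round; integer
axes are relaxed continuously and rounded at evaluation; if all observed
scores are equal the surrogate is uninformative and the round falls back to
random sampling with a warning.

## Problem sizes of the reference protocols

The end-to-end protocol uses one default-shaped session (288 trials × 22
channels, 10 dB class-band SNR), epochs decimated 250 → 125 Hz, float32,
12 training epochs per fold, 10 folds; the shuffled-label control uses 3
folds of the same data; the SNR sweep uses 36 trials/class at {0, 6, 12} dB
with one stratified 96/48 split per repetition, 3 repetitions, comparing
mean held-out accuracies.  These sizes were chosen as the smallest at which
the qualitative claims (separability, chance under shuffling, monotonicity
in SNR) are stable across seeds.

## Known limitations

- The NumPy network is single-threaded and CPU-bound; it is meant for
  correctness and desk-scale experiments, not large-scale training.
- The generator's linear instantaneous mixing and stationary sources make
  the decoding problem easier than real EEG; absolute accuracies on
  synthetic sessions say nothing about benchmark performance on real data.
- GDF/EDF ingestion delegates to MNE and is exercised in tests through the
  FIF path (written natively by MNE); the GDF/EDF readers themselves are
  not covered by fixtures.
- The reference parameter table's published total (1946) is not the sum of
  its own per-layer entries; the per-layer counts are treated as
  authoritative and reproduced exactly.
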