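# Methods

This note documents the models and procedures implemented in
`stratnorm`, the parameters that matter, and the choices made where the
design was genuinely open.

## Feature extraction

Each trial (channels × samples, one sampling rate per dataset) is
reduced to one value per channel and per rhythm — theta 4–7 Hz, alpha
8–13 Hz, beta 14–30 Hz, gamma 31–50 Hz. Delta (0.5–4 Hz) is excluded:
it is dominated by slow drift and sleep-related activity and carries
little evoked-emotion information. The dataset validator requires
fs ≥ 100 Hz so the gamma edge stays below Nyquist.

**Welch band power.** Hann-tapered, mean-detrended segments of 0.5 s
with 0.25 s overlap (two full cycles of the lowest frequency of
interest), averaged into a one-sided density, integrated over each band
with composite Simpson's rule (inclusive band edges; even interval
counts handled by the standard correction term). Segments are
zero-padded so the frequency grid spacing is at most 0.25 Hz: a plain
0.5 s window at 200 Hz would give a 2 Hz grid with only two points
inside theta, too few for quadrature. Zero padding trigonometrically
interpolates the spectrum and leaves integrated power unchanged, so
Parseval checks are unaffected. Note that a 0.5 s Hann window has an
≈8 Hz wide main lobe; narrow-band structure is smeared across
neighboring bands regardless of the grid. This is inherent to the
window length, which is part of the method definition; analyses that
need to resolve a narrow band sharply should pass a longer `win_s` or
use the multitaper route.

**Multitaper band power.** DPSS tapers over the *full* trial with
time-half-bandwidth NW = 4 and 2·NW − 1 = 7 tapers, eigenspectra
averaged with unit weights (no adaptive weighting), integrated like
Welch. Applying the tapers to the whole trial gives the finest
frequency resolution the trial supports.

**Differential entropy.** The channel is band-passed with a 4th-order
Butterworth filter applied forward-backward (zero phase, flat
passband), its variance over the whole trial taken as the Gaussian σ²,
and h = ½ ln(2πeσ²) reported in nats (natural log keeps the closed form
clean). One value per trial/channel/band, because the classifier
consumes exactly one feature row per trial. A zero-variance channel
yields h = −∞, flagged degenerate; `extract_features` rejects the trial
and names the offending channels rather than silently propagating
−∞ into the feature table.

Feature columns are ordered channel-major, then band
(c1_theta … cN_gamma); 62 channels × 4 bands = 248 features.

## Normalization

Let x_ijk be feature k of trial j in stratum i, where a stratum is one
(participant, session) pair.

*Batch (baseline)*: per-feature min-max over all training rows, then,
inside the network, per-feature standardization with mean and
**population** (1/N) variance of the whole batch,
x̂ = (x − μ_k)/√(σ²_k + ε). No learnable scale/shift follows — the
usual fourth batch-normalization step is deliberately omitted, as it
hurts this task. At inference the training-batch statistics are frozen;
min-max values outside the fitted range are clamped to [0, 1]
(fitting min/max on training rows only is the conservative reading and
avoids leakage).

*Stratified*: the same two transforms with all statistics per stratum.
Per-stratum statistics are always recomputed from the rows of the
current pass: training-batch strata during training, the held-out
participant's own rows at inference. This is transductive within the
participant (all trials of a test stratum are normalized together) but
label-free — stratum identity is recording metadata. Exactness: a
per-stratum map x → a·x + b with a > 0 leaves the stratified min-max
output mathematically unchanged and the mean-variance output unchanged
up to the ε term; this is the mechanism by which inter-participant
variability is removed.

ε defaults to 1e-5, placed under the square root with σ². Constant
stratum-columns map to 0 in both transforms (avoids NaN,
deterministic). Note the ε-invariance caveat: the mean-variance
transform's affine invariance degrades as σ² approaches ε (relative
error ≈ ε/2σ²), so near-constant features are only approximately
nuisance-free.

## Classifier

Architecture: dense(n_features→64) → ReLU → normalization → dropout,
dense(64→64) → ReLU → normalization → dropout,
dense(64→64) → ReLU → normalization,
dense(64→n_classes) → log-softmax. The ordering
dense→ReLU→norm→dropout makes "activations after normalization"
well-defined probe targets and keeps dropout from distorting the
normalization statistics. Dropout rate 0.25 on the first two hidden
layers only, active only in training. The output layer has n_classes
units (2 for the binary task): a softmax head with a permanently unused
third class would make the likelihood pathological.

Training: one full batch, negative log-likelihood, Adam
(β₁ = 0.9, β₂ = 0.999, eps = 1e-8), 100 epochs, learning rate 0.005 for
epochs 1–40 and 0.001 thereafter. Initialization is fan-in-scaled
uniform, deterministic given the seed. After the last epoch, batch-mode
statistics are collected in one dropout-free pass over the training
batch and frozen for inference.

The network is implemented directly in NumPy. The one non-textbook
gradient is the one through the normalization statistics: for a group R
of m rows with y = (a − μ_R)/√(σ²_R + ε),

    ∂L/∂a = (g − mean_R(g) − y ⊙ mean_R(g ⊙ y)) / √(σ²_R + ε),

per feature column — the standard batch-norm backward without the
affine step, applied per stratum group in stratified mode. The backward
pass is verified against central finite differences in the test suite.

Numerical notes: log-softmax is computed with max-subtraction;
prediction ties break to the lowest class index; training aborts with a
diagnostic on a non-finite loss. Training and evaluation are bitwise
deterministic given (seed, input); per-fold seeds in cross-validation
are derived as base_seed + fold_index.

## Evaluation

**LOPO.** One fold per participant: train on all others, test on the
held-out participant. A fold whose training rows lack a class is an
error, not a silent skip. Results: per-participant accuracies, their
mean and sample (n−1) SD, and a pooled confusion matrix (display order
positive/neutral/negative) from which pooled accuracy, per-true-class
recalls and per-predicted-class precisions are derived. The binary task
drops neutral trials. Cross-task agreement between two accuracy vectors
uses the Pearson product-moment correlation.

**Layer probing.** Participants are split by seed into three disjoint
test groups; each fold trains the classifier on the other two thirds
and records activations for the pooled test rows at the five probe
points (normalized input, h1–h3 after normalization, softmax output).
Per layer and task (emotion labels; participant identities) an RBF-SVM
(C = 1, gamma = "scale", features standardized per layer) is scored by
stratified 5-fold cross-validation over the test rows only — training
rows never reach a probe. Chance is reported both as the uniform 1/n
baseline and the majority-class share. Accuracy above chance on the
participant-ID task measures how much individual signature a layer
retains.

## Synthetic data

The generator makes the method's premise explicit: a modest emotion
effect carried by a subset of channel-band features, masked by a much
larger per-stratum affine nuisance.

Feature-level: x_ijk = a_ik·(base_k + effect_jk + noise_ijk) + b_ik,
with gains a_ik log-uniform in `participant_gain_range`, offsets b_ik
Gaussian with SD `participant_offset_sd`, both constant within a
stratum. `emotion_effect` is the standardized mean shift per adjacent
class (class codes −1/0/+1 around neutral) on the affected columns,
whose signs are random. Defaults: effect 1.0, affected fraction 0.25,
gains (0.5, 2), offset SD 2.0, noise SD 1.0 — nuisance dominating
signal, the regime the method targets. Labels are balanced within every
session. The full-size preset mirrors the 15 × 3 × 15, 62-channel
reference layout; the mini preset (6 × 2 × 6, 8 channels, fs = 128 Hz,
5 s trials) keeps end-to-end runs under a few seconds and is the size
used by the test suite and the acceptance script.

Signal-level: each trial channel is a sum over the four bands of
band-limited Gaussian noise (white noise through the zero-phase
band-pass, rescaled to unit variance, then scaled to the target band
variance). Planted log-variances follow base + emotion shift + small
trial jitter; since a signal's power cannot be offset additively,
`emotion_effect` acts here as a log-variance shift per class step
(variance ratio e^effect between adjacent classes), and the per-stratum
nuisance maps to a per-channel gain, a DC offset, and a spectral tilt
(log-variance slope across bands). Feature extraction approximately
recovers the planted structure; recovery tests use spectral settings
fine enough to resolve the narrow bands.

What the generator does *not* emulate: volume conduction and channel
correlation, artifacts (blinks, muscle), non-stationarity within
trials, non-affine inter-participant differences, and any realistic
scalp topography. Passing tests therefore demonstrate that the
pipeline behaves as designed when the nuisance is affine per stratum —
the structure the method can provably remove — not that comparable
accuracy will be reached on real recordings, where part of the
inter-participant variability is nonlinear.

## Published benchmark tables

`stratnorm.benchmarks` ships the published LOPO results of this method
on the SEED corpus (per-participant accuracies for both labelings and
the two pooled confusion matrices). They serve as inputs for
summary-arithmetic regression checks — the corpus itself is
access-restricted and is not required by any part of the package.

## Known limitations

- Stratified inference needs all trials of a test stratum at once
  (≥ 2 rows per stratum); single-trial streaming inference is out of
  scope.
- The HDF5 container is this package's own layout; vendor formats
  (.mat, EDF/BDF) must be converted externally.
- Probe accuracies from small test groups carry the usual
  small-sample cross-validation pessimism: on signal-free data CV
  accuracy falls slightly *below* chance, so leakage checks are
  one-sided (no layer may exceed chance by more than sampling error).
- The Welch default window (0.5 s) trades frequency resolution for
  stationarity robustness; narrow-band effects are partially smeared
  across adjacent bands.
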