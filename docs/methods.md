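# Methods

`neurochoice` implements a multimodal pipeline that predicts a binary
consumer choice (buy vs. no-buy) per viewed product from simultaneously
recorded EEG (19 channels, 300 Hz, microvolts) and screen-coordinate eye
tracking (120 Hz). This note documents the models and procedures, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Signal model and preprocessing

**EEG.** Recordings are band-passed 0.5–45 Hz with an order-4 Butterworth
filter applied forward–backward (zero phase; effective order 8 in
magnitude). Artifact Subspace Reconstruction (ASR) then learns a clean-data
subspace: the quietest `asr_calibration_fraction` (default 0.25) of 0.5-s
sliding windows, ranked by RMS, calibrate a PCA basis (eigenvalue floor
`1e-12·trace` against rank deficiency), and each principal component gets a
rejection threshold mean + `asr_cutoff`·SD (default 20, the conservative
standard) of its calibration RMS. At application time each Hann-tapered
sliding window is projected, components exceeding their thresholds are
zeroed, and windows are overlap-added (hop = window/2, so the periodic Hann
tapers sum exactly to one; the signal is reflect-padded so edges are
reconstructed exactly). With thresholds at infinity the operation is the
identity to float precision.

ASR runs on the continuous recording, then trials are cut into 1-s windows
(300 samples) with 50 % overlap, and each window is cleaned by a simplified
wavelet stage in the spirit of the FORCe family: per channel, a `db4`
decomposition to level 4; at each detail level coefficients are **clipped**
to λ = k·median(|d|)/0.6745 with k = 3 (a ~3σ̂ robust threshold); channels
whose approximation-band energy exceeds k× the across-channel median have
their approximation zeroed (slow, high-amplitude transients such as blink
residue). Clipping, rather than soft shrinkage, is what makes the stage an
artifact *limiter*: a transient whose coefficients dwarf the noise scale is
flattened to the threshold, while coefficients at or below the typical scale
— i.e. the ongoing rhythms — pass unchanged. Soft shrinkage by the same λ
(available as an option) only subtracts λ from every coefficient and cannot
meaningfully reduce a large spike. Measured on 10 µV alpha + unit noise with
a 500 µV single-sample spike, clipping removes ≈ 90 % of the spike while
clean channels correlate > 0.999 with their input. No notch filter, channel
interpolation or re-referencing is applied; the full published FORCe (which
adds an ICA stage) is out of scope.

**Eye tracking.** Invalid runs (blinks) shorter than `max_gap_interp`
(default 300 ms, a typical blink; `None` removes the cap) are filled by the
straight line between the bracketing valid samples, separately in x and y;
edge runs are filled by nearest-valid hold; longer runs stay invalid.
Trials are cut into 1-s windows of 120 samples, 50 % overlap. Each window is
rasterized onto a 64×64 black canvas: pixel (⌊x/W·64⌋, ⌊y/H·64⌋), clipped to
the canvas, is set to 255 — binary and idempotent; an accumulate mode
(min–max-scaled visit counts) exists for experimentation. Fixations are
detected with the dispersion algorithm (I-DT): a sample window grows while
(max−min x) + (max−min y) ≤ 50 px and is emitted if it lasts ≥ 100 ms.
Gaze plots are built per 1-s window (not per trial) so EEG and ET window
counts align one-to-one by (trial, ordinal); per-trial pairs are truncated
to the shorter modality.

## Features

**Handcrafted (per EEG channel, per window).** Mean, population variance
(divisor N), bias-corrected skewness and excess kurtosis — the
standardization inside the skew/kurtosis uses the sample SD (divisor N−1),
so the moment set deliberately mixes conventions; with the sample SD these
forms reduce exactly to the adjusted Fisher–Pearson G1/G2 estimators, which
is how they are cross-checked. Welch band powers: Hann segments of 150
samples, 50 % overlap (3 segments per window; 2 Hz resolution — sub-Hz
resolution is impossible in a 1-s window), averaged periodograms, mean PSD
over δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz with half-open band edges
so boundary bins are counted once. DWT mean and SD of the coefficients at
each of 4 `db4` detail levels plus the final approximation. Total handcrafted
EEG width: 19·(4+5+10) = 361. ET features per window: mean fixation
duration, fixation count, mean saccade amplitude (Euclidean distance between
consecutive fixation centroids) and saccade count (width 4); empty results
are zeros with a degeneracy flag.

**Deep.** Two supervised extractors trained on the window label through a
1-unit sigmoid head, implemented in a small deterministic NumPy engine
(valid stride-1 convolution, 2×2 floor-mode max pooling, LSTM, dense layers;
reverse-mode gradients checked against finite differences; Adam with
bias-corrected moments; float32 throughout).

* EEG: Conv2D 32@3×3 → pool → Conv2D 64@3×3 → pool → flatten (14,016) →
  reshape to a 14,016-step sequence of scalars → LSTM(64) → dense 128 → 64.
  Trained with MSE-on-sigmoid (binary cross-entropy is a config switch).
  The scalar-sequence LSTM is kept exactly as the architecture table
  prescribes even though it is computationally eccentric. The standard LSTM
  parameter count for this cell is 4·64·(1+64+1) = 16,896.
* Gaze plots: LeNet-5 — Conv2D 6@5×5 → pool → Conv2D 16@5×5 → pool →
  flatten (2,704) → dense 120 → 84, trained with binary cross-entropy. A
  1-channel 64×64 input gives conv1 156 parameters.

Features are the activations of either the convolutional `flatten`
(14,016 + 2,704 → the 16,720-dim fused deep vector) or the `last_dense`
layer (64 + 84). The pipeline default is `last_dense`: at 16,720 columns a
single gradient-boosting fit costs minutes, making repeated stacked
cross-validation fits impractical on one CPU, while the dense features are
the same trained representation at ensemble-friendly width. The flatten
width itself is always constructed and asserted.

Default extractor budgets (epochs: CNN-LSTM 1, LeNet-5 10; training
subsample caps 96 / 192 windows) are desk-scale choices that keep an
end-to-end cross-validated run in minutes; they are configuration, not
architecture — raise them for longer training.

## Fusion, balancing, classification

Feature blocks concatenate column-wise in the fixed order EEG-deep, ET-deep,
EEG-hand, ET-hand, restricted by mode (`deep_only`, `hand_only`, `full`) and
modality (`both`, `eeg`, `et`). SMOTE (k = 3 neighbours, random state 42)
oversamples the minority class in the fused feature space: each synthetic
point is x + u·(neighbor − x), u ~ U[0,1], for a random minority sample and
one of its 3 nearest minority neighbours, until classes balance. It runs on
the training portion of each CV fold by default; a `global` scope applies it
once to the whole matrix (leakage-prone, provided for comparability).
Operating on fused features rather than raw windows is a deliberate choice:
interpolating mixed raw modalities (images + multichannel time series) is
ill-defined.

The classifier is a two-level stack: Random Forest (265 trees), Gradient
Boosting (89 stages) and XGBoost (300 rounds) as base learners — other
hyperparameters at library defaults — whose out-of-fold predictions
(stratified, shuffled, seeded; 5 internal folds by default, the usual
stacking convention) form a 3-column meta matrix Z; a 100-tree Random
Forest meta-learner is fitted on Z, and the bases are refitted on all
training data. Meta features default to positive-class probabilities; hard
labels are a config switch. Evaluation is outer stratified 10-fold CV
(shuffle, seed 42), with SMOTE and all classifier fitting confined to each
fold's training portion.

**Leakage control for the deep extractors.** Because the extractors are
*supervised*, where they train matters. Three scopes are provided:
`fold` (the default) retrains them inside every CV fold on that fold's
training windows — leakage-free but 10× the training cost; `holdout` trains
them once on a dedicated trial partition (default 25 % of each subject's
trials, proportional per class, seeded) that is then excluded from the CV
evaluation — leakage-free at one training; `global` trains once on
everything, which lets a memorizing extractor encode evaluated labels in
its features. This is not hypothetical: on a null dataset (no class signal)
the globally trained LeNet-5's dense features alone support perfect
"classification" of its own training labels, while every other feature
block sits at chance. Relatedly, *window-level* CV leaks through the 50 %
window overlap (adjacent windows of a trial share half their samples), so
a `group_by="trial"` option keeps whole trials in one fold, and
`group_by="subject"` additionally keeps subjects whole (recommended for
subject-level claims when subjects are many). The package's own end-to-end
evaluations use `holdout` + trial grouping; the `fold` scope is exercised
in tests at small scale.

Metrics: confusion counts with buy as positive class, accuracy, precision,
recall, specificity, F1, exact empirical ROC over all unique score
thresholds, trapezoidal AUC. Reports carry a config hash and are
byte-identical across reruns with the same config and seeds.

## Synthetic data

The generator emulates the statistical skeleton the pipeline assumes, not
the biophysics. EEG trials are sums of band-limited Gaussian noise with
resting-like RMS weights (δ 8, θ 5, α 6, β 3, γ 1.5 µV — a 1/f-ish decay);
buy trials scale the alpha *amplitude* by `alpha_power_ratio`. Gaze trials
alternate fixations (lognormal durations, mean 250 ms + class shift, 2 px
jitter) with ~30 ms ballistic saccades (amplitude ~N(150 px + class shift,
40)). Blinks (Poisson, 15/min by default) produce simultaneous invalid gaze
runs (250 ms) and smooth 120 µV frontal EEG bumps (350 ms) — a cross-modal
artifact for ASR/wavelet cleaning to remove; 50 Hz line noise and 20–45 Hz
temporal-channel muscle bursts are added to the EEG. Labels are assigned
per subject by exact count, round(buy_fraction·trials) clipped so both
classes always occur. Everything is deterministic under the config seed.

The class effects sit exactly where the handcrafted features look (alpha
band power; fixation duration/saccade amplitude), which makes
handcrafted-only ablations meaningful but also means a passing pipeline
demonstrates *recoverability of injected effects*, not performance on real
recordings: real EEG/ET effect sizes, non-stationarity, cross-subject
variability and electrode artifacts are not modelled, and published
accuracies on real data cannot be reproduced from synthetic data. Default
acceptance conditions: strong effect = alpha ratio 0.5 with +200 ms
fixation shift; null = no class effect; each dataset is 10 subjects × 14
balanced 2.5-s trials (4 aligned windows per trial), of which 4 trials per
subject feed the extractor holdout and 10 are evaluated — 400 evaluated
windows under trial-grouped CV (10-fold for the strong effect, 5-fold for
the null and the ablations). Measured under those conditions the full
pipeline reaches ≥ 0.75 CV accuracy on the strong effect and chance
(0.40–0.60) on the null; the ablation grid (EEG-only, ET-only vs. the full
multimodal run) is computed by the acceptance script at the same problem
sizes.

## Numerical and degenerate-input conventions

Sample ranges are 0-based half-open. Constant signals report skew/kurtosis
0 with a flag; empty fixation lists report zero features with a flag; trials
shorter than one window yield zero windows with a warning; perfectly
correlated channels are handled by the ASR eigenvalue floor. Windowing is a
pure view (concatenating non-overlapping halves of adjacent windows
reconstructs the trial exactly). CSV round-trips are bit-exact (`%.17g`
writing, round-trip float parsing). All randomness flows from explicit
seeds; two runs with identical configs produce identical fold assignments,
SMOTE outputs and metric JSON.

## Known limitations

The 21→19 channel selection of the original acquisition is unknown; the
package simply operates on 19 channels. Trial delimitation on disk is a
package convention (the source corpus' container format is out of scope).
The wavelet stage is FORCe-*style*, not the published FORCe. Pupil
dilation, mouse and questionnaire streams are not modelled or used.
Window-level CV (the default) overstates subject-level generalisation when
windows of one trial share folds; use the grouped-CV option for
subject-level claims.
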