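# Methods

## Problem

`erpmask` decodes, from single epoched EEG trials, whether a face stimulus in
a concealed-information (CTP) paradigm was the participant's own face (probe,
positive class) or a stranger's face (irrelevant, negative class).  The
stimulus classes differ electrophysiologically: probes elicit a parietal
P300-like positivity around 300–500 ms, irrelevant faces an N200-like
negativity around 180–250 ms, and the paradigm presents them at a 1:4 ratio.
Training and evaluation are cross-subject: test participants are never seen
during training.

## Model

An epoch is a matrix `S ∈ R^{C×T}` (channels × time, microvolts).  The model
maintains a bank of `K` one-dimensional kernels of base length `l`, randomly
initialized from a zero-mean Gaussian (sd `1/sqrt(l)` by default), and chooses
an *effective* length for every kernel, on every input, as follows:

1. **Feature convolution.** Each of `K` width-3 filters is slid along time over
   every channel with same-padding, giving maps `E ∈ R^{K×C×T}`.
2. **Channel pooling.** Global average pooling over the channel dimension gives
   `E' ∈ R^{K×1×T}`.
3. **Segment extraction.** The slice `L = E'[:, :, P:P+l]` is taken; `P` is
   chosen so the window covers the component-bearing part of the epoch.
4. **Ratio generation.** Per scale `i`, `L_i` is concatenated with the kernel
   `W_i` and pushed through a shared pair of fully connected layers
   (`2l → l → 1`, no hidden nonlinearity) and a sigmoid, giving a ratio
   `r_i ∈ (0, 1)` and an ideal length `l_i = r_i · l`.
5. **Soft mask.** `m_ij = σ(λ (l_i − j))` for `j = 1..l`.  The sharpness `λ`
   controls how closely this approximates a hard 0–1 cutoff; at `λ = 10³` the
   masked convolution is numerically indistinguishable (≤1e−5 relative) from
   convolving with the hard-truncated kernel.  Because the mask is a smooth
   function of `l_i`, the length decision remains trainable by gradient
   descent.
6. **Depthwise convolution.** The masked kernels `W ⊙ M` are applied
   independently to every channel of the end-zero-padded epoch (valid
   correlation, cropped to `T` samples), keeping per-(scale, channel) maps:
   `D ∈ R^{K×C×T}`.  No cross-channel mixing or pointwise convolution follows.
7. **Head.** Per-scale batch normalization, inverted dropout (rate 0.5), a
   flatten, and a single linear unit produce the logit.

The **standard** variant fixes every mask at 1 (full-length kernels, the
generator path inactive) and is otherwise identical; it is the ablation
baseline.

Masks, ratios and lengths are recomputed per input sample; the kernels and all
fully connected weights are shared.  Mask indices `j` are 1-based, matching
the formula above; all time slices are 0-based half-open.

### Resolved ambiguities

* The depthwise convolution keeps per-(scale, channel) maps rather than
  summing over channels, preserving the stated `K×C×T` feature shape; the
  classifier consumes the full flatten.
* The mask-generator input is sliced from the pooled features `E'`, whose
  dimensions are the only ones compatible with `L ∈ R^{K×1×l}`.
* The base kernels are trainable by default (a flag can freeze them); the
  generator's fully connected pair is shared across scales.
* Valid convolution of the padded epoch yields `T+1` samples; the output is
  cropped to the first `T`.
* Batch normalization precedes dropout; running statistics (momentum 0.1)
  make evaluation deterministic.

### Numerical notes

* The logistic function saturates in float64 once `|λ(l_i − j)| ≳ 36`; the
  mathematical strict monotonicity and open bounds of mask rows hold exactly
  only inside that range.  Tests of those properties confine themselves to it.
* As `r → 1` the mask's final entry tends to `σ(0) = 0.5`, so the masked model
  converges to the full-length model only up to a half-weighted final tap;
  the continuity check therefore uses kernels whose final tap is zero.
* Training runs in float32 with float64 accumulators for batch statistics;
  gradient checks run the same code path in float64.
* Under batch-statistics normalization the loss is exactly invariant to the
  per-scale convolution bias, so that bias's gradient is numerically zero.

## Training

Class-weighted binary cross-entropy on logits (positive-class weight 4, the
paradigm's inverse class frequency), optimized with adaptive moment estimation
and decoupled weight decay (learning rate 1e−5, weight decay 1e−4; plain SGD
available).  Batch size 32, dropout 0.5, prediction threshold 0.5 with ties
classified positive, default 100 epochs.  No early stopping is performed; the
per-epoch loss history is returned for external use.  Fits are deterministic
given the seed, which drives initialization, batch shuffling and dropout.

The backward pass is derived by hand and validated against central finite
differences on coordinates from every parameter group (agreement ≤1e−4
relative).  The expensive depthwise convolution with per-sample kernels runs
through real FFTs with per-dataset cached epoch spectra; the
normalization/dropout/linear head runs through fused numba kernels.  A slow,
transparent per-sample reference implementation of every stage exists
alongside and the test suite asserts the two paths agree.

## Evaluation protocol

The unit of data division is the participant: `split_by_subject` holds out
`max(1, round(n_subjects · (1 − train_fraction)))` whole subjects per fold
(default train fraction 0.9), with disjoint test sets across folds drawn from
a seed-shuffled subject order.  Reported metrics are balanced accuracy
(mean of TPR and TNR), F1, TPR, TNR, FPR, precision and the midrank
Mann–Whitney AUC.  Ratios with zero denominators are reported as undefined
(nan) with a warning, never silently as zero, so degenerate folds cannot
inflate aggregates.

Condition differences in ERP waveforms are located by a pointwise paired
two-sided t-test across subjects with no multiplicity correction; maximal runs
of consecutively significant samples (p < 0.05) are returned as half-open
windows.  Zero within-pair-variance points are undefined and non-significant.

## Synthetic data

The study's 118-participant dataset is not public, so experiments run on a
simulator of the paradigm.  Per subject, one latency and one amplitude are
drawn per component (P300: 400 ± 20 ms within 300–500 ms, +5 ± 1 µV; N200:
211 ± 8 ms within 180–250 ms, −3 ± 0.6 µV), the component is a half-period
raised-cosine bump compactly supported inside its window with the peak snapped
to the sample grid, scaled across channels by a Gaussian scalp topography
peaking (gain 1) at a designated Pz-like channel, and added to Gaussian noise
(optionally 1/f-shaped; white by default).  Probe and irrelevant trials are
generated at 1:4 per subject (12 vs. 48 of 60 by default).

The default noise level, 3 µV, represents epochs *after* across-block
averaging — roughly 10 µV of single-trial background averaged over ~10 block
repetitions — matching how the paradigm's data are prepared; the
`average_blocks` operation reproduces that averaging for raw simulated trials.

What the simulator deliberately omits: real electrode geometry and volume
conduction (the topography is a 1-D gain profile), trial-to-trial latency
jitter within a subject, non-stationary and non-Gaussian artifacts, late
(600–1000 ms) memory-related components, and the numeric target/non-target
stimulus stream of the full paradigm.  Passing tests therefore demonstrate
that the architecture, losses and protocol work as specified and can recover
planted class structure across subjects — not that the headline accuracies on
the real dataset are reproduced.

## Problem sizes

Library defaults follow the study scale: 1000 Hz sampling, 0–1000 ms epochs
(T = 1000), kernel length 200 samples, mask window start 400, K = 30 scales,
30 channels.  The package's own evaluation experiments (the acceptance tests
and `scripts/acceptance.py`) run the identical protocol at 250 Hz sampling —
T = 250, kernel length 50 samples (= 200 ms), window start 75 (= 300 ms) —
with 10 subjects × 60 trials, K = 10, 50 training epochs, and one 9:1
subject-disjoint split per seed.  Since the paradigm's signals are low-passed
at 30 Hz, 250 Hz sampling is lossless for the signal content, and every
condition is preserved in physical units.  The window-position sweep trains
12 epochs per cell.

## Known limitations

* Single-trial decoding of *raw* (non-averaged) EEG is harder than the
  simulated post-averaging regime; expect lower accuracies there.
* The mask-generator's benefit over the standard variant should not be
  expected on easily separable data: with the study's small learning rate the
  generator stays close to initialization, so mask ratios fluctuate with the
  input noise and add multiplicative kernel noise that a clean task cannot
  reward.  The paired masked-vs-standard comparison (reported by
  `scripts/acceptance.py` and asserted directionally in the test suite) can
  come out at or below zero on the simulator even though the architecture is
  implemented and differentiable exactly as specified.
* Batch-norm running statistics are stored as biased variances; checkpoints
  are not interchangeable with frameworks storing unbiased ones.
* The EEGLAB `.set` importer is best-effort and requires `mne`.
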