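# Methods

## Problem and model

Tear-film break-up time (TBUT) is measured per *subtest*: one open-eye
interval between two blinks, with t = 0 at the first stable open-eye frame.
The pipeline reduces TBUT estimation to per-frame binary classification
(breakup vs non-breakup) followed by deterministic temporal post-processing.

### Dual-task Siamese network

Frame pairs (x₁, x₂) from a single subtest pass through two weight-shared
encoder branches producing embeddings (z₁, z₂) and, via a linear + sigmoid
head on each embedding, breakup probabilities (p₁, p₂). The objective is

    L_total = w₁ · (L_b1 + L_b2) + w₂ · L_c

where L_b is the mean binary cross-entropy of one branch and the contrastive
term is

    L_c = mean[ (1 − Y) · ‖z₁ − z₂‖² + Y · max(margin − ‖z₁ − z₂‖, 0)² ]

with pair label Y = 1 iff the two frames belong to different classes. Note
the asymmetry, implemented exactly as stated: the similar term squares the
distance, the dissimilar term squares the hinge of the *unsquared* distance.
Defaults: w₁ = 0.9, w₂ = 0.1, margin = 0.01. The change-detection task is a
regularizer — it forces the shared encoder to represent the visual change
that defines breakup onset — while a single branch is the classifier used at
validation and inference time.

With unnormalized embeddings and margin 0.01, the dissimilar hinge is active
only while dissimilar embeddings are nearly coincident (early training);
afterwards the contrastive gradient comes almost entirely from the
similar-pair attraction. Embedding normalization is deliberately not applied
(the loss is defined on raw Euclidean distance); margin and the task weights
are configuration.

### Architecture

The shipped backbone (`tiny-cnn`) is a compact encoder suited to the
synthetic data and CPU training: three 3×3 convolution + ReLU blocks
(8, 16, 32 channels) with 2×2 max pooling after the first two, global
average pooling, batch normalization of the 32 pooled features, and a linear
projection to the embedding (default dimension 32). The classifier head is a
single linear layer + sigmoid on the embedding — the minimal head consistent
with using one branch as a classifier. The batch-norm stage matters
operationally: pooled activations of this encoder have a dynamic range of
~10⁻², and without normalization the sigmoid head cannot reach calibrated
probabilities within short schedules at learning rate 10⁻⁴ (rankings become
perfect long before probabilities cross 0.5, which would break the
threshold-based TBUT rule). Inference always uses batch-norm running
statistics, so per-frame outputs are deterministic and independent of batch
composition.

The layer stack, backpropagation and the Adam/StepLR optimizers are
implemented in-package on numpy (`tbut._nn`); analytic gradients are
verified against central finite differences in the test suite. Named
pretrained backbone families are not bundled — they require a GPU deep
learning runtime and weight downloads — so `ModelConfig` rejects them with
an explicit error rather than silently substituting.

### Training protocol

Adam at learning rate 10⁻⁴, StepLR decay (step 10 epochs, γ = 0.5 — the
schedule parameters are free choices exposed in config), batch size 32,
40 epochs by default. Cross-validation is five-fold at the video (patient)
level so no patient's frames leak across folds; folds are stratified to keep
each fold's breakup:non-breakup frame ratio within a tolerance (default 5
percentage points) of the global ratio, via greedy largest-first assignment
plus pairwise swap refinement. Per fold, the checkpoint with the best
validation frame AUC is kept; AUC ties are broken toward the *later* epoch,
because on separable data the AUC saturates almost immediately while
probability calibration keeps improving — the later model is the better
classifier at a fixed 0.5 threshold. Test-time prediction averages the
probabilities of the fold models (arithmetic mean).

Pairs are sampled per training video with equal counts of similar and
dissimilar pairs, both members from the same subtest, frame gap uniform on
[1, max_gap_frames] (default 60 ≈ 1 s at 60 fps), with replacement;
`unknown` and `blinking` frames never enter pairs but all frames are scored
at validation (non-binary labels are excluded from the AUC). A
RandAugment-style augmentation policy (2 ops at magnitude 9: rotation,
translation, brightness/contrast/sharpness) is available and seeded; it is
off by default since the synthetic frames need no invariance training.

### From probabilities to seconds

Per subtest, raw probabilities are smoothed by discrete convolution with a
normalized Gaussian kernel, σ = 5 *frames*, truncated at 4σ, reflect
boundary. σ is per-frame rather than per-second: the frame-rate sweep reuses
σ = 5 at every rate, i.e. the method is held fixed while the data rate
changes. The TBUT is i*/fps where i* is the smallest index with smoothed
probability ≥ 0.5 (≥, not >); with no crossing the fallback reports
(L − 1)/fps, the 0-based last frame's time. Frame indices are 0-based at the
first open-eye frame, so t = 0 is eye opening; the alternative 1-based
convention differs by one frame (≤ 17 ms at 60 fps) and is immaterial, but
the 0-based choice is fixed so tests can be exact. An eye's TBUT is the mean
over its subtests.

## Synthetic data

The simulator emulates the *classifiable* property of fluorescein imaging —
dark rupture spots on a bright disc — not its photometric realism. Each
subtest: optional leading blink frames (eyelid sweeping open), an open span
of `open_duration_s` seconds, trailing blink frames. An onset time is drawn
from `onset_time_s`; from onset, 1–4 circular spots of base radius 2 px grow
at `spot_growth_px_per_s`, darkening with radius. Onsets beyond the open
span yield subtests with no breakup (truth: none). Labels follow the
grammar non-breakup* unknown* breakup* inside the open span; the `unknown`
ambiguity band is a symmetric ±`unknown_band_s` window around onset
(default 0.1 s — the duration of real annotator ambiguity is not known, so
it is a configurable guess). Pixel noise is additive Gaussian. Everything is
driven by per-subtest RNG streams spawned from one seed, so videos are
bit-reproducible.

Defaults: 128 px frames (64 px in the in-repo experiments; the clinical
1080 px is supported via config), 60 fps, 3 subtests per eye, open spans of
4–8 s, onsets 0.5–10 s (so some subtests never break up), blink sequences of
0.1–0.4 s.

What passing tests on this simulator does and does not show: it validates
the pipeline's machinery — pair construction, optimization, weight sharing,
smoothing/threshold arithmetic, evaluation — and that the network can
recover a known onset from images whose discriminative feature resembles the
clinical one. It does not establish clinical performance: real videos have
specular reflections, eyelashes, uneven illumination, drifting gaze,
residual dye artifacts after blinks (a documented failure mode of
threshold-based estimation), and annotator disagreement, none of which are
modeled.

## Experiment sizes

The in-repo experiments are deliberately desk-scale: 10 videos (7 train /
3 held out), 2 000 training pairs, 10 epochs for the parameter-recovery
experiment; 8 videos, 4 epochs, and a pair budget proportional to the
surviving frame count for the frame-rate sweep (so lower rates train on
proportionally less data, matching a rate change applied to development and
testing alike). The protocol-scale defaults (3 000 pairs per video, 40
epochs, 5 folds) remain the configuration defaults.

## Numerical choices and degenerate inputs

- Probabilities are clamped to [10⁻⁷, 1 − 10⁻⁷] inside the cross-entropy.
- The dissimilar contrastive gradient at exactly zero distance is taken as 0
  (subgradient choice; the loss there is the flat maximum margin²).
- Network arithmetic is float32; losses and metrics are accumulated in
  float64.
- ROC-AUC uses the Mann–Whitney convention (ties count ½) via
  scikit-learn and is verified against an O(n²) pair-counting oracle; AUC on
  single-class inputs raises. Pearson r on zero-variance inputs raises from
  the metric function; the batch evaluator records NaN for that report field
  instead of failing.
- The TBUT error is signed (estimate − truth); its sd uses the n − 1
  denominator. For subtests whose truth is "no breakup", the truth-side
  value for error/correlation purposes is the same last-frame fallback the
  estimator uses, keeping both scales comparable.
- Error densities use 0.5 s bins over [−12, 12] s for any two methods being
  compared, binned identically.
- `resample_frame_rate` accepts only integer divisors of the native rate and
  keeps every k-th frame from index 0; labels and the true TBUT carry over.
- Degenerate simulator draws (onset inside the leading ambiguity band) are
  re-sampled internally.

## Known limitations

- The compact backbone is sized for the simulator; clinical-resolution
  transfer would need a pretrained backbone, which this package deliberately
  does not bundle.
- Subtest extraction (blink segmentation) is the caller's responsibility;
  the annotation schema carries subtest membership.
- The simulator's spots are stationary disks with linear growth; it cannot
  probe robustness to spot morphology, drift, or illumination changes.
- Fold stratification is heuristic (greedy + swaps); it enforces the ratio
  tolerance rather than finding an optimal partition.
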