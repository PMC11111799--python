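# tbut — automated tear-film break-up time estimation

Tear-film break-up time (TBUT) is the standard clinical test for evaporative
dry eye disease: after fluorescein instillation, the seconds from full eye
opening until the first dark rupture spot appears in the stained tear film.
A TBUT above 10 s is considered normal; below 5 s indicates severe dry eye.
Manual TBUT readings are notoriously irreproducible, which motivates
automating them from slit-lamp video.

`tbut` implements an automated TBUT pipeline for slit-lamp videos, aimed at
researchers in ocular-surface imaging:

1. **Dual-task Siamese network (DTSN).** Two weight-shared convolutional
   branches embed a pair of frames (x₁, x₂) from one open-eye interval into
   vectors (z₁, z₂). Each embedding feeds a linear + sigmoid head producing a
   per-frame breakup probability p (the classification task); the Euclidean
   distance ‖z₁ − z₂‖ drives a contrastive change-detection objective. The
   training loss is

   L_total = w₁·(L_b1 + L_b2) + w₂·L_c,

   with L_b the binary cross-entropy of each branch,
   L_c = mean[(1 − Y)·‖z₁ − z₂‖² + Y·max(margin − ‖z₁ − z₂‖, 0)²] over pairs
   (Y = 0 similar, Y = 1 dissimilar), and defaults w₁ = 0.9, w₂ = 0.1,
   margin = 0.01. Training follows Adam at lr 10⁻⁴ with step-decay, batch 32,
   five-fold cross-validation at the patient level; at inference a single
   branch classifies frames and the fold models are averaged.
2. **TBUT estimation.** Per-frame probabilities of one subtest (an open-eye
   interval between blinks) are smoothed with a Gaussian filter (σ = 5
   frames), and the TBUT is the first frame whose smoothed probability
   reaches 0.5, divided by the frame rate; if no frame reaches it, the last
   frame's time is reported. Three subtests per eye are averaged.
3. **Synthetic data.** Because clinical TBUT recordings are proprietary, the
   package ships a simulator that renders a bright corneal disc on which dark
   spots appear at a known onset and grow, complete with blink sequences and
   the four-class frame taxonomy (non-breakup / breakup / unknown /
   blinking). Every stage of the pipeline is tested against this exact ground
   truth.

## Worked example

```python
import numpy as np
from tbut import (SimConfig, generate_video, sample_pairs,
                  train_fold, TrainConfig, ModelConfig)
from tbut.tbut_estimation import predict_subtest
from tbut.evaluation import evaluate_videos

cfg = SimConfig(image_size=64, fps=60.0,
                open_duration_s=(4.0, 6.0), onset_time_s=(0.5, 3.5),
                spot_growth_px_per_s=8.0, spot_contrast=0.7, noise_sd=0.02)
rng = np.random.default_rng(0)
videos = [generate_video(cfg, rng, video_id=f"v{i:03d}") for i in range(6)]

train_recs = [r for v in videos[:4] for s in v.subtests for r in s.frames]
pairs = sample_pairs(train_recs, 1200, max_gap_frames=60, rng=rng)
held_out = videos[4:]
val_recs = [r for v in held_out for s in v.subtests for r in s.frames]
fold = train_fold(pairs, val_recs, ModelConfig(), TrainConfig(epochs=10, seed=0))

for sub in held_out[0].subtests:
    est, _ = predict_subtest([fold.model], sub.open_frames, sub.fps)
    print(f"true TBUT {sub.true_tbut_s:.2f} s  ->  estimated {est.tbut_s:.2f} s ({est.rule})")
report = evaluate_videos([fold.model], held_out)
print(f"held-out frame AUC {report.frame_auc:.3f}, Pearson r {report.pearson_r:.3f}, "
      f"mean error {report.mean_error_s:+.3f} +/- {report.sd_error_s:.3f} s")
```

Output:

```
true TBUT 2.82 s  ->  estimated 3.00 s (crossed-threshold)
true TBUT 1.84 s  ->  estimated 1.87 s (crossed-threshold)
true TBUT 2.44 s  ->  estimated 2.93 s (crossed-threshold)
held-out frame AUC 1.000, Pearson r 0.972, mean error +0.176 +/- 0.167 s
```

Each line compares the simulator's true break-up onset with the estimate the
trained network produced for that subtest; the summary line aggregates the
two held-out videos (six subtests): perfect frame ranking, a strong
correlation between estimated and true TBUT, and a small positive bias (the
classifier needs the spots to grow for a few frames before it is confident).

## Command line

The same pipeline is available as a CLI (`tbut --help`):

```bash
tbut simulate --out data/ --n-videos 10 --seed 1
tbut train    --annotations data/annotations.csv --out run/ --folds 5 --seed 1
tbut predict  --run run/ --annotations data/annotations.csv --out pred/ --seed 1
tbut evaluate --predictions pred/ --annotations data/annotations.csv \
              --truth data/ground_truth.json --out report.json --seed 1
```

File formats are documented in `FORMATS.md`; the model and training defaults
(Adam, lr 10⁻⁴, StepLR, batch 32, margin 0.01, 40 epochs, w₁ = 0.9,
w₂ = 0.1, σ = 5, threshold 0.5, 60 fps) can be overridden with a YAML file
passed as `--config`.

## Documentation

See `docs/methods.md` for the model assumptions, the simulator's scope and
limitations, parameter defaults with rationale, and numerical choices.
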