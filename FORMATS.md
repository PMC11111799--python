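# File formats

## Annotation CSV

One row per frame, header required:

```
video_id,eye,subtest_id,frame_index,label,image_ref
v000,R,s0,0,blinking,data/video_v000/eye_R/subtest_0/frame_000000.png
```

- `eye`: `L` or `R`.
- `frame_index`: 0-based position within the subtest (leading blink frames
  included; TBUT timing starts at the first non-blinking frame).
- `label`: one of `non-breakup`, `breakup`, `unknown`, `blinking`
  (case-insensitive on read, canonical on write).
- `image_ref`: path to the frame image; empty for label-only records.
- Duplicate `(video_id, eye, subtest_id, frame_index)` keys are rejected.

## Simulated video directory (`tbut simulate --out DIR`)

```
DIR/
  annotations.csv            # all videos combined
  ground_truth.json          # see below
  video_<id>/
    annotations.csv          # this video only
    ground_truth.json
    eye_<L|R>/subtest_<k>/frame_<%06d>.png   # 8-bit grayscale PNG
```

`ground_truth.json` (combined form):

```json
{"fps": 60.0,
 "videos": {"v000": {"eye": "R",
                     "true_tbut_s": [2.47, null, 1.40],
                     "open_frames": [300, 283, 293]}}}
```

`true_tbut_s` is per subtest, `null` when no breakup occurred while the eye
was open; `open_frames` counts open-eye frames per subtest.

## Training run directory (`tbut train --out RUN_DIR`)

```
RUN_DIR/
  fold_<k>.npz      # model weights + batch-norm statistics
  fold_<k>.json     # ModelConfig sidecar
  history.csv       # per-fold, per-epoch train loss and validation AUC
  summary.json      # fold AUCs, mean/sd, fold assignment of each video
  run.log
```

## Predictions (`tbut predict --out PRED_DIR`)

```
PRED_DIR/video_<id>/
  scores_<subtest_id>.csv    # frame_index, raw_p, smoothed_p
  estimates.json             # per-subtest {subtest_id, tbut_s, rule, crossing_index}
                             # plus eye_tbut_s (mean over subtests)
```

`rule` is `crossed-threshold` or `no-breakup-fallback`; `crossing_index` is
the 0-based frame of the first smoothed probability >= threshold (null for
the fallback).

## Evaluation report (`tbut evaluate --out report.json`)

```json
{"frame_auc": 0.98,
 "pearson_r_subtests": 0.97, "pearson_r_videos": 0.99,
 "mean_error_s": 0.12, "sd_error_s": 0.19, "mean_abs_error_s": 0.12,
 "n_subtests": 9, "n_frames": 2637}
```

Errors are signed (estimate − truth) in seconds; correlation is reported at
both subtest and video (mean of subtests) granularity.

## Run configuration (YAML, `--config`)

Top-level keys `sim`, `model`, `train`, `inference`, `eval`, `seed`; unknown
keys are rejected with the offending path. Omitted keys take the defaults
(Adam, lr 1e-4, StepLR, batch 32, margin 0.01, 40 epochs, w1 0.9 / w2 0.1,
sigma 5 frames, threshold 0.5, 60 fps). Example:

```yaml
seed: 1
sim:
  image_size: 64
  onset_time_s: [0.5, 3.5]
train:
  epochs: 10
inference:
  sigma: 5.0
  threshold: 0.5
  fps: 60
```
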