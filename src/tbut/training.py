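"""Training protocol: Adam + step-decay, five-fold CV, fold-ensemble scoring.

Training minimises the dual-task loss on mini-batches of frame pairs; the
validation metric is the frame-level ROC-AUC of the single-branch classifier
over every validation frame carrying a binary label (unknown/blinking frames
are scored but excluded from the AUC).  The checkpoint with the best
validation AUC across epochs is kept per fold.  Test-time prediction averages
the probabilities of the k fold models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import _nn
from .dataset import FramePair, FrameRecord, preprocess_frame, sample_pairs, split_folds
from .model import DTSN, LossWeights, ModelConfig

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "FoldResult", "train_fold", "cross_validate", "ensemble_predict"]


class TrainConfig(BaseModel, extra="forbid"):
    """Optimisation hyperparameters (defaults follow the published protocol)."""

    optimizer: str = "adam"
    learning_rate: float = Field(default=1e-4, gt=0)
    scheduler: str = "steplr"
    step_size: int = Field(default=10, ge=1)
    gamma: float = Field(default=0.5, gt=0)
    batch_size: int = Field(default=32, ge=1)
    margin: float = Field(default=0.01, gt=0)
    epochs: int = Field(default=40, ge=0)
    w1: float = Field(default=0.9, ge=0)
    w2: float = Field(default=0.1, ge=0)
    augment: bool = False
    seed: int = 0

    @property
    def loss_weights(self) -> LossWeights:
        return LossWeights(w1=self.w1, w2=self.w2, margin=self.margin)


@dataclass
class FoldResult:
    fold: int
    model: DTSN
    val_auc: float
    history: pd.DataFrame = field(repr=False)


def _frames_tensor(
    frames: Sequence[FrameRecord],
    resolution: int,
    augment: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    return np.stack(
        [preprocess_frame(f.image_ref, resolution, augment=augment, rng=rng) for f in frames]
    )


def _pairs_tensors(
    pairs: Sequence[FramePair],
    resolution: int,
    augment: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x1 = _frames_tensor([p.a for p in pairs], resolution, augment, rng)
    x2 = _frames_tensor([p.b for p in pairs], resolution, augment, rng)
    y1 = np.array([p.y_a for p in pairs], dtype=np.float64)
    y2 = np.array([p.y_b for p in pairs], dtype=np.float64)
    Y = np.array([p.Y for p in pairs], dtype=np.float64)
    return x1, x2, y1, y2, Y


def _frame_auc(model: DTSN, x_val: np.ndarray, y_val: np.ndarray) -> float:
    from .evaluation import roc_auc

    probs = model.forward_single(x_val)
    return roc_auc(y_val, probs)


def _clone_params(model: DTSN) -> list[np.ndarray]:
    arrays = [p.value.copy() for p in model.parameters()]
    arrays += [b.copy() for b in model.encoder.buffers()]
    return arrays


def _restore_params(model: DTSN, values: list[np.ndarray]) -> None:
    targets = [p.value for p in model.parameters()] + model.encoder.buffers()
    for t, v in zip(targets, values):
        t[...] = v


def train_fold(
    pairs_train: Sequence[FramePair],
    frames_val: Sequence[FrameRecord],
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    fold: int = 0,
) -> FoldResult:
    """Train one fold and keep the best-validation-AUC checkpoint.

    Validation scores every binary-labeled frame with the single branch;
    unknown/blinking validation frames do not enter the AUC.
    """
    if not pairs_train:
        raise ValueError("empty training set")
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    rng = np.random.default_rng(train_config.seed + 7919 * fold)
    model = DTSN(model_config, seed=int(rng.integers(0, 2**31 - 1)))
    weights = train_config.loss_weights
    opt = _nn.Adam(model.parameters(), lr=train_config.learning_rate)
    sched = _nn.StepLR(opt, step_size=train_config.step_size, gamma=train_config.gamma)

    res = model_config.input_resolution
    # static tensors: augmentation, when enabled, is re-drawn per epoch below
    if not train_config.augment:
        x1, x2, y1, y2, Y = _pairs_tensors(pairs_train, res)

    val_binary = [f for f in frames_val if f.binary_label is not None]
    if len({f.binary_label for f in val_binary}) < 2:
        raise ValueError("validation frames must contain both classes for AUC")
    x_val = _frames_tensor(val_binary, res)
    y_val = np.array([f.binary_label for f in val_binary], dtype=int)

    n = len(pairs_train)
    best_auc = _frame_auc(model, x_val, y_val)
    best_params = _clone_params(model)
    rows = [{"epoch": 0, "train_loss": np.nan, "val_auc": best_auc}]

    for epoch in range(1, train_config.epochs + 1):
        if train_config.augment:
            x1, x2, y1, y2, Y = _pairs_tensors(pairs_train, res, augment=True, rng=rng)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            opt.zero_grad()
            loss = model.pair_loss_and_grads(
                x1[idx], x2[idx], y1[idx], y2[idx], Y[idx], weights
            )
            opt.step()
            losses.append(loss)
        sched.step()
        auc = _frame_auc(model, x_val, y_val)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": auc})
        logger.info("fold %d epoch %d loss %.4f val AUC %.4f", fold, epoch, rows[-1]["train_loss"], auc)
        # >= breaks AUC ties toward the later epoch: on separable data the AUC
        # saturates early while probability calibration keeps improving
        if auc >= best_auc:
            best_auc = auc
            best_params = _clone_params(model)

    _restore_params(model, best_params)
    return FoldResult(fold=fold, model=model, val_auc=best_auc, history=pd.DataFrame(rows))


def cross_validate(
    records: Sequence[FrameRecord],
    k: int = 5,
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    pairs_per_video: int = 3000,
    max_gap_frames: int = 60,
    tolerance: float = 0.05,
) -> tuple[list[FoldResult], dict]:
    """k-fold cross-validation at the video level.

    For each fold, pairs are sampled from the other folds' videos
    (``pairs_per_video`` per training video) and the held-out fold's frames
    form the validation set.  The summary reports the mean and sd of the fold
    AUCs.
    """
    train_config = train_config or TrainConfig()
    rng = np.random.default_rng(train_config.seed)
    assignment = split_folds(records, k=k, tolerance=tolerance, rng=rng)
    results: list[FoldResult] = []
    for fold in range(k):
        val_videos = set(assignment.videos_in_fold(fold))
        train_recs = [r for r in records if r.video_id not in val_videos]
        val_recs = [r for r in records if r.video_id in val_videos]
        n_train_videos = len({r.video_id for r in train_recs})
        pairs = sample_pairs(
            train_recs,
            n_pairs=2 * ((pairs_per_video * n_train_videos) // 2),
            max_gap_frames=max_gap_frames,
            rng=rng,
        )
        results.append(train_fold(pairs, val_recs, model_config, train_config, fold=fold))
    aucs = np.array([r.val_auc for r in results])
    summary = {
        "fold_aucs": aucs.tolist(),
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)) if k > 1 else 0.0,
        "fold_assignment": assignment.fold_of_video,
    }
    return results, summary


def ensemble_predict(
    models: Sequence[DTSN],
    frames: Sequence[FrameRecord],
    resolution: Optional[int] = None,
    batch_size: int = 256,
) -> np.ndarray:
    """Mean single-branch probability over the fold models for each frame."""
    if not models:
        raise ValueError("need at least one model")
    resolution = resolution or models[0].config.input_resolution
    x = _frames_tensor(frames, resolution)
    probs = np.zeros(len(frames))
    for model in models:
        out = np.concatenate(
            [model.forward_single(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        )
        probs += out
    return probs / len(models)


def save_run(results: Sequence[FoldResult], summary: dict, run_dir: Path) -> None:
    """Persist fold checkpoints, fold assignment, history and summary."""
    import json

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for r in results:
        r.model.save(run_dir / f"fold_{r.fold}.npz")
    pd.concat([r.history.assign(fold=r.fold) for r in results]).to_csv(
        run_dir / "history.csv", index=False
    )
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))


def load_run(run_dir: Path) -> list[DTSN]:
    run_dir = Path(run_dir)
    paths = sorted(run_dir.glob("fold_*.npz"))
    if not paths:
        raise FileNotFoundError(f"no fold checkpoints in {run_dir}")
    return [DTSN.load(p) for p in paths]
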