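"""Dual-task Siamese network for breakup / non-breakup frame classification.

Two weight-shared encoder branches map a pair of frames (x1, x2) into a
common embedding space (z1, z2).  A linear + sigmoid head on each embedding
gives the per-frame breakup probability (the classification task); the
Euclidean distance between the embeddings drives a contrastive objective
(the change-detection task).  At inference time a single branch acts as an
ordinary frame classifier.

The training objective is

    L_total = w1 * (L_b1 + L_b2) + w2 * L_c

with L_b the binary cross-entropy of each branch and L_c the contrastive
loss: similar pairs (Y=0) contribute the squared distance ||z1-z2||^2,
dissimilar pairs (Y=1) contribute max(margin - ||z1-z2||, 0)^2 -- the hinge
is taken on the *unsquared* distance.  Defaults w1=0.9, w2=0.1, margin=0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, Field

from . import _nn

EPS = 1e-7  # probability clamp for log stability

#: backbones that ship with the package; the published pretrained families
#: (rexnet150, inception_v3, efficientnet_b3, ...) need an external
#: deep-learning runtime and pretrained weights, neither of which this
#: package depends on, so only the compact in-repo encoder is accepted.
AVAILABLE_BACKBONES = ("tiny-cnn",)

__all__ = [
    "ModelConfig",
    "LossWeights",
    "PairOutput",
    "DTSN",
    "bce_loss",
    "contrastive_loss",
    "total_loss",
]


class ModelConfig(BaseModel, extra="forbid"):
    backbone: str = "tiny-cnn"
    embedding_dim: int = Field(default=32, ge=2)
    pretrained: bool = False
    input_resolution: int = Field(default=32, ge=8)
    in_channels: int = Field(default=1, ge=1)

    def model_post_init(self, __context) -> None:
        if self.backbone not in AVAILABLE_BACKBONES:
            raise ValueError(
                f"backbone {self.backbone!r} is not available; this package ships "
                f"{AVAILABLE_BACKBONES} (external pretrained families are not "
                f"bundled)"
            )
        if self.pretrained:
            raise ValueError("no pretrained weights are bundled with this package")
        if self.input_resolution % 4 != 0:
            raise ValueError("tiny-cnn requires input_resolution divisible by 4")


class LossWeights(BaseModel, extra="forbid"):
    """Weights of the two tasks and the contrastive margin."""

    w1: float = Field(default=0.9, ge=0)
    w2: float = Field(default=0.1, ge=0)
    margin: float = Field(default=0.01, gt=0)


@dataclass(frozen=True)
class PairOutput:
    """Embeddings, per-branch breakup probabilities and embedding distance."""

    z1: np.ndarray
    z2: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    @property
    def d(self) -> np.ndarray:
        return np.linalg.norm(self.z1 - self.z2, axis=-1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy -[y log p + (1-y) log(1-p)]."""
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def contrastive_loss(
    z1: np.ndarray, z2: np.ndarray, Y: np.ndarray, margin: float = 0.01
) -> float:
    """Mean of (1-Y)||z1-z2||^2 + Y max(margin - ||z1-z2||, 0)^2 over pairs."""
    z1 = np.atleast_2d(np.asarray(z1, dtype=np.float64))
    z2 = np.atleast_2d(np.asarray(z2, dtype=np.float64))
    if z1.shape != z2.shape:
        raise ValueError(f"shape mismatch: z1 {z1.shape} vs z2 {z2.shape}")
    Y = np.asarray(Y, dtype=np.float64).reshape(-1)
    d = np.linalg.norm(z1 - z2, axis=1)
    hinge = np.maximum(margin - d, 0.0)
    return float(np.mean((1.0 - Y) * d**2 + Y * hinge**2))


def total_loss(
    p1: np.ndarray,
    p2: np.ndarray,
    y1: np.ndarray,
    y2: np.ndarray,
    z1: np.ndarray,
    z2: np.ndarray,
    Y: np.ndarray,
    weights: Optional[LossWeights] = None,
) -> float:
    """Weighted dual-task loss w1*(L_b1 + L_b2) + w2*L_c."""
    w = weights or LossWeights()
    return (
        w.w1 * (bce_loss(p1, y1) + bce_loss(p2, y2))
        + w.w2 * contrastive_loss(z1, z2, Y, w.margin)
    )


class DTSN:
    """The dual-task Siamese network with the compact in-repo encoder.

    Encoder: three 3x3 conv + ReLU blocks (8, 16, 32 channels), 2x2 max
    pooling after the first two, global average pooling, batch-normalised
    pooled features, then a linear projection to ``embedding_dim``.
    Classifier head: linear + sigmoid on the embedding.  Both branches share
    this single parameter set.  Inference always runs in evaluation mode
    (batch-norm running statistics), so outputs are per-frame deterministic.
    """

    def __init__(self, config: Optional[ModelConfig] = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        c = self.config.in_channels
        self.encoder = _nn.Sequential(
            _nn.Conv3x3(c, 8, rng),
            _nn.ReLU(),
            _nn.MaxPool2(),
            _nn.Conv3x3(8, 16, rng),
            _nn.ReLU(),
            _nn.MaxPool2(),
            _nn.Conv3x3(16, 32, rng),
            _nn.ReLU(),
            _nn.GlobalAvgPool(),
            _nn.BatchNorm1d(32),
            _nn.Linear(32, self.config.embedding_dim, rng),
        )
        self.head = _nn.Linear(self.config.embedding_dim, 1, rng)
        self.encoder.set_training(False)

    # --- forward ---------------------------------------------------------

    def parameters(self) -> list[_nn.Parameter]:
        return self.encoder.parameters() + self.head.parameters()

    def _check_resolution(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_nn.DTYPE)
        if x.ndim == 3:
            x = x[None]
        r = self.config.input_resolution
        if x.shape[1:] != (self.config.in_channels, r, r):
            raise ValueError(
                f"expected input of shape (N, {self.config.in_channels}, {r}, {r}), "
                f"got {x.shape}"
            )
        return x

    def embed(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One branch: embedding z and breakup probability p (eval mode)."""
        x = self._check_resolution(x)
        self.encoder.set_training(False)
        z = self.encoder.forward(x)
        logit = self.head.forward(z)[:, 0]
        return z, _sigmoid(logit)

    def forward_pair(self, x1: np.ndarray, x2: np.ndarray) -> PairOutput:
        z1, p1 = self.embed(x1)
        z2, p2 = self.embed(x2)
        return PairOutput(z1=z1, z2=z2, p1=p1, p2=p2)

    def forward_single(self, x: np.ndarray) -> np.ndarray:
        """Breakup probability of each frame (the validation-time classifier)."""
        _, p = self.embed(x)
        return p

    # --- training step ---------------------------------------------------

    def pair_loss_and_grads(
        self,
        x1: np.ndarray,
        x2: np.ndarray,
        y1: np.ndarray,
        y2: np.ndarray,
        Y: np.ndarray,
        weights: LossWeights,
    ) -> float:
        """Accumulate dL/dtheta for one mini-batch of pairs; returns the loss.

        Both branches are re-run one after the other (the layer caches hold a
        single forward), backpropagating each branch's BCE + contrastive
        gradient into the shared parameters.
        """
        x1 = self._check_resolution(x1)
        x2 = self._check_resolution(x2)
        y1 = np.asarray(y1, dtype=np.float64)
        y2 = np.asarray(y2, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        n = x1.shape[0]

        # both branches share parameters, so run them as one batch of 2n
        self.encoder.set_training(True)
        x = np.concatenate([x1, x2], axis=0)
        z = self.encoder.forward(x)
        logits = self.head.forward(z)[:, 0]
        p = _sigmoid(logits)
        z1, z2 = z[:n], z[n:]
        p1, p2 = p[:n], p[n:]

        diff = z1 - z2
        d = np.linalg.norm(diff, axis=1)
        hinge = np.maximum(weights.margin - d, 0.0)
        loss = weights.w1 * (bce_loss(p1, y1) + bce_loss(p2, y2)) + weights.w2 * float(
            np.mean((1.0 - Y) * d**2 + Y * hinge**2)
        )

        # dLc/dz1 per pair: similar 2*diff, dissimilar -2*hinge*diff/d (0 at d=0)
        gc = np.zeros_like(diff)
        sim = Y == 0
        gc[sim] = 2.0 * diff[sim]
        dis = (~sim) & (hinge > 0) & (d > 0)
        gc[dis] = (-2.0 * hinge[dis] / d[dis])[:, None] * diff[dis]
        gc /= n

        dlogits = (weights.w1 * (p - np.concatenate([y1, y2])) / n).astype(_nn.DTYPE)
        dz = self.head.backward(dlogits[:, None])
        dz[:n] += (weights.w2 * gc).astype(_nn.DTYPE)
        dz[n:] -= (weights.w2 * gc).astype(_nn.DTYPE)
        self.encoder.backward(dz.astype(_nn.DTYPE))
        return float(loss)

    # --- serialization ---------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Write weights as .npz plus a ModelConfig JSON sidecar."""
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        arrays.update({f"b{i}": b for i, b in enumerate(self.encoder.buffers())})
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(self.config.model_dump_json(indent=2))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "DTSN":
        path = Path(path)
        config = ModelConfig.model_validate_json(path.with_suffix(".json").read_text())
        model = cls(config)
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"p{i}"]
        for i, b in enumerate(model.encoder.buffers()):
            b[...] = data[f"b{i}"]
        return model
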