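"""Run-level configuration: one YAML/JSON file, one master seed.

A :class:`RunConfig` bundles the simulator, model, training, inference and
evaluation settings.  Every sub-config validates itself (unknown keys are
rejected with the offending path), omitted keys fall back to the published
protocol defaults (Adam, lr 1e-4, StepLR, batch 32, margin 0.01, 40 epochs,
w1=0.9/w2=0.1; smoothing sigma 5 frames, threshold 0.5, 60 fps).  The master
seed deterministically derives independent per-module streams.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from .model import ModelConfig
from .synthetic_data import SimConfig
from .training import TrainConfig

__all__ = ["InferenceConfig", "EvalConfig", "RunConfig", "load_config", "dump_config", "derive_seed"]


class InferenceConfig(BaseModel, extra="forbid"):
    sigma: float = Field(default=5.0, gt=0)  # frames
    threshold: float = Field(default=0.5, gt=0, lt=1)
    fps: float = Field(default=60.0, gt=0)


class EvalConfig(BaseModel, extra="forbid"):
    bin_width_s: float = Field(default=0.5, gt=0)
    bin_limit_s: float = Field(default=12.0, gt=0)
    rates: list[float] = [60.0, 30.0, 15.0, 5.0]


class RunConfig(BaseModel, extra="forbid"):
    sim: SimConfig = SimConfig()
    model: ModelConfig = ModelConfig()
    train: TrainConfig = TrainConfig()
    inference: InferenceConfig = InferenceConfig()
    eval: EvalConfig = EvalConfig()
    seed: int = 0


_MODULE_STREAMS = {"sim": 0, "train": 1, "predict": 2, "evaluate": 3}


def derive_seed(master: int, module: str) -> int:
    """Per-module seed (< 2^31) derived deterministically from the master seed."""
    key = _MODULE_STREAMS[module]
    ss = np.random.SeedSequence(entropy=master, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def load_config(path: Union[str, Path, None] = None) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    ``None`` or an empty file yields the full default configuration.  Unknown
    keys raise with a path-to-key message; out-of-range values raise with the
    validator's explanation.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if data is None:
        return RunConfig()
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        locs = "; ".join(
            "->".join(str(p) for p in err["loc"]) + f": {err['msg']}" for err in exc.errors()
        )
        raise ValueError(f"invalid configuration {path}: {locs}") from exc


def dump_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(json.loads(config.model_dump_json())))
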