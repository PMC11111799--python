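"""From per-frame breakup probabilities to a break-up time in seconds.

The pipeline follows the clinical definition of TBUT: t = 0 at eye opening,
and the break-up time is the instant the tear film first ruptures.  Raw
per-frame classifier probabilities are noisy, so they are smoothed with a
Gaussian filter (sigma in *frames*, default 5) before a 0.5 decision
threshold is applied.  The TBUT is the first frame index whose smoothed
probability reaches the threshold, divided by the frame rate; if no frame
reaches it, the subtest never broke up while the eye was open and the last
frame index over fps is reported instead (the fallback rule).  Frame indices
are 0-based from the first open-eye frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .dataset import FrameRecord, preprocess_frame

RULE_CROSSED = "crossed-threshold"
RULE_FALLBACK = "no-breakup-fallback"

__all__ = [
    "PredictionSeries",
    "TBUTEstimate",
    "gaussian_smooth",
    "estimate_tbut",
    "average_tbut",
    "predict_subtest",
    "predict_video",
]


@dataclass
class PredictionSeries:
    """Ordered per-frame breakup probabilities for one subtest."""

    probs: np.ndarray
    fps: float
    smoothed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.size == 0:
            raise ValueError("prediction series must be non-empty")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


@dataclass(frozen=True)
class TBUTEstimate:
    """Break-up time of one subtest and the rule that produced it."""

    tbut_s: float
    rule: str
    crossing_index: Optional[int]

    def __post_init__(self) -> None:
        if self.tbut_s < 0:
            raise ValueError("tbut_s must be >= 0")
        if (self.rule == RULE_FALLBACK) != (self.crossing_index is None):
            raise ValueError("crossing_index is None iff the fallback rule fired")


def gaussian_smooth(series: PredictionSeries, sigma: float = 5.0) -> PredictionSeries:
    """Smooth the raw probabilities with a normalized Gaussian kernel.

    Sigma is measured in frames.  The kernel is truncated at 4 sigma and the
    boundary is handled by reflection, so a constant series stays constant
    and outputs remain in [0, 1].
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    smoothed = gaussian_filter1d(series.probs, sigma=sigma, mode="reflect", truncate=4.0)
    return PredictionSeries(probs=series.probs, fps=series.fps, smoothed=np.clip(smoothed, 0.0, 1.0))


def estimate_tbut(series: PredictionSeries, threshold: float = 0.5) -> TBUTEstimate:
    """First threshold crossing of the smoothed series, in seconds.

    The crossing uses >= (a smoothed probability equal to the threshold
    counts).  Without a crossing the fallback reports the last frame's time,
    (L-1)/fps.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if series.smoothed is None:
        raise ValueError("series must be smoothed first (gaussian_smooth)")
    above = np.nonzero(series.smoothed >= threshold)[0]
    if above.size:
        idx = int(above[0])
        return TBUTEstimate(tbut_s=idx / series.fps, rule=RULE_CROSSED, crossing_index=idx)
    last = len(series.smoothed) - 1
    return TBUTEstimate(tbut_s=last / series.fps, rule=RULE_FALLBACK, crossing_index=None)


def average_tbut(estimates: Sequence[TBUTEstimate]) -> float:
    """Per-eye TBUT: the arithmetic mean of the subtest break-up times."""
    if not estimates:
        raise ValueError("need at least one subtest estimate")
    return float(np.mean([e.tbut_s for e in estimates]))


def _score_frames(models, frames: Sequence[FrameRecord], resolution: int) -> np.ndarray:
    from .training import ensemble_predict

    return ensemble_predict(models, frames, resolution=resolution)


def predict_subtest(
    models,
    open_frames: Sequence[FrameRecord],
    fps: float,
    sigma: float = 5.0,
    threshold: float = 0.5,
    resolution: Optional[int] = None,
) -> tuple[TBUTEstimate, PredictionSeries]:
    """Score one subtest's open-eye frames and estimate its TBUT."""
    if not open_frames:
        raise ValueError("subtest has no open-eye frames")
    resolution = resolution or models[0].config.input_resolution
    probs = _score_frames(models, open_frames, resolution)
    series = gaussian_smooth(PredictionSeries(probs=probs, fps=fps), sigma=sigma)
    return estimate_tbut(series, threshold=threshold), series


@dataclass
class VideoPrediction:
    estimates: list[TBUTEstimate]
    series: list[PredictionSeries]
    eye_tbut_s: float = field(init=False)

    def __post_init__(self) -> None:
        self.eye_tbut_s = average_tbut(self.estimates)


def predict_video(
    models,
    subtests: Sequence[Sequence[FrameRecord]],
    fps: float,
    sigma: float = 5.0,
    threshold: float = 0.5,
    out_dir: Optional[Path] = None,
) -> VideoPrediction:
    """Estimate TBUT for every subtest of one eye.

    ``subtests`` are lists of open-eye FrameRecords (subtest extraction is the
    caller's job).  With ``out_dir`` set, a per-frame CSV
    (frame_index, raw_p, smoothed_p) and a JSON of estimates are written.
    """
    estimates, all_series = [], []
    for frames in subtests:
        est, series = predict_subtest(models, frames, fps, sigma=sigma, threshold=threshold)
        estimates.append(est)
        all_series.append(series)
    pred = VideoPrediction(estimates=estimates, series=all_series)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sub_ids = [frames[0].subtest_id for frames in subtests]
        for sid, series, frames in zip(sub_ids, all_series, subtests):
            pd.DataFrame(
                {
                    "frame_index": [f.frame_index for f in frames],
                    "raw_p": series.probs,
                    "smoothed_p": series.smoothed,
                }
            ).to_csv(out_dir / f"scores_{sid}.csv", index=False)
        payload = [
            {
                "subtest_id": sid,
                "tbut_s": e.tbut_s,
                "rule": e.rule,
                "crossing_index": e.crossing_index,
            }
            for sid, e in zip(sub_ids, estimates)
        ]
        (out_dir / "estimates.json").write_text(
            json.dumps({"subtests": payload, "eye_tbut_s": pred.eye_tbut_s}, indent=2)
        )
    return pred
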