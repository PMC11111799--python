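"""Synthetic tear-film video simulator with known ground-truth TBUT.

Real TBUT recordings show a bright fluorescein-stained corneal disc under
cobalt-blue light; tear-film rupture appears as dark spots that emerge at some
onset time and persist, growing, until the next blink.  This module renders a
stylised version of that appearance -- a uniform bright disc on a dark
background on which dark circular spots appear at a known onset and grow
linearly -- so that every downstream stage (pair sampling, the Siamese
classifier, smoothing/thresholding, evaluation) can be exercised against exact
ground truth without clinical data.

Each simulated *subtest* is one open-eye interval: an optional leading blink
sequence, the open-eye span (non-breakup frames, an ambiguity band of
``unknown`` frames around onset, then breakup frames), and a trailing blink
sequence.  A video holds ``n_subtests_per_eye`` subtests for one eye.  The
true TBUT of a subtest is the time from the first open-eye frame to spot
onset; when the drawn onset falls beyond the open span the subtest simply
never breaks up and its true TBUT is ``None``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .dataset import (
    LABEL_BLINKING,
    LABEL_BREAKUP,
    LABEL_NON_BREAKUP,
    LABEL_UNKNOWN,
    FrameRecord,
    write_annotations,
)

__all__ = [
    "SimConfig",
    "SpotState",
    "Subtest",
    "SyntheticVideo",
    "render_frame",
    "generate_subtest",
    "generate_video",
    "resample_frame_rate",
    "write_video",
]


class SimConfig(BaseModel, extra="forbid"):
    """Parameters of the simulator.

    Ranges are (low, high) tuples sampled uniformly per subtest. ``onset_time_s``
    may exceed ``open_duration_s``, in which case the subtest has no breakup.
    """

    image_size: int = Field(default=128, ge=32)
    fps: float = Field(default=60.0, gt=0)
    n_subtests_per_eye: int = Field(default=3, ge=1)
    open_duration_s: tuple[float, float] = (4.0, 8.0)
    onset_time_s: tuple[float, float] = (0.5, 10.0)
    n_spots: tuple[int, int] = (1, 4)
    spot_growth_px_per_s: float = Field(default=6.0, gt=0)
    spot_base_radius_px: float = Field(default=2.0, ge=0)
    spot_contrast: float = Field(default=0.55, gt=0, le=1)
    blink_duration_s: tuple[float, float] = (0.1, 0.4)
    unknown_band_s: float = Field(default=0.1, ge=0)
    noise_sd: float = Field(default=0.02, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self) -> "SimConfig":
        for name in ("open_duration_s", "onset_time_s", "n_spots", "blink_duration_s"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
            if lo < 0:
                raise ValueError(f"{name}: negative bound {lo}")
        return self


@dataclass(frozen=True)
class SpotState:
    """Instantaneous scene description handed to :func:`render_frame`.

    ``centers`` are (row, col) pixel coordinates inside the corneal disc;
    ``radii`` are the current spot radii in pixels (0 = not yet visible).
    ``lid_closure`` in [0, 1] is the fraction of the image covered by the
    eyelid (1 = fully closed blink frame).
    """

    image_size: int
    centers: tuple[tuple[float, float], ...] = ()
    radii: tuple[float, ...] = ()
    disc_brightness: float = 0.9
    background: float = 0.05
    spot_contrast: float = 0.55
    noise_sd: float = 0.0
    lid_closure: float = 0.0


def _disc_geometry(size: int) -> tuple[np.ndarray, float, float]:
    c = (size - 1) / 2.0
    radius = 0.45 * size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    rr = np.hypot(yy - c, xx - c)
    return rr, c, radius


def render_frame(state: SpotState, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Render one grayscale frame in [0, 1] from a :class:`SpotState`.

    The corneal disc is uniform at ``disc_brightness``; each spot darkens its
    interior by a contrast margin that grows with the spot radius (larger
    ruptures are darker, mimicking dye depletion).  Additive Gaussian noise of
    sd ``noise_sd`` is applied last and the image is clipped to [0, 1].
    """
    size = state.image_size
    if size <= 0:
        raise ValueError(f"image_size must be positive, got {size}")
    if any(r < 0 for r in state.radii):
        raise ValueError("spot radii must be >= 0")
    rr, c, disc_r = _disc_geometry(size)
    img = np.full((size, size), state.background, dtype=np.float64)
    disc = rr <= disc_r
    img[disc] = state.disc_brightness

    for (cy, cx), radius in zip(state.centers, state.radii):
        if np.hypot(cy - c, cx - c) > disc_r:
            raise ValueError(f"spot center ({cy}, {cx}) lies outside the disc")
        if radius <= 0:
            continue
        # contrast deepens with radius, saturating at spot_contrast
        depth = state.spot_contrast * min(1.0, 0.3 + 0.07 * radius)
        yy, xx = np.ogrid[0:size, 0:size]
        spot = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        img[spot & disc] = state.disc_brightness - depth

    if state.lid_closure > 0:
        lid_rows = int(round(state.lid_closure * size))
        img[:lid_rows, :] = 0.12

    if state.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        img = img + rng.normal(0.0, state.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


@dataclass
class Subtest:
    """One open-eye interval with optional blink frames at its boundaries.

    ``frames[i].frame_index == i`` over the whole subtest; ``open_start`` is
    the index of the first open-eye frame, and TBUT timing is measured from it
    (t = 0 at eye opening).
    """

    frames: list[FrameRecord]
    fps: float
    true_tbut_s: Optional[float]

    @property
    def open_start(self) -> int:
        for rec in self.frames:
            if rec.label != LABEL_BLINKING:
                return rec.frame_index
        raise ValueError("subtest has no open-eye frames")

    @property
    def open_frames(self) -> list[FrameRecord]:
        return [r for r in self.frames if r.label != LABEL_BLINKING]


@dataclass
class SyntheticVideo:
    video_id: str
    eye: str
    subtests: list[Subtest]
    sim_config: SimConfig
    true_tbut_s: list[Optional[float]] = field(init=False)

    def __post_init__(self) -> None:
        self.true_tbut_s = [s.true_tbut_s for s in self.subtests]


def _uniform(rng: np.random.Generator, bounds: Sequence[float]) -> float:
    lo, hi = bounds
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def _label_for_open_frame(t: float, onset: Optional[float], band: float) -> str:
    if onset is None or t < onset - band:
        return LABEL_NON_BREAKUP
    if t < onset + band:
        return LABEL_UNKNOWN
    return LABEL_BREAKUP


def generate_subtest(
    config: SimConfig,
    rng: np.random.Generator,
    *,
    video_id: str = "v000",
    eye: str = "R",
    subtest_id: str = "s0",
    render: bool = True,
) -> Subtest:
    """Generate one labeled subtest.

    Leading blink frames, then the open-eye span (labels non-breakup /
    unknown / breakup per the ambiguity band around onset), then trailing
    blink frames.  Spots appear at onset with ``spot_base_radius_px`` and grow
    at ``spot_growth_px_per_s``.  With ``render=False`` only labels are
    produced (``image_ref=None``), which is cheap for sampler/splitter tests.
    """
    fps = config.fps
    open_dur = _uniform(rng, config.open_duration_s)
    onset = _uniform(rng, config.onset_time_s)
    # degenerate draw: onset inside the leading ambiguity band -> resample
    for _ in range(100):
        if onset >= config.unknown_band_s:
            break
        onset = _uniform(rng, config.onset_time_s)
    n_open = max(1, int(round(open_dur * fps)))
    has_breakup = onset + config.unknown_band_s < open_dur
    true_tbut: Optional[float] = onset if has_breakup else None

    n_spots = int(rng.integers(config.n_spots[0], config.n_spots[1] + 1))
    rr, c, disc_r = _disc_geometry(config.image_size)
    centers = []
    for _ in range(n_spots):
        while True:
            ang = rng.uniform(0, 2 * np.pi)
            rad = disc_r * 0.7 * np.sqrt(rng.uniform())
            cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
            if np.hypot(cy - c, cx - c) <= disc_r:
                break
        centers.append((cy, cx))

    def make_state(t: float, lid: float = 0.0) -> SpotState:
        if has_breakup and t >= onset:
            radii = tuple(
                config.spot_base_radius_px + config.spot_growth_px_per_s * (t - onset)
                for _ in centers
            )
            cts = tuple(centers)
        else:
            cts, radii = (), ()
        return SpotState(
            image_size=config.image_size,
            centers=cts,
            radii=radii,
            spot_contrast=config.spot_contrast,
            noise_sd=config.noise_sd,
            lid_closure=lid,
        )

    frames: list[FrameRecord] = []

    def emit(label: str, state: SpotState) -> None:
        img = render_frame(state, rng) if render else None
        frames.append(
            FrameRecord(
                video_id=video_id,
                eye=eye,
                subtest_id=subtest_id,
                frame_index=len(frames),
                label=label,
                image_ref=img,
            )
        )

    n_blink_lead = int(round(_uniform(rng, config.blink_duration_s) * fps))
    n_blink_trail = int(round(_uniform(rng, config.blink_duration_s) * fps))
    for i in range(n_blink_lead):
        # lid sweeps open over the blink sequence
        emit(LABEL_BLINKING, make_state(0.0, lid=1.0 - i / max(1, n_blink_lead)))
    for k in range(n_open):
        t = k / fps
        emit(_label_for_open_frame(t, onset if has_breakup else None, config.unknown_band_s), make_state(t))
    for i in range(n_blink_trail):
        emit(LABEL_BLINKING, make_state(n_open / fps, lid=(i + 1) / n_blink_trail))

    return Subtest(frames=frames, fps=fps, true_tbut_s=true_tbut)


def generate_video(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    *,
    video_id: str = "v000",
    eye: str = "R",
    render: bool = True,
) -> SyntheticVideo:
    """Generate one eye's video: ``n_subtests_per_eye`` independent subtests.

    Each subtest gets its own RNG stream spawned from the video seed so that
    subtests are individually reproducible.
    """
    if rng is None:
        ss = np.random.SeedSequence(config.seed)
    else:
        ss = np.random.SeedSequence(int(rng.integers(0, 2**31 - 1)))
    subtests = []
    for k, child in enumerate(ss.spawn(config.n_subtests_per_eye)):
        subtests.append(
            generate_subtest(
                config,
                np.random.default_rng(child),
                video_id=video_id,
                eye=eye,
                subtest_id=f"s{k}",
                render=render,
            )
        )
    return SyntheticVideo(video_id=video_id, eye=eye, subtests=subtests, sim_config=config)


def resample_frame_rate(subtest: Subtest, target_fps: float) -> Subtest:
    """Decimate a subtest to a lower frame rate that evenly divides its fps.

    Keeps every (fps/target_fps)-th frame starting at the first frame; labels
    and the true TBUT are unchanged.  Frame indices are renumbered
    consecutively at the new rate.
    """
    ratio = subtest.fps / target_fps
    if abs(ratio - round(ratio)) > 1e-9 or target_fps <= 0:
        raise ValueError(
            f"target_fps {target_fps} does not evenly divide native fps {subtest.fps}"
        )
    step = int(round(ratio))
    kept = subtest.frames[::step]
    frames = [replace(rec, frame_index=i) for i, rec in enumerate(kept)]
    return Subtest(frames=frames, fps=target_fps, true_tbut_s=subtest.true_tbut_s)


def write_video(video: SyntheticVideo, out_dir: Path) -> Path:
    """Write frames as PNGs plus the annotation CSV and ground-truth JSON.

    Layout: ``video_<id>/eye_<L|R>/subtest_<k>/frame_<%06d>.png``; the CSV and
    ``ground_truth.json`` sit next to the video directory.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    records = []
    for k, subtest in enumerate(video.subtests):
        sub_dir = out_dir / f"video_{video.video_id}" / f"eye_{video.eye}" / f"subtest_{k}"
        sub_dir.mkdir(parents=True, exist_ok=True)
        for rec in subtest.frames:
            if rec.image_ref is None:
                raise ValueError("cannot write a video generated with render=False")
            path = sub_dir / f"frame_{rec.frame_index:06d}.png"
            iio.imwrite(path, (np.asarray(rec.image_ref) * 255).astype(np.uint8))
            records.append(replace(rec, image_ref=str(path)))
    write_annotations(records, out_dir / f"video_{video.video_id}" / "annotations.csv")
    truth = {
        "video_id": video.video_id,
        "eye": video.eye,
        "fps": video.sim_config.fps,
        "true_tbut_s": video.true_tbut_s,
    }
    gt_path = out_dir / f"video_{video.video_id}" / "ground_truth.json"
    gt_path.write_text(json.dumps(truth, indent=2))
    return out_dir / f"video_{video.video_id}"
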