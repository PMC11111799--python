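"""Frame annotations, training-pair construction, fold splitting, preprocessing.

Frames carry one of four labels: ``non-breakup`` (open eye, intact tear film),
``breakup`` (open eye with dark rupture spots), ``unknown`` (ambiguous around
breakup onset) and ``blinking`` (eyelid in motion or closed).  Only the two
binary classes feed training; unknown and blinking frames are excluded from
pair sampling but are still scored at inference time.

The change-detection branch of the network trains on frame *pairs* drawn from
a single subtest with a randomized frame gap: similar pairs (same binary
class, pair label Y=0) and dissimilar pairs (one non-breakup + one breakup,
Y=1) in equal proportion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance

LABEL_NON_BREAKUP = "non-breakup"
LABEL_BREAKUP = "breakup"
LABEL_UNKNOWN = "unknown"
LABEL_BLINKING = "blinking"
LABELS = (LABEL_NON_BREAKUP, LABEL_BREAKUP, LABEL_UNKNOWN, LABEL_BLINKING)

#: binary encoding of the two trainable classes
BINARY_LABELS = {LABEL_NON_BREAKUP: 0, LABEL_BREAKUP: 1}

ANNOTATION_COLUMNS = ["video_id", "eye", "subtest_id", "frame_index", "label", "image_ref"]

__all__ = [
    "LABELS",
    "BINARY_LABELS",
    "FrameRecord",
    "FramePair",
    "FoldAssignment",
    "read_annotations",
    "write_annotations",
    "sample_pairs",
    "split_folds",
    "preprocess_frame",
    "load_frame_image",
]


@dataclass(frozen=True)
class FrameRecord:
    """One video frame: identity, temporal position, label, and pixel source.

    ``image_ref`` is either a filesystem path (str) or an in-memory grayscale
    array in [0, 1]; ``None`` for label-only records.
    """

    video_id: str
    eye: str
    subtest_id: str
    frame_index: int
    label: str
    image_ref: Union[str, np.ndarray, None] = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if self.label not in LABELS:
            raise ValueError(f"label {self.label!r} not in {LABELS}")

    @property
    def subtest_key(self) -> tuple[str, str, str]:
        return (self.video_id, self.eye, self.subtest_id)

    @property
    def binary_label(self) -> Optional[int]:
        return BINARY_LABELS.get(self.label)


@dataclass(frozen=True)
class FramePair:
    """Two frames from one subtest with the derived similarity label.

    ``Y = 0`` marks a similar pair (same binary class), ``Y = 1`` a dissimilar
    one; neither member may be unknown/blinking.
    """

    a: FrameRecord
    b: FrameRecord
    y_a: int
    y_b: int
    Y: int

    def __post_init__(self) -> None:
        if self.a.subtest_key != self.b.subtest_key:
            raise ValueError("pair members must share video, eye and subtest")
        for rec, y in ((self.a, self.y_a), (self.b, self.y_b)):
            if rec.binary_label is None:
                raise ValueError(f"pair member has non-binary label {rec.label!r}")
            if rec.binary_label != y:
                raise ValueError("stored binary label disagrees with the frame label")
        if self.Y != int(self.y_a != self.y_b):
            raise ValueError("pair label Y must equal (y_a != y_b)")


@dataclass(frozen=True)
class FoldAssignment:
    """Video-level partition into k folds."""

    k: int
    fold_of_video: dict[str, int]

    def videos_in_fold(self, fold: int) -> list[str]:
        return sorted(v for v, f in self.fold_of_video.items() if f == fold)

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps({"k": self.k, "fold_of_video": self.fold_of_video}, indent=2))

    @classmethod
    def from_json(cls, path: Path) -> "FoldAssignment":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], fold_of_video=d["fold_of_video"])


_CANONICAL = {lbl.lower(): lbl for lbl in LABELS}


def read_annotations(path: Union[str, Path]) -> list[FrameRecord]:
    """Read an annotation CSV into FrameRecords.

    Labels are normalized case-insensitively to the canonical four-class
    vocabulary; anything outside it raises with the offending row numbers.
    Duplicate (video, eye, subtest, frame_index) keys are rejected.
    """
    df = pd.read_csv(path, dtype={"image_ref": str}, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path} is missing columns: {missing}")
    labels = df["label"].astype(str).str.strip().str.lower()
    bad = df.index[~labels.isin(_CANONICAL)].tolist()
    if bad:
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(
            f"annotation file {path} has labels outside {LABELS} at rows {rows}"
        )
    keys = df[["video_id", "eye", "subtest_id", "frame_index"]]
    dup = keys.duplicated()
    if dup.any():
        raise ValueError(
            f"annotation file {path} has duplicate frame keys at rows "
            f"{[i + 2 for i in df.index[dup][:10].tolist()]}"
        )
    records = []
    for row, lbl in zip(df.itertuples(index=False), labels):
        ref = row.image_ref if row.image_ref else None
        records.append(
            FrameRecord(
                video_id=str(row.video_id),
                eye=str(row.eye),
                subtest_id=str(row.subtest_id),
                frame_index=int(row.frame_index),
                label=_CANONICAL[lbl],
                image_ref=ref,
            )
        )
    return records


def write_annotations(records: Sequence[FrameRecord], path: Union[str, Path]) -> None:
    """Write FrameRecords to CSV (in-memory image refs are written empty)."""
    rows = [
        {
            "video_id": r.video_id,
            "eye": r.eye,
            "subtest_id": r.subtest_id,
            "frame_index": r.frame_index,
            "label": r.label,
            "image_ref": r.image_ref if isinstance(r.image_ref, str) else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def _eligible_by_subtest(records: Sequence[FrameRecord]) -> dict[tuple, np.ndarray]:
    """Per subtest: dense array of binary labels indexed by frame_index, -1 = excluded."""
    groups: dict[tuple, dict[int, int]] = {}
    for rec in records:
        y = rec.binary_label
        groups.setdefault(rec.subtest_key, {})[rec.frame_index] = -1 if y is None else y
    out = {}
    for key, idx_map in groups.items():
        n = max(idx_map) + 1
        arr = np.full(n, -1, dtype=np.int8)
        for i, y in idx_map.items():
            arr[i] = y
        out[key] = arr
    return out


def sample_pairs(
    records: Sequence[FrameRecord],
    n_pairs: int,
    max_gap_frames: int = 60,
    rng: Optional[np.random.Generator] = None,
) -> list[FramePair]:
    """Sample n_pairs/2 similar + n_pairs/2 dissimilar same-subtest pairs.

    The frame gap is drawn uniformly from [1, max_gap_frames] (restricted to
    gaps for which at least one candidate pair of the requested kind exists);
    sampling is with replacement.  Unknown/blinking frames never enter pairs.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_pairs % 2 != 0:
        raise ValueError(f"n_pairs must be even, got {n_pairs}")
    if max_gap_frames < 1:
        raise ValueError("max_gap_frames must be >= 1")

    rec_by_key: dict[tuple, dict[int, FrameRecord]] = {}
    for rec in records:
        rec_by_key.setdefault(rec.subtest_key, {})[rec.frame_index] = rec
    labels = _eligible_by_subtest(records)
    keys = sorted(labels)

    # candidates[kind][gap] -> (subtest key index, first frame index) arrays
    candidates: dict[int, dict[int, tuple[np.ndarray, np.ndarray]]] = {0: {}, 1: {}}
    for g in range(1, max_gap_frames + 1):
        sim_k, sim_i, dis_k, dis_i = [], [], [], []
        for ki, key in enumerate(keys):
            arr = labels[key]
            if len(arr) <= g:
                continue
            a, b = arr[:-g], arr[g:]
            ok = (a >= 0) & (b >= 0)
            dis = ok & (a != b)
            sim = ok & (a == b)
            (idx,) = np.nonzero(sim)
            sim_k.extend([ki] * len(idx)); sim_i.extend(idx.tolist())
            (idx,) = np.nonzero(dis)
            dis_k.extend([ki] * len(idx)); dis_i.extend(idx.tolist())
        if sim_k:
            candidates[0][g] = (np.array(sim_k), np.array(sim_i))
        if dis_k:
            candidates[1][g] = (np.array(dis_k), np.array(dis_i))

    if not candidates[1]:
        raise ValueError(
            "cannot form dissimilar pairs: no subtest contains both a "
            "non-breakup and a breakup frame within max_gap_frames"
        )
    if not candidates[0]:
        raise ValueError("cannot form similar pairs: no eligible same-class pairs")

    pairs: list[FramePair] = []
    for kind in (0, 1):
        gaps = np.array(sorted(candidates[kind]))
        draw_gaps = rng.choice(gaps, size=n_pairs // 2, replace=True)
        for g, count in zip(*np.unique(draw_gaps, return_counts=True)):
            ks, starts = candidates[kind][int(g)]
            picks = rng.integers(0, len(ks), size=count)
            for p in picks:
                key = keys[ks[p]]
                i = int(starts[p])
                a = rec_by_key[key][i]
                b = rec_by_key[key][i + int(g)]
                pairs.append(
                    FramePair(a=a, b=b, y_a=a.binary_label, y_b=b.binary_label, Y=kind)
                )
    # interleave deterministically so batches mix both kinds
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def pairs_to_frame(pairs: Sequence[FramePair]) -> pd.DataFrame:
    """Audit export of sampled pairs."""
    return pd.DataFrame(
        [
            (p.a.video_id, p.a.subtest_id, p.a.frame_index, p.b.frame_index, p.y_a, p.y_b, p.Y)
            for p in pairs
        ],
        columns=["video_id", "subtest_id", "idx_a", "idx_b", "y_a", "y_b", "Y"],
    )


def split_folds(
    records: Sequence[FrameRecord],
    k: int = 5,
    tolerance: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> FoldAssignment:
    """Partition videos into k folds, stratified on per-video class counts.

    Splitting is at the video (patient) level so no frames of one patient leak
    across folds.  Fold sizes are balanced within one video.  Videos are
    assigned greedily (largest first, to the fold whose breakup:non-breakup
    ratio it improves most), then refined by video swaps between folds until
    the worst per-fold deviation from the global breakup fraction is within
    ``tolerance`` or no swap helps.  Deterministic given the rng.
    """
    if rng is None:
        rng = np.random.default_rng()
    stats: dict[str, list[int]] = {}
    for rec in records:
        pos_neg = stats.setdefault(rec.video_id, [0, 0])
        y = rec.binary_label
        if y is not None:
            pos_neg[y] += 1
    videos = sorted(stats)
    if len(videos) < k:
        raise ValueError(f"need at least k={k} videos, got {len(videos)}")

    perm = rng.permutation(len(videos))
    shuffled = [videos[i] for i in perm]
    shuffled.sort(key=lambda v: -(stats[v][0] + stats[v][1]))  # stable; ties random

    n = len(videos)
    base, extra = divmod(n, k)
    counts = np.zeros(k, dtype=int)
    fold_pos = np.zeros(k)
    fold_tot = np.zeros(k)
    total = np.array([sum(s[0] for s in stats.values()), sum(s[1] for s in stats.values())])
    global_frac = total[1] / total.sum()
    fold_of_video: dict[str, int] = {}

    def has_room(f: int) -> bool:
        if counts[f] >= base + 1:
            return False
        if counts[f] < base:
            return True
        return int((counts == base + 1).sum()) < extra

    for v in shuffled:
        neg, pos = stats[v]
        best_f, best_dev = -1, np.inf
        for f in range(k):
            if not has_room(f):
                continue
            tot = fold_tot[f] + neg + pos
            dev = abs((fold_pos[f] + pos) / tot - global_frac) if tot else 0.0
            if dev < best_dev:
                best_f, best_dev = f, dev
        fold_of_video[v] = best_f
        counts[best_f] += 1
        fold_pos[best_f] += pos
        fold_tot[best_f] += neg + pos

    def fold_devs() -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.abs(np.where(fold_tot > 0, fold_pos / fold_tot, global_frac) - global_frac)

    # pairwise swap refinement: keeps fold sizes, lowers the worst deviation
    for _ in range(200):
        devs = fold_devs()
        if devs.max() <= tolerance:
            break
        improved = False
        for va in videos:
            fa = fold_of_video[va]
            for vb in videos:
                fb = fold_of_video[vb]
                if fb <= fa:
                    continue
                pa, ta = stats[va][1], sum(stats[va])
                pb, tb = stats[vb][1], sum(stats[vb])
                new_pos_a = fold_pos[fa] - pa + pb
                new_pos_b = fold_pos[fb] - pb + pa
                new_tot_a = fold_tot[fa] - ta + tb
                new_tot_b = fold_tot[fb] - tb + ta
                if new_tot_a <= 0 or new_tot_b <= 0:
                    continue
                old = max(devs[fa], devs[fb])
                new = max(
                    abs(new_pos_a / new_tot_a - global_frac),
                    abs(new_pos_b / new_tot_b - global_frac),
                )
                if new < old - 1e-12:
                    fold_of_video[va], fold_of_video[vb] = fb, fa
                    fold_pos[fa], fold_pos[fb] = new_pos_a, new_pos_b
                    fold_tot[fa], fold_tot[fb] = new_tot_a, new_tot_b
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break

    assignment = FoldAssignment(k=k, fold_of_video=fold_of_video)
    dev = max_ratio_deviation(records, assignment)
    if dev > tolerance:
        raise ValueError(
            f"could not stratify folds: class-ratio deviation {dev:.3f} exceeds "
            f"tolerance {tolerance}"
        )
    return assignment


def max_ratio_deviation(records: Sequence[FrameRecord], assignment: FoldAssignment) -> float:
    """Largest |per-fold breakup fraction - global breakup fraction| over folds."""
    counts = np.zeros((assignment.k, 2))
    total = np.zeros(2)
    for rec in records:
        y = rec.binary_label
        if y is None:
            continue
        counts[assignment.fold_of_video[rec.video_id], y] += 1
        total[y] += 1
    global_frac = total[1] / total.sum()
    devs = []
    for f in range(assignment.k):
        n = counts[f].sum()
        if n:
            devs.append(abs(counts[f, 1] / n - global_frac))
    return float(max(devs))


def load_frame_image(ref: Union[str, Path, np.ndarray]) -> np.ndarray:
    """Materialize an image_ref as a grayscale float array in [0, 1]."""
    if isinstance(ref, np.ndarray):
        return np.asarray(ref, dtype=np.float32)
    try:
        img = Image.open(ref).convert("L")
    except OSError as exc:
        raise ValueError(f"unreadable image {ref}: {exc}") from exc
    return np.asarray(img, dtype=np.float32) / 255.0


# --- RandAugment-style policy -------------------------------------------------
# A seeded subset of the standard photometric/geometric ops; magnitude is on
# the usual 0..10 scale.

def _aug_ops(magnitude: int):
    m = magnitude / 10.0

    def rotate(img: Image.Image, sign: float) -> Image.Image:
        return img.rotate(sign * 20 * m, resample=Image.BILINEAR, fillcolor=0)

    def translate_x(img: Image.Image, sign: float) -> Image.Image:
        dx = sign * 0.2 * m * img.width
        return img.transform(img.size, Image.AFFINE, (1, 0, dx, 0, 1, 0), fillcolor=0)

    def translate_y(img: Image.Image, sign: float) -> Image.Image:
        dy = sign * 0.2 * m * img.height
        return img.transform(img.size, Image.AFFINE, (1, 0, 0, 0, 1, dy), fillcolor=0)

    def brightness(img: Image.Image, sign: float) -> Image.Image:
        return ImageEnhance.Brightness(img).enhance(1.0 + sign * 0.5 * m)

    def contrast(img: Image.Image, sign: float) -> Image.Image:
        return ImageEnhance.Contrast(img).enhance(1.0 + sign * 0.5 * m)

    def sharpness(img: Image.Image, sign: float) -> Image.Image:
        return ImageEnhance.Sharpness(img).enhance(1.0 + sign * 0.9 * m)

    return [rotate, translate_x, translate_y, brightness, contrast, sharpness]


def preprocess_frame(
    image: Union[str, Path, np.ndarray],
    target_resolution: int = 32,
    augment: bool = False,
    rng: Optional[np.random.Generator] = None,
    n_ops: int = 2,
    magnitude: int = 9,
) -> np.ndarray:
    """Resize (and optionally augment) a frame into a (1, R, R) float tensor.

    With ``augment`` a random sub-policy of ``n_ops`` operations at the given
    magnitude is applied before resizing; the draw comes from ``rng`` so the
    output is reproducible under a fixed seed.  Values stay in [0, 1].
    """
    arr = load_frame_image(image)
    pil = Image.fromarray((arr * 255).astype(np.uint8), mode="L")
    if augment:
        if rng is None:
            raise ValueError("augment=True requires an rng")
        ops = _aug_ops(magnitude)
        for op_idx in rng.integers(0, len(ops), size=n_ops):
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            pil = ops[int(op_idx)](pil, sign)
    pil = pil.resize((target_resolution, target_resolution), Image.BILINEAR)
    out = np.asarray(pil, dtype=np.float32) / 255.0
    return out[None, :, :]
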