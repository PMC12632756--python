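"""Odor place-preference analysis in a y-maze arena.

Animal positions are recovered from a grayscale frame stack by classic
background subtraction: a background image is built as the pixelwise median
over a subset of frames (the median rejects the transient animals), each
frame is subtracted and thresholded, and connected components become "blob"
detections whose centroids give per-frame positions. Occupancy is then the
normalized left-arm fraction of detections falling inside the two arms,
excluding the central bowl and anything outside the maze.

Frames may be 8-bit or float; they are normalized internally to [0, 1].
Connected components use 8-connectivity; centroids are unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .core import ValidationError

__all__ = [
    "ArenaGeometry",
    "build_background",
    "default_background_subset",
    "detect_positions",
    "arm_occupancy",
]

REGIONS = ("left", "right", "bowl")


@dataclass
class ArenaGeometry:
    """Disjoint region masks (same shape as the frames) labeling the left arm,
    right arm and central bowl; unlabeled pixels are outside the maze."""

    left: np.ndarray
    right: np.ndarray
    bowl: np.ndarray

    def __post_init__(self) -> None:
        for name in REGIONS:
            m = getattr(self, name)
            if m.dtype != bool:
                setattr(self, name, m.astype(bool))
        if not (self.left.shape == self.right.shape == self.bowl.shape):
            raise ValidationError("region masks must share shape")
        overlap = (
            self.left.astype(int) + self.right.astype(int) + self.bowl.astype(int)
        )
        if (overlap > 1).any():
            raise ValidationError("region masks must be disjoint")

    def classify(self, y: float, x: float) -> str:
        """Region containing pixel (row y, col x); 'outside' if none."""
        iy, ix = int(round(y)), int(round(x))
        h, w = self.left.shape
        if not (0 <= iy < h and 0 <= ix < w):
            return "outside"
        for name in REGIONS:
            if getattr(self, name)[iy, ix]:
                return name
        return "outside"

    def flip_horizontal(self) -> "ArenaGeometry":
        return ArenaGeometry(
            left=self.right[:, ::-1], right=self.left[:, ::-1], bowl=self.bowl[:, ::-1]
        )


def _normalize(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if np.issubdtype(frames.dtype, np.integer):
        return frames.astype(np.float64) / np.iinfo(frames.dtype).max
    return frames.astype(np.float64)


def default_background_subset(n_frames: int, max_frames: int = 201) -> np.ndarray:
    """Every k-th frame with k chosen to keep the subset <= ``max_frames``."""
    k = max(1, int(np.ceil(n_frames / max_frames)))
    return np.arange(0, n_frames, k)


def build_background(
    frames: np.ndarray, subset: np.ndarray | list[int] | None = None
) -> np.ndarray:
    """Pixelwise median over a subset of frames.

    With the animals at any given pixel in fewer than half of the sampled
    frames, the median recovers the static scene.
    """
    frames = _normalize(frames)
    if subset is None:
        subset = default_background_subset(len(frames))
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValidationError("background subset must be non-empty")
    if subset.size < 3:
        raise ValidationError("background subset needs >= 3 frames")
    return np.median(frames[subset], axis=0)


def detect_positions(
    frames: np.ndarray,
    background: np.ndarray,
    threshold: float,
    max_animals: int = 1,
    frame_rate: float = 45.0,
) -> pd.DataFrame:
    """Blob detection on background-subtracted frames.

    Per frame, \\|frame - background\\| is thresholded (strict >), 8-connected
    components are extracted, and the ``max_animals`` largest by area become
    detections at their unweighted centroids. Equal areas break ties to the
    topmost, then leftmost centroid. Returns a tidy track table with one row
    per (frame, animal slot): frame, time_s, animal, x, y, detected.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    frames = _normalize(frames)
    background = _normalize(background)
    if frames.shape[1:] != background.shape:
        raise ValidationError("frames and background must share shape")
    rows = []
    for i, frame in enumerate(frames):
        diff = np.abs(frame - background) > threshold
        lab = measure.label(diff, connectivity=2)
        props = measure.regionprops(lab)
        props.sort(key=lambda p: (-p.area, p.centroid[0], p.centroid[1]))
        t = i / frame_rate
        for slot in range(max_animals):
            if slot < len(props):
                cy, cx = props[slot].centroid
                rows.append((i, t, slot, cx, cy, True))
            else:
                rows.append((i, t, slot, np.nan, np.nan, False))
    return pd.DataFrame(
        rows, columns=["frame", "time_s", "animal", "x", "y", "detected"]
    )


def arm_occupancy(
    track: pd.DataFrame, geometry: ArenaGeometry
) -> tuple[float, dict[str, int]]:
    """Normalized left-arm occupancy from cumulative position traces.

    occ = detections_in_left / (detections_in_left + detections_in_right);
    bowl, outside and undetected frames are excluded from the denominator.
    Each detection contributes one count, so with several animals per trial a
    frame can contribute multiple counts (group assay semantics). Returns
    (occupancy, per-region counts); occupancy is NaN (flagged undefined) when
    no detection falls in either arm.
    """
    counts = {"left": 0, "right": 0, "bowl": 0, "outside": 0, "undetected": 0}
    det = track[track["detected"].astype(bool)]
    counts["undetected"] = int(len(track) - len(det))
    for y, x in zip(det["y"].to_numpy(), det["x"].to_numpy()):
        counts[geometry.classify(y, x)] += 1
    arm = counts["left"] + counts["right"]
    occ = counts["left"] / arm if arm > 0 else float("nan")
    return occ, counts
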