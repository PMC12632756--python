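"""Core domain types and interval algebra for behavioral annotation data.

Time is real-valued seconds; every bout is a half-open interval
``[start, stop)``. Frames are 0-based and frame ``i`` at rate ``fps`` covers
``[i/fps, (i+1)/fps)``. These conventions eliminate double counting at
boundaries and make the frame/bout conversions exact inverses on
frame-aligned data.

The two interchangeable trial representations are :class:`BoutTable`
(a list of labeled intervals, the pipeline's central currency) and
:class:`FrameLabelTable` (per-frame binary indicators per fly and action,
the native output of automated behavior classifiers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_VOCABULARY",
    "AGGRESSIVE_ACTIONS",
    "COURTSHIP_ACTIONS",
    "Bout",
    "BoutTable",
    "FrameLabelTable",
    "StimBlock",
    "StimSchedule",
    "TrialMetadata",
    "ValidationError",
    "merge_intervals",
    "interval_union_length",
    "frames_to_bouts",
    "bouts_to_frames",
    "normalize_bouts",
    "truncate_at_copulation",
]

#: Aggressive actions scored in male-male interactions.
AGGRESSIVE_ACTIONS = (
    "threat", "pump", "charge", "lunge", "hold", "tussle", "headbutt", "barrage",
)

#: Courtship actions (UWE = unilateral wing extension, the canonical male
#: courtship proxy; BWE = bilateral wing extension).
COURTSHIP_ACTIONS = (
    "UWE", "BWE", "row", "circle", "copulation attempt",
)

#: Default per-trial action vocabulary: the scored aggressive and courtship
#: actions plus the terminal "copulation" state used for truncation.
DEFAULT_VOCABULARY = AGGRESSIVE_ACTIONS + COURTSHIP_ACTIONS + ("copulation",)


class ValidationError(ValueError):
    """Raised when input data violate a documented invariant."""


@dataclass(frozen=True)
class Bout:
    """One maximal interval during which ``fly_id`` performs ``action``.

    ``target_id`` identifies the fly the action is directed at; it is only
    needed for trio analyses (e.g. female- vs male-directed courtship).
    """

    fly_id: str
    action: str
    start: float
    stop: float
    target_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.start >= 0):
            raise ValidationError(f"bout start must be >= 0, got {self.start}")
        if not (self.stop > self.start):
            raise ValidationError(
                f"bout stop must exceed start, got [{self.start}, {self.stop})"
            )

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass
class BoutTable:
    """All bouts of one trial plus trial-level timing metadata.

    ``vocabulary`` declares the admissible action names; bouts with actions
    outside it are rejected rather than silently dropped. When ``None`` the
    vocabulary is taken to be the set of actions present.
    """

    trial_id: str
    bouts: list[Bout]
    trial_duration: float
    copulation_time: float | None = None
    vocabulary: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.trial_duration < 0:
            raise ValidationError("trial_duration must be non-negative")
        for b in self.bouts:
            if b.start < 0 or b.stop > self.trial_duration + 1e-9:
                raise ValidationError(
                    f"bout [{b.start}, {b.stop}) outside trial [0, {self.trial_duration}]"
                )
            if self.vocabulary is not None and b.action not in self.vocabulary:
                raise ValidationError(
                    f"unknown action {b.action!r}; declared vocabulary: {self.vocabulary}"
                )
        if (
            self.copulation_time is not None
            and self.copulation_time > self.trial_duration
        ):
            raise ValidationError("copulation_time exceeds trial_duration")

    @property
    def actions(self) -> tuple[str, ...]:
        if self.vocabulary is not None:
            return self.vocabulary
        seen: dict[str, None] = {}
        for b in self.bouts:
            seen.setdefault(b.action, None)
        return tuple(seen)

    @property
    def fly_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.bouts:
            seen.setdefault(b.fly_id, None)
        return tuple(seen)

    def select(self, fly_id: str | None = None, action: str | None = None,
               target_id: str | None = None) -> list[Bout]:
        """Bouts matching all given filters (None = no constraint)."""
        out = []
        for b in self.bouts:
            if fly_id is not None and b.fly_id != fly_id:
                continue
            if action is not None and b.action != action:
                continue
            if target_id is not None and b.target_id != target_id:
                continue
            out.append(b)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame view (trial_id, fly_id, action, start_s, stop_s, target_id)."""
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "fly_id": [b.fly_id for b in self.bouts],
                "action": [b.action for b in self.bouts],
                "start_s": [b.start for b in self.bouts],
                "stop_s": [b.stop for b in self.bouts],
                "target_id": [b.target_id for b in self.bouts],
            }
        )


@dataclass
class FrameLabelTable:
    """Per-frame binary action indicators per fly at a known frame rate.

    ``labels`` is a frames x (fly, action) DataFrame with a two-level column
    index and entries in {0, 1}.
    """

    trial_id: str
    frame_rate: float
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if not isinstance(self.labels.columns, pd.MultiIndex) or self.labels.columns.nlevels != 2:
            raise ValidationError("labels must have (fly_id, action) column MultiIndex")
        vals = self.labels.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValidationError("label entries must be binary")
        self.labels = self.labels.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def series(self, fly_id: str, action: str) -> np.ndarray:
        return self.labels[(fly_id, action)].to_numpy()


@dataclass(frozen=True)
class StimBlock:
    """One photostimulation block of an optogenetic protocol."""

    onset: float
    offset: float
    frequency_hz: float
    intensity_uw_mm2: float = 0.0
    pulse_width_ms: float = 10.0

    def __post_init__(self) -> None:
        if not (self.offset > self.onset):
            raise ValidationError("block offset must exceed onset")


@dataclass
class StimSchedule:
    """Ordered, non-overlapping photostimulation blocks within one trial."""

    blocks: list[StimBlock]
    trial_duration: float

    def __post_init__(self) -> None:
        prev = 0.0
        for blk in self.blocks:
            if blk.onset < prev - 1e-9:
                raise ValidationError("blocks must be time-ordered and non-overlapping")
            prev = blk.offset
        if self.blocks and self.blocks[-1].offset > self.trial_duration + 1e-9:
            raise ValidationError("schedule exceeds trial duration")


@dataclass
class TrialMetadata:
    """Descriptive per-trial metadata; carried through, never computed on."""

    species: str = ""
    sex: dict[str, str] = field(default_factory=dict)
    housing: dict[str, str] = field(default_factory=dict)
    chamber: str = ""
    food: str = ""
    assay: str = ""


# ---------------------------------------------------------------------------
# interval algebra


def merge_intervals(
    intervals: Iterable[tuple[float, float]], merge_gap: float = 0.0
) -> list[tuple[float, float]]:
    """Union of half-open intervals, additionally fusing gaps < ``merge_gap``.

    At ``merge_gap == 0`` abutting intervals ([0,1), [1,2)) are fused, which
    preserves total covered length.
    """
    if merge_gap < 0:
        raise ValidationError("merge_gap must be >= 0")
    ivs = sorted(intervals)
    out: list[tuple[float, float]] = []
    for s, e in ivs:
        if out and s - out[-1][1] <= merge_gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_union_length(intervals: Iterable[tuple[float, float]]) -> float:
    """Total length covered by the union of the intervals."""
    return float(sum(e - s for s, e in merge_intervals(intervals)))


# ---------------------------------------------------------------------------
# representation conversions


def frames_to_bouts(labels: FrameLabelTable) -> BoutTable:
    """Convert per-frame indicators to bouts.

    A bout is a maximal run of consecutive 1-frames of one (fly, action)
    series: start = first_frame/fps, stop = (last_frame + 1)/fps.
    """
    fps = labels.frame_rate
    bouts: list[Bout] = []
    for fly, action in labels.labels.columns:
        x = labels.series(fly, action)
        if not x.any():
            continue
        padded = np.concatenate(([0], x, [0]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        for s, e in zip(starts, stops):
            bouts.append(Bout(fly, action, s / fps, e / fps))
    bouts.sort(key=lambda b: (b.fly_id, b.action, b.start))
    return BoutTable(
        trial_id=labels.trial_id,
        bouts=bouts,
        trial_duration=labels.duration,
    )


def bouts_to_frames(
    bouts: BoutTable,
    frame_rate: float,
    columns: Sequence[tuple[str, str]] | None = None,
) -> FrameLabelTable:
    """Rasterize bouts onto a frame grid.

    Frame ``i`` is set iff its interval ``[i/fps, (i+1)/fps)`` intersects a
    bout of that (fly, action) — faithful rasterization rather than midpoint
    sampling, so ``frames_to_bouts`` inverts it exactly on frame-aligned
    tables.
    """
    if frame_rate <= 0:
        raise ValidationError("frame_rate must be positive")
    n_frames = int(np.ceil(bouts.trial_duration * frame_rate - 1e-9))
    if columns is None:
        cols = sorted({(b.fly_id, b.action) for b in bouts.bouts})
    else:
        cols = list(columns)
    mat = np.zeros((n_frames, len(cols)), dtype=np.uint8)
    col_idx = {c: j for j, c in enumerate(cols)}
    eps = 1e-9
    for b in bouts.bouts:
        j = col_idx.get((b.fly_id, b.action))
        if j is None:
            raise ValidationError(
                f"bout column ({b.fly_id}, {b.action}) not in requested columns"
            )
        # first frame whose interval intersects [start, stop): floor(start*fps)
        # last intersecting frame: the one containing stop, excluded if stop
        # is exactly on a frame edge (half-open bout).
        first = int(np.floor(b.start * frame_rate + eps))
        last = int(np.ceil(b.stop * frame_rate - eps))
        mat[first:min(last, n_frames), j] = 1
    df = pd.DataFrame(
        mat, columns=pd.MultiIndex.from_tuples(cols, names=["fly_id", "action"])
    )
    return FrameLabelTable(trial_id=bouts.trial_id, frame_rate=frame_rate, labels=df)


def normalize_bouts(bouts: BoutTable, merge_gap: float = 0.0) -> BoutTable:
    """Canonicalize a bout table.

    Sorts by (fly, action, start) and merges overlapping or abutting bouts of
    the same (fly, action, target); gaps smaller than ``merge_gap`` are fused
    as well. With ``merge_gap == 0`` the total covered time per series is
    conserved, and the operation is idempotent.
    """
    groups: dict[tuple[str, str, str | None], list[tuple[float, float]]] = {}
    for b in bouts.bouts:
        groups.setdefault((b.fly_id, b.action, b.target_id), []).append(
            (b.start, b.stop)
        )
    merged: list[Bout] = []
    for (fly, action, target), ivs in groups.items():
        for s, e in merge_intervals(ivs, merge_gap):
            merged.append(Bout(fly, action, s, e, target))
    merged.sort(key=lambda b: (b.fly_id, b.action, b.start))
    return replace(bouts, bouts=merged)


def truncate_at_copulation(
    bouts: BoutTable, copulation_action: str = "copulation"
) -> BoutTable:
    """Cut a trial at the point of copulation.

    Bouts after the copulation time are dropped, straddling bouts are clipped,
    and the effective ``trial_duration`` becomes the copulation latency — the
    convention under which all subsequent rates and fractions are normalized
    by time to copulation rather than total interaction time. If
    ``copulation_time`` is not set explicitly, the onset of the earliest bout
    named ``copulation_action`` is used; if neither exists the table is
    returned unchanged.
    """
    t = bouts.copulation_time
    if t is None:
        cop = bouts.select(action=copulation_action)
        if not cop:
            return bouts
        t = min(b.start for b in cop)
    if t > bouts.trial_duration:
        raise ValidationError("copulation_time exceeds trial_duration")
    clipped = [
        Bout(b.fly_id, b.action, b.start, min(b.stop, t), b.target_id)
        for b in bouts.bouts
        if b.start < t
    ]
    return replace(bouts, bouts=clipped, trial_duration=t, copulation_time=t)
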