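"""Behavioral metrics: time budgets, rates, latencies, expressivity traces,
peri-photostimulation alignment, and stimulation-epoch aggregation.

Conventions shared by all operations:

* windows are half-open ``[start, stop)`` like bouts; an onset exactly at a
  window's start counts, one at its stop does not;
* time fractions use union semantics — duplicated or overlapping bouts of the
  same action never count twice;
* sliding windows are centered and truncated at trial edges (no padding);
* s.e.m. across trials uses the sample standard deviation (n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    BoutTable,
    FrameLabelTable,
    StimSchedule,
    ValidationError,
    interval_union_length,
)

__all__ = [
    "MetricsParams",
    "Latency",
    "EpochSpec",
    "build_epochs",
    "time_fraction",
    "event_rate",
    "latency_to_first",
    "sliding_expressivity",
    "peristimulus_fraction",
    "sham_bout_fraction",
    "epoch_summary",
]


@dataclass(frozen=True)
class MetricsParams:
    """Tunable windows and thresholds.

    sliding_window
        Width (s) of the centered sliding window for expressivity traces.
    peri_pre / peri_post_after_offset
        Seconds shown before block onset / after block offset in
        peri-stimulation traces ("six-second windows surrounding PS blocks"
        for 2-s blocks: 2 + 2 + 2).
    onset_filter
        A (fly, block) sample qualifies when the action is ON at some frame in
        ``[onset - onset_filter, onset]`` ("spontaneous courtship within a
        half second of PS onset").
    sham_bout_threshold
        Minimum duration (s, strict >) for a spontaneous bout to count toward
        the sham baseline fraction.
    onset_filter_symmetric
        Alternative reading of "within a half second": use
        ``[onset - onset_filter, onset + onset_filter]``.
    """

    sliding_window: float = 10.0
    peri_pre: float = 2.0
    peri_post_after_offset: float = 2.0
    onset_filter: float = 0.5
    sham_bout_threshold: float = 2.0
    onset_filter_symmetric: bool = False

    def __post_init__(self) -> None:
        for name in ("sliding_window", "peri_pre", "peri_post_after_offset",
                     "onset_filter", "sham_bout_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class Latency:
    """Latency to first event; ``censored`` marks trials where it never occurred.

    A censored latency carries the trial duration as its value so rank tests
    can place it at the distribution's end, but it is never silently equal to
    a real latency.
    """

    value: float
    censored: bool = False


@dataclass
class EpochSpec:
    """Named epochs partitioning a stimulation trial.

    ``baseline`` is the period before the first PS block ("PS-"); ``blocks``
    the PS blocks themselves; ``ibis`` the inter-block intervals; ``post`` the
    period after the final block. The pooled "PS+" definitions are the blocks
    (courtship-style induction) or the IBIs plus post period (rebound-style).
    """

    baseline: tuple[float, float]
    blocks: list[tuple[float, float]]
    ibis: list[tuple[float, float]]
    post: tuple[float, float] | None

    def all_epochs(self) -> list[tuple[str, tuple[float, float]]]:
        out: list[tuple[str, tuple[float, float]]] = []
        if self.baseline[1] > self.baseline[0]:
            out.append(("baseline", self.baseline))
        for i, w in enumerate(self.blocks):
            out.append((f"PS{i + 1}", w))
        for i, w in enumerate(self.ibis):
            out.append((f"IBI{i + 1}", w))
        if self.post is not None and self.post[1] > self.post[0]:
            out.append(("post", self.post))
        return out


def build_epochs(schedule: StimSchedule) -> EpochSpec:
    """Partition ``[0, trial_duration]`` into baseline / PS / IBI / post epochs."""
    T = schedule.trial_duration
    if not schedule.blocks:
        return EpochSpec(baseline=(0.0, T), blocks=[], ibis=[], post=None)
    blocks = [(b.onset, b.offset) for b in schedule.blocks]
    baseline = (0.0, blocks[0][0])
    ibis = [
        (blocks[i][1], blocks[i + 1][0])
        for i in range(len(blocks) - 1)
        if blocks[i + 1][0] > blocks[i][1]
    ]
    post = (blocks[-1][1], T) if T > blocks[-1][1] else None
    return EpochSpec(baseline=baseline, blocks=blocks, ibis=ibis, post=post)


def _window_check(window: tuple[float, float]) -> None:
    if window[1] <= window[0]:
        raise ValidationError("window must have positive length")


def time_fraction(
    bouts: BoutTable, action: str | Iterable[str], window: tuple[float, float]
) -> float:
    """Fraction of ``window`` covered by the union of matching bouts.

    ``action`` may be a single name or an iterable (e.g. all aggressive
    actions for a cumulative time budget). Overlapping bouts count once.
    """
    _window_check(window)
    actions = {action} if isinstance(action, str) else set(action)
    lo, hi = window
    ivs = [
        (max(b.start, lo), min(b.stop, hi))
        for b in bouts.bouts
        if b.action in actions and b.stop > lo and b.start < hi
    ]
    return interval_union_length(ivs) / (hi - lo)


def event_rate(
    bouts: BoutTable, action: str | Iterable[str], window: tuple[float, float]
) -> float:
    """Bout onsets per minute within ``window`` (e.g. lunges per minute)."""
    _window_check(window)
    actions = {action} if isinstance(action, str) else set(action)
    lo, hi = window
    n = sum(1 for b in bouts.bouts if b.action in actions and lo <= b.start < hi)
    return n * 60.0 / (hi - lo)


def latency_to_first(bouts: BoutTable, action: str | Iterable[str]) -> Latency:
    """Onset of the earliest matching bout, or a censored trial-duration value."""
    actions = {action} if isinstance(action, str) else set(action)
    onsets = [b.start for b in bouts.bouts if b.action in actions]
    if not onsets:
        return Latency(value=bouts.trial_duration, censored=True)
    return Latency(value=min(onsets), censored=False)


def _sliding_mean(x: np.ndarray, m: int) -> np.ndarray:
    """Centered moving average over ``m`` frames with edge truncation.

    The window at frame i is ``[i - m//2, i - m//2 + m)``; ``m == 1``
    reproduces the raw trace.
    """
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    i = np.arange(n)
    lo = np.maximum(i - m // 2, 0)
    hi = np.minimum(i - m // 2 + m, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def sliding_expressivity(
    group: Sequence[FrameLabelTable],
    action: str,
    params: MetricsParams | None = None,
    fly_id: str | None = None,
) -> pd.DataFrame:
    """Mean +/- s.e.m. expressivity trace across trials.

    Per trial: fraction of frames labeled 1 within a centered sliding window
    of ``params.sliding_window`` seconds, truncated at trial edges. Frames
    from all flies carrying the action are pooled per trial unless ``fly_id``
    restricts to one. Returns a tidy frame (time_s, mean, sem, n); with a
    single trial the s.e.m. column is 0 and flagged via ``df.attrs['sem_defined']``.
    """
    params = params or MetricsParams()
    if len(group) == 0:
        raise ValidationError("group must contain at least one trial")
    fps = group[0].frame_rate
    n_frames = group[0].n_frames
    for t in group:
        if t.frame_rate != fps or t.n_frames != n_frames:
            raise ValidationError("trials must share frame_rate and duration")
    m = max(int(round(params.sliding_window * fps)), 1)
    traces = []
    for t in group:
        cols = [
            c for c in t.labels.columns
            if c[1] == action and (fly_id is None or c[0] == fly_id)
        ]
        if not cols:
            raise ValidationError(f"action {action!r} absent from trial {t.trial_id}")
        x = t.labels[cols].to_numpy().mean(axis=1)
        traces.append(_sliding_mean(x, m))
    arr = np.asarray(traces)
    mean = arr.mean(axis=0)
    if len(group) > 1:
        sem = arr.std(axis=0, ddof=1) / np.sqrt(len(group))
        sem_defined = True
    else:
        sem = np.zeros(n_frames)
        sem_defined = False
    df = pd.DataFrame(
        {"time_s": np.arange(n_frames) / fps, "mean": mean, "sem": sem,
         "n": len(group)}
    )
    df.attrs["sem_defined"] = sem_defined
    return df


def peristimulus_fraction(
    group: Sequence[tuple[FrameLabelTable, StimSchedule]],
    action: str,
    params: MetricsParams | None = None,
) -> pd.DataFrame:
    """Event-aligned fraction-of-samples trace around photostimulation blocks.

    A (fly, block) sample qualifies when the action is ON at some frame in the
    onset-filter window (default ``[onset - 0.5 s, onset]``). The returned
    trace spans relative time ``[-peri_pre, block_length + peri_post]`` and
    gives, per aligned frame, the fraction of qualifying samples with the
    action ON. ``df.attrs['n_samples']`` carries the qualifying count; zero
    qualifying samples yield an empty frame with the count 0.
    """
    params = params or MetricsParams()
    if len(group) == 0:
        raise ValidationError("group must contain at least one trial")
    fps = group[0][0].frame_rate
    block_len = None
    rows = []
    for table, schedule in group:
        if table.frame_rate != fps:
            raise ValidationError("trials must share frame_rate")
        for fly in table.labels.columns.get_level_values(0).unique():
            if (fly, action) not in table.labels.columns:
                continue
            x = table.series(fly, action)
            for blk in schedule.blocks:
                L = blk.offset - blk.onset
                if block_len is None:
                    block_len = L
                elif abs(L - block_len) > 1e-9:
                    raise ValidationError("blocks must share duration within the aligned set")
                onset_f = int(round(blk.onset * fps))
                if params.onset_filter_symmetric:
                    f0 = int(np.floor((blk.onset - params.onset_filter) * fps))
                    f1 = int(np.ceil((blk.onset + params.onset_filter) * fps))
                else:
                    f0 = int(np.floor((blk.onset - params.onset_filter) * fps))
                    f1 = onset_f + 1
                f0 = max(f0, 0)
                if not x[f0:min(f1, len(x))].any():
                    continue
                pre = int(round(params.peri_pre * fps))
                post = int(round((L + params.peri_post_after_offset) * fps))
                lo, hi = onset_f - pre, onset_f + post
                seg = np.zeros(pre + post, dtype=float)
                src_lo, src_hi = max(lo, 0), min(hi, len(x))
                seg[src_lo - lo: src_hi - lo] = x[src_lo:src_hi]
                rows.append(seg)
    if not rows:
        df = pd.DataFrame({"time_s": [], "fraction": [], "n": []})
        df.attrs["n_samples"] = 0
        return df
    arr = np.asarray(rows)
    pre = int(round(params.peri_pre * fps))
    t = (np.arange(arr.shape[1]) - pre) / fps
    df = pd.DataFrame({"time_s": t, "fraction": arr.mean(axis=0), "n": len(rows)})
    df.attrs["n_samples"] = len(rows)
    return df


def sham_bout_fraction(
    bouts: BoutTable, action: str, params: MetricsParams | None = None
) -> float:
    """Fraction of matching bouts longer than the sham-bout threshold.

    Used as the sham-trial baseline for stimulation-driven interruption:
    the fraction of spontaneous bouts lasting more than (strict) the
    threshold (default 2 s). Undefined with zero matching bouts.
    """
    params = params or MetricsParams()
    durs = [b.duration for b in bouts.bouts if b.action == action]
    if not durs:
        raise ValidationError("no matching bouts; sham baseline undefined")
    return sum(1 for d in durs if d > params.sham_bout_threshold) / len(durs)


def epoch_summary(
    bouts: BoutTable,
    schedule: StimSchedule,
    action: str | Iterable[str],
    aggregate: str = "fraction",
) -> pd.DataFrame:
    """Per-epoch and pooled behavior aggregates for a stimulation trial.

    ``aggregate`` is ``"fraction"`` (time fraction, union semantics),
    ``"count"`` (bout onsets) or ``"rate"`` (onsets per minute). Rows cover
    every epoch plus three pooled definitions: ``PS-`` (baseline),
    ``PS+blocks`` (all PS blocks pooled — induction during stimulation) and
    ``PS+rebound`` (IBIs plus the post-final period pooled — rebound-style
    induction between and after stimulations).
    """
    if abs(schedule.trial_duration - bouts.trial_duration) > 1e-6:
        raise ValidationError("schedule inconsistent with trial duration")
    spec = build_epochs(schedule)

    def agg(windows: list[tuple[float, float]]) -> tuple[float, float]:
        total = sum(hi - lo for lo, hi in windows)
        if total == 0:
            return np.nan, 0.0
        actions = {action} if isinstance(action, str) else set(action)
        if aggregate == "fraction":
            cov = sum(
                time_fraction(bouts, actions, w) * (w[1] - w[0]) for w in windows
            )
            return cov / total, total
        n = sum(
            1
            for b in bouts.bouts
            if b.action in actions
            and any(lo <= b.start < hi for lo, hi in windows)
        )
        if aggregate == "count":
            return float(n), total
        if aggregate == "rate":
            return n * 60.0 / total, total
        raise ValidationError(f"unknown aggregate {aggregate!r}")

    rows = []
    for name, w in spec.all_epochs():
        v, dur = agg([w])
        rows.append({"epoch": name, "value": v, "duration_s": dur})
    pooled = [
        ("PS-", [spec.baseline] if spec.baseline[1] > spec.baseline[0] else []),
        ("PS+blocks", spec.blocks),
        ("PS+rebound", spec.ibis + ([spec.post] if spec.post else [])),
    ]
    for name, ws in pooled:
        v, dur = agg(ws)
        rows.append({"epoch": name, "value": v, "duration_s": dur})
    return pd.DataFrame(rows)
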