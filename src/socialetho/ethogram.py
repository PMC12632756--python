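"""Ethogram construction: action frequencies and transition-edge weights.

An ethogram summarizes a behavioral repertoire as a graph. Nodes are bout
counts per action, sized by frequency normalized to the summed bouts across
all actions. A directed edge a -> b carries the fraction of bouts of action a
(arrow origin) for which at least one bout of action b (arrow destination)
began within the transition cutoff after a's offset — 1 second by default.

The transition trigger window is ``(offset_a, offset_a + cutoff]`` measured
offset-to-onset: a bout of b whose onset precedes a's offset (i.e. overlaps a)
does not count as a transition from a, and a gap exactly equal to the cutoff
does (closed upper bound). Each source bout contributes a 0/1 indicator per
target action, so multiple qualifying followers of the same action count once.
Both conventions are configurable.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field

import numpy as np

from .core import BoutTable, ValidationError

__all__ = ["EthogramParams", "Ethogram", "build_ethogram", "ethogram_oracle"]


@dataclass(frozen=True)
class EthogramParams:
    """Parameters of ethogram construction.

    cutoff
        Transition time window in seconds (offset of source bout to onset of
        target bout); default 1.0 s.
    actor_scope
        ``"pair-pooled"`` pools both flies' bouts into one stream (ethograms
        describe the pair); ``"per-fly"`` builds transitions only within each
        fly's own stream.
    include_self_transitions
        Whether a -> a edges are counted.
    count_overlap_onsets
        If True, a target onset inside the source bout (onset <= offset_a but
        > onset_a) also triggers the edge; default False (strictly after the
        source bout ends).
    """

    cutoff: float = 1.0
    actor_scope: str = "pair-pooled"
    include_self_transitions: bool = True
    count_overlap_onsets: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be positive")
        if self.actor_scope not in ("pair-pooled", "per-fly"):
            raise ValidationError("actor_scope must be 'pair-pooled' or 'per-fly'")


@dataclass
class Ethogram:
    """Node frequencies and transition-weight matrix over an action vocabulary."""

    actions: tuple[str, ...]
    node_count: np.ndarray
    node_freq: np.ndarray
    edge_weight: np.ndarray
    n_bouts_total: int
    params: EthogramParams = field(default_factory=EthogramParams)

    def row_defined(self) -> np.ndarray:
        """Boolean mask of actions with at least one bout (defined edge rows)."""
        return self.node_count > 0

    def edge(self, a: str, b: str) -> float:
        return float(self.edge_weight[self.actions.index(a), self.actions.index(b)])

    def to_dict(self) -> dict:
        return {
            "actions": list(self.actions),
            "node_count": self.node_count.tolist(),
            "node_freq": self.node_freq.tolist(),
            "edge_weight": self.edge_weight.tolist(),
            "n_bouts_total": self.n_bouts_total,
            "params": {
                "cutoff": self.params.cutoff,
                "actor_scope": self.params.actor_scope,
                "include_self_transitions": self.params.include_self_transitions,
                "count_overlap_onsets": self.params.count_overlap_onsets,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_dot(self, min_edge: float = 0.0) -> str:
        """Graphviz DOT export (no layout aesthetics, just structure)."""
        lines = ["digraph ethogram {"]
        for a, f in zip(self.actions, self.node_freq):
            lines.append(f'  "{a}" [width={max(f, 0.05):.3f}];')
        for i, a in enumerate(self.actions):
            for j, b in enumerate(self.actions):
                w = self.edge_weight[i, j]
                if w > min_edge:
                    lines.append(f'  "{a}" -> "{b}" [weight={w:.3f}];')
        lines.append("}")
        return "\n".join(lines)


def _streams(bouts: BoutTable, params: EthogramParams):
    """Bout streams within which transitions are scored."""
    if params.actor_scope == "pair-pooled":
        return [list(bouts.bouts)]
    return [bouts.select(fly_id=f) for f in bouts.fly_ids]


def build_ethogram(bouts: BoutTable, params: EthogramParams | None = None) -> Ethogram:
    """Build an ethogram from a normalized bout table.

    Uses per-action sorted onset lists and binary search, O(n log n) overall.
    An empty bout table yields an ethogram with zero counts (not an error);
    an empty declared vocabulary is an error.
    """
    params = params or EthogramParams()
    actions = bouts.actions
    if len(actions) == 0 and bouts.bouts:
        raise ValidationError("empty action vocabulary")
    idx = {a: i for i, a in enumerate(actions)}
    k = len(actions)
    node_count = np.zeros(k, dtype=int)
    triggered = np.zeros((k, k), dtype=float)
    for stream in _streams(bouts, params):
        onsets: dict[str, list[float]] = {a: [] for a in actions}
        for b in stream:
            onsets[b.action].append(b.start)
        for a in actions:
            onsets[a].sort()
        for b in stream:
            i = idx[b.action]
            node_count[i] += 1
            lo = b.start if params.count_overlap_onsets else b.stop
            hi = b.stop + params.cutoff
            for a in actions:
                if a == b.action and not params.include_self_transitions:
                    continue
                ons = onsets[a]
                # onset in (lo, hi] — closed at the cutoff
                left = bisect.bisect_right(ons, lo)
                right = bisect.bisect_right(ons, hi)
                if right > left:
                    triggered[i, idx[a]] += 1.0
    total = int(node_count.sum())
    node_freq = node_count / total if total > 0 else np.zeros(k)
    with np.errstate(invalid="ignore", divide="ignore"):
        edge = np.where(
            node_count[:, None] > 0, triggered / np.maximum(node_count[:, None], 1), 0.0
        )
    return Ethogram(
        actions=actions,
        node_count=node_count,
        node_freq=node_freq,
        edge_weight=edge,
        n_bouts_total=total,
        params=params,
    )


def ethogram_oracle(bouts: BoutTable, params: EthogramParams | None = None) -> Ethogram:
    """Brute-force O(n^2) all-pairs reference implementation.

    Identical contract to :func:`build_ethogram`; kept deliberately naive so
    the two can be checked against each other exactly.
    """
    params = params or EthogramParams()
    actions = bouts.actions
    if len(actions) == 0 and bouts.bouts:
        raise ValidationError("empty action vocabulary")
    idx = {a: i for i, a in enumerate(actions)}
    k = len(actions)
    node_count = np.zeros(k, dtype=int)
    triggered = np.zeros((k, k), dtype=float)
    for stream in _streams(bouts, params):
        for src in stream:
            i = idx[src.action]
            node_count[i] += 1
            lo = src.start if params.count_overlap_onsets else src.stop
            hi = src.stop + params.cutoff
            hit = set()
            for tgt in stream:
                if tgt is src:
                    continue
                if tgt.action == src.action and not params.include_self_transitions:
                    continue
                if lo < tgt.start <= hi:
                    hit.add(tgt.action)
            for a in hit:
                triggered[i, idx[a]] += 1.0
    total = int(node_count.sum())
    node_freq = node_count / total if total > 0 else np.zeros(k)
    edge = np.where(
        node_count[:, None] > 0, triggered / np.maximum(node_count[:, None], 1), 0.0
    )
    return Ethogram(
        actions=actions,
        node_count=node_count,
        node_freq=node_freq,
        edge_weight=edge,
        n_bouts_total=total,
        params=params,
    )
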