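"""Social-behavior indices: preference, pair bias, normalized ovipositor
extrusion, receptivity, and dominance carry-over.

All two-argument indices are difference-over-sum contrasts,
``(a - b) / (a + b)``, bounded in [-1, 1], antisymmetric under swapping the
arguments and invariant to rescaling both by the same positive factor. A 0/0
contrast is *undefined* — an animal that never performed either behavior
carries no preference information — and undefined values are flagged and
excluded from group statistics rather than coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import BoutTable, ValidationError, interval_union_length

__all__ = [
    "IndexParams",
    "DominanceRecord",
    "preference_index",
    "pair_bias",
    "normalized_oe",
    "receptivity_index",
    "dominance_carryover",
]


@dataclass(frozen=True)
class IndexParams:
    """Binarization thresholds and filters.

    oe_binarize_threshold
        A female counts as rejecting when her normalized OE exceeds this
        (strict >); default -0.25.
    ws_binarize_threshold
        A female counts as receptive when wing-spreading time exceeds this
        (strict >); default 0.
    dominance_min_courtship
        Pairs with less total male-directed courtship (s) in the paired phase
        are excluded from carry-over analysis; default 20 s.
    """

    oe_binarize_threshold: float = -0.25
    ws_binarize_threshold: float = 0.0
    dominance_min_courtship: float = 20.0

    def __post_init__(self) -> None:
        if self.dominance_min_courtship < 0:
            raise ValidationError("dominance_min_courtship must be >= 0")


@dataclass
class DominanceRecord:
    """Outcome of a paired-then-trio dominance carry-over comparison."""

    pair_id: str
    phase1_bias: float | None
    phase1_total_courtship: float
    dominant_id: str | None
    phase2_female_bias: float | None
    phase2_dominant_id: str | None
    carried_over: bool | None
    excluded: bool
    copulator_id: str | None = None


def preference_index(t_a: float, t_b: float) -> float | None:
    """Difference in time spent on each target normalized by the sum.

    ``(t_a - t_b) / (t_a + t_b)``; returns ``None`` (undefined) when both
    are zero.
    """
    if t_a < 0 or t_b < 0:
        raise ValidationError("durations must be non-negative")
    tot = t_a + t_b
    if tot == 0:
        return None
    return (t_a - t_b) / tot


def pair_bias(
    bouts: BoutTable, action: str, flies: tuple[str, str] | None = None
) -> tuple[float | None, str | None]:
    """Behavioral bias between the two flies of a pair.

    Returns ``(bias, dominant_id)`` where bias is the preference index of the
    two flies' total action durations (union semantics per fly, first fly as
    the positive pole) and the dominant fly is the one with the larger total.
    Exactly equal nonzero totals give bias 0 and no dominant; two totals of
    zero give an undefined bias. ``flies`` names the two flies explicitly
    (needed when one fly has no bouts at all); otherwise both must appear in
    the table.
    """
    if flies is None:
        flies = bouts.fly_ids
    if len(flies) != 2:
        raise ValidationError(f"pair_bias needs exactly 2 flies, got {len(flies)}")
    totals = [
        interval_union_length(
            [(b.start, b.stop) for b in bouts.select(fly_id=f, action=action)]
        )
        for f in flies
    ]
    bias = preference_index(totals[0], totals[1])
    if bias is None or bias == 0:
        return bias, None
    return bias, flies[0] if totals[0] > totals[1] else flies[1]


def normalized_oe(t_oe: float, t_uwe: float) -> float | None:
    """Female ovipositor extrusion normalized to male courtship.

    Difference divided by sum of time spent by the female in OE and by the
    male in unilateral wing extension; ``None`` when both are zero (the male
    never courted and the female never extruded).
    """
    return preference_index(t_oe, t_uwe)


def receptivity_index(
    females: Sequence[tuple[float, float | None]],
    params: IndexParams | None = None,
) -> float:
    """Cohort-level receptivity: mean of per-female (WS - OE) binary contrasts.

    Each female contributes ``ws_bin - oe_bin`` in {-1, 0, 1}, where
    ``ws_bin = [ws_time > 0]`` and ``oe_bin = [oe_norm > -0.25]`` under the
    default thresholds; a female with undefined normalized OE contributes
    ``oe_bin = 0`` (absence of rejection is not rejection). The index is the
    sum normalized by the number of females scored.
    """
    params = params or IndexParams()
    if len(females) == 0:
        raise ValidationError("receptivity_index needs at least one female")
    total = 0
    for ws_time, oe_norm in females:
        if ws_time < 0:
            raise ValidationError("ws_time must be non-negative")
        ws_bin = 1 if ws_time > params.ws_binarize_threshold else 0
        oe_bin = (
            1 if (oe_norm is not None and oe_norm > params.oe_binarize_threshold) else 0
        )
        total += ws_bin - oe_bin
    return total / len(females)


def per_female_scores(
    females: Sequence[tuple[float, float | None]],
    params: IndexParams | None = None,
) -> list[int]:
    """Per-female (ws_bin - oe_bin) values in {-1, 0, 1}."""
    params = params or IndexParams()
    out = []
    for ws_time, oe_norm in females:
        ws_bin = 1 if ws_time > params.ws_binarize_threshold else 0
        oe_bin = (
            1 if (oe_norm is not None and oe_norm > params.oe_binarize_threshold) else 0
        )
        out.append(ws_bin - oe_bin)
    return out


def dominance_carryover(
    phase1: BoutTable,
    phase2: BoutTable,
    female_id: str,
    courtship_action: str = "UWE",
    params: IndexParams | None = None,
    copulator_id: str | None = None,
    male_ids: tuple[str, str] | None = None,
) -> DominanceRecord:
    """Does male-directed courtship dominance in a pair carry over to
    female-directed courtship dominance in the subsequent trio?

    ``phase1`` holds the male-male paired period; ``phase2`` the trio period,
    whose courtship bouts must carry ``target_id``. The record is flagged
    excluded when phase-1 total courtship falls below
    ``params.dominance_min_courtship`` (default 20 s), no matter the bias.
    ``carried_over`` is defined only when both phases have a dominant male.
    """
    params = params or IndexParams()
    males = male_ids if male_ids is not None else phase1.fly_ids
    if len(males) != 2:
        raise ValidationError("phase1 must contain exactly 2 males")
    extra = set(phase2.fly_ids) - set(males) - {female_id}
    if extra:
        raise ValidationError(f"unexpected flies in phase2: {sorted(extra)}")
    court2 = [
        b for b in phase2.bouts
        if b.action == courtship_action and b.fly_id in males
    ]
    if any(b.target_id is None for b in court2):
        raise ValidationError("phase2 courtship bouts must carry target_id")

    bias1, dom1 = pair_bias(phase1, courtship_action, flies=tuple(males))
    total1 = sum(
        interval_union_length(
            [(b.start, b.stop) for b in phase1.select(fly_id=m, action=courtship_action)]
        )
        for m in males
    )
    excluded = total1 < params.dominance_min_courtship

    # female-directed bias in the trio, restricted to bouts targeting the female
    fem_totals = {
        m: interval_union_length(
            [
                (b.start, b.stop)
                for b in court2
                if b.fly_id == m and b.target_id == female_id
            ]
        )
        for m in males
    }
    bias2 = preference_index(fem_totals[males[0]], fem_totals[males[1]])
    if bias2 is None or bias2 == 0:
        dom2 = None
    else:
        dom2 = males[0] if fem_totals[males[0]] > fem_totals[males[1]] else males[1]

    carried: bool | None
    if dom1 is None or dom2 is None:
        carried = None
    else:
        carried = dom1 == dom2
    return DominanceRecord(
        pair_id=phase1.trial_id,
        phase1_bias=bias1,
        phase1_total_courtship=total1,
        dominant_id=dom1,
        phase2_female_bias=bias2,
        phase2_dominant_id=dom2,
        carried_over=carried,
        excluded=excluded,
        copulator_id=copulator_id,
    )
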