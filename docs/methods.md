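# Methods

This note documents the conventions, models and design decisions behind
`socialetho`, in the spirit of a package methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Time and interval conventions

Time is real-valued seconds. Every bout is a half-open interval
`[start, stop)`; frames are 0-based and frame `i` at rate `fps` covers
`[i/fps, (i+1)/fps)`. Half-open intervals remove double counting at shared
boundaries: an onset exactly at a window's start counts, one at its stop
does not. Rasterization (`bouts_to_frames`) marks a frame when its interval
*intersects* the bout rather than sampling the frame midpoint; this makes
`frames_to_bouts` an exact inverse on frame-aligned tables, which the suite
checks by property test over random binary matrices. Annotations need not be
frame-locked — sub-frame bout times are kept and rasterized on demand.

Bout tables are canonicalized by `normalize_bouts`: sorting by
(fly, action, start) and merging overlapping or abutting bouts of the same
(fly, action, target); at `merge_gap = 0` the union is conserved and the
operation is idempotent.

Trials with copulation are cut at the copulation time: later bouts are
dropped, straddling bouts clipped, and the effective trial duration becomes
the copulation latency, so all subsequent fractions and rates normalize by
time-to-copulation rather than total interaction time. When no explicit
copulation time is given, the onset of the earliest bout named
`"copulation"` is used.

## Ethograms

Nodes carry bout counts per action with frequencies normalized to the summed
bouts across all actions. The edge weight from action *a* to *b* is the
fraction of bouts of *a* for which at least one bout of *b* begins within
the cutoff (default 1 s) after *a*'s offset. Three conventions needed
pinning where common usage is ambiguous, and each is a config flag:

* **Trigger window** — `(offset_a, offset_a + cutoff]`, measured
  offset-to-onset. A bout of *b* whose onset precedes *a*'s offset (i.e.
  overlaps *a*) does not count by default ("a second action occurred within
  one second" is read as after the first ends); `count_overlap_onsets=True`
  switches to onset-after-*a*-begins. A gap exactly equal to the cutoff
  counts (closed upper bound), asserted by boundary fixtures.
* **Indicator, not count** — each source bout contributes 0/1 per target
  action; several qualifying followers of the same action count once.
* **Scope** — pair-pooled by default (ethograms describe the pair's joint
  stream); per-fly scope restricts transitions to each fly's own stream.
  Self-transitions (a → a) are included by default and toggleable.

`ethogram_oracle` is a deliberately naive O(n²) all-pairs implementation
with the identical contract; the acceptance suite requires exact equality on
1,000 random bout tables of up to 200 bouts.

## Metrics

* **Time budgets** use union semantics: duplicated or overlapping bouts of
  the included actions never count twice, so adding a duplicate bout cannot
  change a fraction (tested as a monotonicity/idempotence property).
* **Rates** count bout onsets in the half-open window, scaled to per-minute.
* **Latencies** are the earliest matching onset; a trial with no event is
  returned as a *censored* value carrying the trial duration. Rank tests can
  receive censored latencies at the trial-duration value with the censoring
  flag carried along, or callers can exclude them; both modes are possible
  because the field uses both and neither is canonical.
* **Sliding expressivity** uses a centered window of `w` seconds
  (default 10 s), truncated — not padded — at the trial edges, to avoid
  inventing data outside the recording. The window at frame `i` covers
  frames `[i - m//2, i - m//2 + m)` with `m = round(w·fps)`, so a 1-frame
  window reproduces the raw trace exactly and a step input reads 0.5 at the
  step frame. The s.e.m. across trials uses the sample standard deviation
  (n − 1); a single trial yields s.e.m. 0 with an explicit flag.
* **Peri-stimulation alignment** qualifies a (fly, block) sample when the
  action is ON at some frame in `[onset − 0.5 s, onset]`; a symmetric
  ±0.5 s reading is available as a flag. The aligned trace spans
  `[−pre, block + post]` (defaults 2 s each side, giving 6-s windows around
  2-s blocks) and reports the fraction of qualifying samples ON per frame.
* **Epoch aggregation** partitions a stimulation trial into baseline
  (PS−), PS blocks, inter-block intervals and the post-final period
  (partition verified to sum to the trial duration), and always reports both
  pooled "PS+" readings: blocks pooled (induction during stimulation) and
  IBIs + post pooled (rebound-style induction).
* **Sham-bout baseline** is the fraction of spontaneous bouts strictly
  longer than 2 s.

## Social indices

All two-argument indices are `(a − b)/(a + b)`: antisymmetric under swap,
scale-invariant, bounded in [−1, 1]. A 0/0 contrast is **undefined**, not 0:
an animal that never performed either behavior carries no preference
information, and undefined values are flagged and excluded from group
statistics. Pair-bias ties (exactly equal totals) yield bias 0 with no
dominant and are excluded from carry-over fractions.

The receptivity index binarizes wing spreading as `WS > 0` and normalized
ovipositor extrusion as `OE(norm) > −0.25` (strict inequalities), then
averages `ws_bin − oe_bin ∈ {−1, 0, 1}` over females. A female whose
normalized OE is undefined (no OE and no male courtship) contributes
`oe_bin = 0` — absence of rejection is not rejection. This convention for
zero-courtship females is a documented choice; the alternative (excluding
such females) can be applied upstream by filtering.

Dominance carry-over compares the identity of the dominant male-directed
courter in a male-male pair with the dominant female-directed courter in the
subsequent trio (courtship bouts must carry `target_id`). Pairs with less
than 20 s of total phase-1 courtship are flagged excluded, no matter the
bias. Carry-over is defined only when both phases have a dominant.

## Song

The peak of each annotated event is the maximum |signal| within a 20-ms
window centered on the annotation (window clipped at waveform bounds), ties
broken to the earliest sample; absolute value is used because recorded peaks
may be negative-going, with a raw-max mode available. Trains are maximal
runs of same-type events whose consecutive peak-to-peak separations are
strictly below the type's threshold — 200 ms for pulse, 400 ms for clack; a
separation exactly at the threshold splits, and runs of length one are
isolated events, not trains. Separation is measured peak-to-peak (rather
than annotation-to-annotation) because peak times are the physically defined
quantity; the annotation times are operator-placed approximations.

## Place preference

Frames (8-bit or float) are normalized to [0, 1]. The background is the
pixelwise median over a frame subset; the default subset takes every k-th
frame with k chosen to keep ≤ 201 frames, which is ample for the median to
reject transient animals. Detection thresholds |frame − background|,
extracts 8-connected components, and keeps the `max_animals` largest by area
(ties broken to the topmost, then leftmost centroid); centroids are
unweighted. Occupancy is `left/(left + right)` over detections falling in
the two arm masks, excluding the central bowl, outside regions and
undetected frames; each detection contributes one count, so multi-animal
(group-assay) frames contribute several. The detection threshold and subset
size are required inputs with package defaults — they are tuning parameters
of any specific rig, not constants of the method.

## Statistics

Conventions, all pinned and tested:

* "Paired Mann–Whitney" and the one-sample comparison to a null median are
  the Wilcoxon signed-rank test (the established behavior of the paired
  option in the R `wilcox.test` family), with zero differences dropped.
* Exact p-values by enumeration when the combined sample is ≤ 12 and tie-free
  (matched against brute-force enumeration over all rank splits / sign
  patterns in the suite); otherwise the normal approximation with tie and
  continuity corrections.
* Dunn's post-hoc z uses mean pooled ranks with the tie-corrected standard
  error `√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)]`, two-sided
  normal p, BH adjusted across all pairs.
* The compact letter display covers the non-significance graph with maximal
  cliques (insert-and-absorb: redundant cliques whose members and pairs are
  covered elsewhere are dropped), letters named a, b, c… by first use.
  Letter sharing exactly complements the significance matrix — verified
  exhaustively over all patterns for up to 4 groups.
* One-sample frequency tests are exact binomial with the two-sided
  "sum of outcome probabilities ≤ P(observed)" rule. The two-sample
  frequency comparison is Fisher's exact test on the 2×2 table, with a
  two-proportion z-test offered as an alternative mode — "two-sample
  binomial test" has no single canonical meaning and the choice is
  documented in the result's method label.
* Quartiles for Tukey fences use linear interpolation between order
  statistics; fences are `Q1 − 1.5·IQR` / `Q3 + 1.5·IQR` (strict). Flags
  are informational only — no value is ever removed from any computation.
* Cohen's d uses the pooled-variance form with a normal-approximation CI,
  `se = √[(n1+n2)/(n1·n2) + d²/(2(n1+n2−2))]`.
* BH families are caller-specified: the package adjusts whatever vector it
  is handed and never guesses which tests belong together.

A calibration property is part of acceptance: on 2,000 null replicates with
n = 10 per group, the two-sample rank test rejects at α = 0.05 at a rate
within [0.03, 0.07].

## Synthetic data: what it emulates, and what it does not

The generators are semi-Markov rather than per-frame Markov: actions follow
a Markov chain while bout (dwell) and inter-bout gap durations follow
explicit log-normal distributions (medians and log-sd are the parameters;
sigma 0 degenerates to deterministic schedules, which the suite exploits for
closed-form bout-count checks). This yields right-skewed, realistic bout
durations and makes transition recovery well-posed: with gaps almost surely
below the 1-s ethogram cutoff and dwells above it, edge weights converge to
the generating transition matrix — the acceptance run demands < 0.02 max-abs
deviation at ~10,000 bouts (an ~18,000 s simulated stream at the default
cycle length). Stimulation trials scale per-action initiation propensities
per epoch: sub-unit multipliers thin initiations, multipliers above 1
shorten the preceding gap, infinity forces continuous expression; with all
multipliers at 1 the process reduces exactly to the plain dyad process
(checked distributionally by KS over 50 trials).

Song synthesis places single-sample impulses with within-train IPIs drawn
from (30, 80) ms and between-train gaps from (600, 1200) ms — supports
separated from the 200-ms threshold by construction, so ground-truth
membership is unambiguous; annotations are jittered up to ±5 ms to emulate
operator placement. The y-maze generator walks a region graph
(bowl ↔ arms) with arm choice probability `p_left` and log-normal dwells
(bowl 0.5 s, arm 0.8 s medians), 45 Hz, 4 animals per 10-minute trial
(within the 2–4 animals per trial of the group assay); short dwells give
each trial roughly 1,500–1,800 independent arm visits so occupancy recovers
`p_left` within ±0.03 with comfortable margin. Rendering draws Gaussian
blobs (σ = 2 px) on a flat background. The receptivity cohort draws display
probabilities from logistic dose-response curves; a rejecting female's OE
time is drawn comparable to the male's courtship time so that the −0.25
normalized-OE threshold is informative. The carry-over cohort constructs
trios with a known carry-over probability and deliberately includes a
fraction of pairs below the 20-s courtship filter to verify exclusion.

None of the generators emulate tracking noise, classifier false
positives/negatives, identity swaps, song carrier-frequency structure, or
optics (vignetting, shadows). Passing recovery tests therefore demonstrates
the correctness of the estimators given faithful upstream labels — not
robustness to upstream failure modes, which belongs to the trackers and
classifiers themselves.

## Problem sizes and determinism

Every simulation takes an explicit integer seed and is bit-reproducible.
The default verification sizes — 1,000 random tables for oracle equivalence,
~10,000 bouts for transition recovery, 2,000 null replicates for
calibration, 10-minute 45-Hz maze trials, 500 trios — were chosen so each
quantity's sampling error sits well inside its assertion band while the
whole verification run completes in seconds.

## Known limitations

* No identity tracking across frames in place preference; the assay needs
  only positions. Multi-animal occupancy is detection-weighted.
* No automatic song event detection from raw audio; annotations are
  consumed, not produced.
* Trio preference uses raw summed durations per target with no
  simultaneous-courtship tie-breaking.
* Censored-latency handling (trial-end value vs. exclusion) is a caller
  decision; the package only guarantees the censoring flag is never lost.
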