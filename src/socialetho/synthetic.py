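"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be emulated here: semi-Markov dyadic
(and trio) bout streams, photostimulation trials, courtship-song waveforms
with annotations, dose-response receptivity cohorts, and y-maze tracks with
optional rendered frame stacks. Each generator takes an explicit seed, is
bit-reproducible given that seed, and returns a machine-readable ground-truth
record sufficient to score the downstream estimator — parameter recovery is
the package's principal test surface.

The bout generator is semi-Markov rather than per-frame Markov: actions are
chosen by a Markov chain but bout (dwell) and inter-bout gap durations follow
explicit log-normal distributions. This produces realistic right-skewed bout
lengths and makes ethogram-transition recovery well-posed: when gaps are
almost surely shorter than the transition cutoff and dwells longer than it,
the ethogram edge weights converge to the generating transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Bout,
    BoutTable,
    FrameLabelTable,
    StimBlock,
    StimSchedule,
    ValidationError,
    bouts_to_frames,
)

__all__ = [
    "DyadModel",
    "SongModel",
    "MazeModel",
    "simulate_dyad",
    "simulate_ps_trial",
    "simulate_song",
    "simulate_maze",
    "render_maze_frames",
    "simulate_receptivity_cohort",
    "simulate_carryover_cohort",
    "PRESETS",
]


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size=None):
    """Log-normal parameterized by its median (sigma = 0 degenerates to it)."""
    if sigma == 0:
        return np.full(size, median) if size is not None else median
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=size)


@dataclass
class DyadModel:
    """Semi-Markov generator of per-fly action streams.

    actions
        Action names (the idle state between bouts is implicit: the gap).
    transition
        Row-stochastic matrix over actions: next action given current.
    dwell_median_s / dwell_sigma
        Log-normal bout-duration parameters (per action or scalar).
    gap_median_s / gap_sigma
        Log-normal inter-bout-gap parameters.
    activity
        Per-fly multiplier on activity (divides gap medians).
    n_flies
        Independent streams per trial (2 for a dyad).
    """

    actions: tuple[str, ...]
    transition: np.ndarray
    dwell_median_s: float | np.ndarray = 1.5
    dwell_sigma: float = 0.3
    gap_median_s: float = 0.3
    gap_sigma: float = 0.3
    activity: float = 1.0
    n_flies: int = 2

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (len(self.actions), len(self.actions)):
            raise ValidationError("transition matrix shape mismatch")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("transition rows must sum to 1")
        if np.any(self.transition < 0):
            raise ValidationError("transition entries must be non-negative")
        if np.any(np.asarray(self.dwell_median_s) <= 0) or self.gap_median_s <= 0:
            raise ValidationError("dwell/gap medians must be positive")


#: Illustrative species-style presets (aggression-dominated vs.
#: courtship-dominated vs. mostly inactive repertoires). Qualitative only.
PRESETS: dict[str, DyadModel] = {}


def _make_presets() -> None:
    agg = ("lunge", "threat", "charge", "UWE")
    PRESETS["aggression-dominated"] = DyadModel(
        actions=agg,
        transition=np.array(
            [
                [0.55, 0.20, 0.20, 0.05],
                [0.45, 0.30, 0.20, 0.05],
                [0.50, 0.20, 0.25, 0.05],
                [0.30, 0.20, 0.20, 0.30],
            ]
        ),
        dwell_median_s=0.8,
        gap_median_s=2.0,
        gap_sigma=0.8,
    )
    crt = ("UWE", "BWE", "circle", "lunge")
    PRESETS["courtship-dominated"] = DyadModel(
        actions=crt,
        transition=np.array(
            [
                [0.60, 0.15, 0.20, 0.05],
                [0.50, 0.25, 0.20, 0.05],
                [0.55, 0.15, 0.25, 0.05],
                [0.40, 0.20, 0.20, 0.20],
            ]
        ),
        dwell_median_s=2.0,
        gap_median_s=1.5,
        gap_sigma=0.8,
    )
    PRESETS["inactive"] = DyadModel(
        actions=("lunge", "UWE"),
        transition=np.array([[0.5, 0.5], [0.5, 0.5]]),
        dwell_median_s=0.5,
        gap_median_s=60.0,
        gap_sigma=1.0,
    )


_make_presets()


def _simulate_stream(
    model: DyadModel,
    duration: float,
    rng: np.random.Generator,
    fly_id: str,
) -> tuple[list[Bout], list[tuple[int, int]]]:
    """One fly's alternating gap/bout stream; returns bouts and realized
    transitions as (from_idx, to_idx) pairs."""
    k = len(model.actions)
    dwell_med = np.broadcast_to(np.asarray(model.dwell_median_s, dtype=float), (k,))
    bouts: list[Bout] = []
    transitions: list[tuple[int, int]] = []
    t = 0.0
    state: int | None = None
    while True:
        gap = _lognormal(rng, model.gap_median_s / model.activity, model.gap_sigma)
        t += gap
        if t >= duration:
            break
        if state is None:
            nxt = int(rng.integers(k))
        else:
            nxt = int(rng.choice(k, p=model.transition[state]))
        dwell = _lognormal(rng, float(dwell_med[nxt]), model.dwell_sigma)
        stop = min(t + dwell, duration)
        bouts.append(Bout(fly_id, model.actions[nxt], t, stop))
        if state is not None:
            transitions.append((state, nxt))
        state = nxt
        t += dwell
    return bouts, transitions


def simulate_dyad(
    model: DyadModel,
    duration: float,
    frame_rate: float = 30.0,
    seed: int = 0,
) -> tuple[FrameLabelTable, BoutTable, dict]:
    """Simulate one trial of independent per-fly semi-Markov streams.

    Returns the frame-label rasterization, the bout table, and a ground-truth
    record with the model transition matrix and realized transition counts.
    """
    rng = np.random.default_rng(seed)
    all_bouts: list[Bout] = []
    trans_counts = np.zeros((len(model.actions),) * 2, dtype=int)
    for f in range(model.n_flies):
        bouts, transitions = _simulate_stream(model, duration, rng, f"fly{f + 1}")
        all_bouts.extend(bouts)
        for i, j in transitions:
            trans_counts[i, j] += 1
    all_bouts.sort(key=lambda b: (b.fly_id, b.action, b.start))
    table = BoutTable(
        trial_id=f"sim-dyad-{seed}",
        bouts=all_bouts,
        trial_duration=duration,
        vocabulary=model.actions,
    )
    columns = [(f"fly{f + 1}", a) for f in range(model.n_flies) for a in model.actions]
    frames = bouts_to_frames(table, frame_rate, columns=columns)
    truth = {
        "transition": model.transition.tolist(),
        "realized_transition_counts": trans_counts.tolist(),
        "n_bouts": len(all_bouts),
        "actions": list(model.actions),
        "seed": seed,
    }
    return frames, table, truth


def simulate_ps_trial(
    model: DyadModel,
    schedule: StimSchedule,
    stim_effect: dict[str, tuple[float, float]],
    frame_rate: float = 30.0,
    seed: int = 0,
) -> tuple[FrameLabelTable, BoutTable, dict]:
    """Simulate a photostimulation trial with epoch-dependent behavior.

    ``stim_effect`` maps action -> (multiplier during PS blocks, multiplier
    outside blocks) scaling the propensity of initiating a bout of that
    action. Multipliers in [0, 1] thin bout initiations (0 silences the
    action in that epoch); multipliers above 1 shorten the preceding
    inter-bout gap by the same factor (more frequent initiation);
    ``numpy.inf`` forces the action continuously ON for the whole epoch
    (certain expression). With all multipliers at 1 the process reduces
    exactly to :func:`simulate_dyad`'s distribution.
    """
    for m_on, m_off in stim_effect.values():
        if m_on < 0 or m_off < 0:
            raise ValidationError("stim multipliers must be non-negative")
    rng = np.random.default_rng(seed)
    duration = schedule.trial_duration

    def in_block(t: float) -> bool:
        return any(b.onset <= t < b.offset for b in schedule.blocks)

    def multiplier(action: str, t: float) -> float:
        m_on, m_off = stim_effect.get(action, (1.0, 1.0))
        return m_on if in_block(t) else m_off

    k = len(model.actions)
    dwell_med = np.broadcast_to(np.asarray(model.dwell_median_s, dtype=float), (k,))
    all_bouts: list[Bout] = []
    for f in range(model.n_flies):
        fly = f"fly{f + 1}"
        t = 0.0
        state: int | None = None
        while True:
            if state is None:
                nxt = int(rng.integers(k))
            else:
                nxt = int(rng.choice(k, p=model.transition[state]))
            gap = _lognormal(rng, model.gap_median_s / model.activity, model.gap_sigma)
            boost = max(multiplier(model.actions[nxt], t), 1.0)
            t += gap if not np.isfinite(boost) else gap / boost
            if t >= duration:
                break
            m = multiplier(model.actions[nxt], t)
            if np.isfinite(m) and rng.random() >= min(m, 1.0):
                continue  # initiation thinned away; chain state unchanged
            dwell = _lognormal(rng, float(dwell_med[nxt]), model.dwell_sigma)
            all_bouts.append(Bout(fly, model.actions[nxt], t, min(t + dwell, duration)))
            state = nxt
            t += dwell
        # certain-expression actions: ON for every epoch with an inf multiplier
        for action, (m_on, m_off) in stim_effect.items():
            if np.isinf(m_on):
                for blk in schedule.blocks:
                    all_bouts.append(Bout(fly, action, blk.onset, blk.offset))
            if np.isinf(m_off):
                raise ValidationError("inf multiplier outside blocks is not supported")
    all_bouts.sort(key=lambda b: (b.fly_id, b.action, b.start))
    table = BoutTable(
        trial_id=f"sim-ps-{seed}",
        bouts=all_bouts,
        trial_duration=duration,
        vocabulary=model.actions,
    )
    columns = [(f"fly{f + 1}", a) for f in range(model.n_flies) for a in model.actions]
    frames = bouts_to_frames(table, frame_rate, columns=columns)
    truth = {
        "stim_effect": {a: list(v) for a, v in stim_effect.items()},
        "seed": seed,
    }
    return frames, table, truth


@dataclass
class SongModel:
    """Generator of impulse-like song events organized into trains.

    Within-train inter-event intervals and between-train gaps are drawn
    uniformly from supports that must sit strictly below / above the
    segmentation threshold for the type, so ground-truth train membership is
    well defined.
    """

    event_type: str = "pulse"
    n_trains: int = 20
    events_per_train: tuple[int, int] = (3, 8)
    ipi_range_s: tuple[float, float] = (0.030, 0.080)
    gap_range_s: tuple[float, float] = (0.600, 1.200)
    amplitude: float = 1.0
    amp_jitter: float = 0.2
    sample_rate: float = 10_000.0
    noise_sd: float = 0.0
    annotation_jitter_s: float = 0.005

    def __post_init__(self) -> None:
        if self.ipi_range_s[0] <= 0 or self.ipi_range_s[1] < self.ipi_range_s[0]:
            raise ValidationError("invalid IPI range")
        if self.gap_range_s[0] <= self.ipi_range_s[1]:
            raise ValidationError("between-train gaps must exceed within-train IPIs")


def simulate_song(
    model: SongModel, duration: float, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Synthesize a waveform, a jittered annotation table, and truth trains.

    Events are single-sample impulses of known amplitude plus optional
    Gaussian noise; annotations are jittered by at most
    ``annotation_jitter_s`` from the true peaks; truth records each event's
    time, amplitude and train membership (train -1 = isolated).
    """
    rng = np.random.default_rng(seed)
    times: list[float] = []
    membership: list[int] = []
    t = rng.uniform(*model.gap_range_s)
    for tr in range(model.n_trains):
        n_ev = int(rng.integers(model.events_per_train[0], model.events_per_train[1] + 1))
        for e in range(n_ev):
            if e > 0:
                t += rng.uniform(*model.ipi_range_s)
            times.append(t)
            membership.append(tr if n_ev >= 2 else -1)
        t += rng.uniform(*model.gap_range_s)
    if times and times[-1] > duration - 0.05:
        raise ValidationError(
            f"train placement needs {times[-1]:.2f} s, duration is {duration} s"
        )
    n = int(duration * model.sample_rate)
    signal = rng.normal(0.0, model.noise_sd, n) if model.noise_sd > 0 else np.zeros(n)
    amps = model.amplitude * (1 + rng.uniform(-model.amp_jitter, model.amp_jitter, len(times)))
    for tt, a in zip(times, amps):
        signal[int(round(tt * model.sample_rate))] += a
    jit = rng.uniform(-model.annotation_jitter_s, model.annotation_jitter_s, len(times))
    annotations = pd.DataFrame(
        {
            "type": model.event_type,
            "time_s": np.asarray(times) + jit,
        }
    )
    truth = {
        "event_times": list(map(float, times)),
        "amplitudes": amps.tolist(),
        "membership": membership,
        "n_trains": len({m for m in membership if m >= 0}),
        "train_sizes": [membership.count(tr) for tr in sorted({m for m in membership if m >= 0})],
        "seed": seed,
    }
    return signal, annotations, truth


@dataclass
class MazeModel:
    """Region-graph random walk in a y-maze.

    Animals alternate between the central bowl and an arm; on leaving the
    bowl they choose the left arm with probability ``p_left``. Dwell times
    are log-normal. Defaults emulate the odor assay: 45 Hz video and 2-4
    animals loaded per trial (4 by default).
    """

    p_left: float = 0.5
    frame_rate: float = 45.0
    n_animals: int = 4
    bowl_dwell_median_s: float = 0.5
    bowl_dwell_sigma: float = 0.3
    arm_dwell_median_s: float = 0.8
    arm_dwell_sigma: float = 0.2
    frame_shape: tuple[int, int] = (120, 160)

    def __post_init__(self) -> None:
        if not (0 <= self.p_left <= 1):
            raise ValidationError("p_left must lie in [0, 1]")


def make_y_maze_geometry(shape: tuple[int, int] = (120, 160)):
    """Simple rectangular y-maze mask layout: bowl at center bottom, arms at
    upper left / upper right. Good enough for synthetic walks and rendering."""
    from .placepref import ArenaGeometry

    h, w = shape
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    bowl = np.zeros(shape, dtype=bool)
    bowl[2 * h // 3: h - 5, w // 3: 2 * w // 3] = True
    left[5: h // 2, 5: w // 3] = True
    right[5: h // 2, 2 * w // 3: w - 5] = True
    return ArenaGeometry(left=left, right=right, bowl=bowl)


def _region_center(mask: np.ndarray) -> tuple[float, float]:
    ys, xs = np.nonzero(mask)
    return float(ys.mean()), float(xs.mean())


def simulate_maze(
    model: MazeModel, duration: float, seed: int = 0, geometry=None
) -> tuple[pd.DataFrame, dict]:
    """Simulate bowl <-> arm random walks for ``n_animals``.

    Returns a track table (frame, time_s, animal, x, y, detected, region) and
    a truth record with per-region frame counts; the realized left-arm
    occupancy in truth is an unbiased estimate of ``p_left`` because both
    arms share the dwell distribution.
    """
    rng = np.random.default_rng(seed)
    geometry = geometry or make_y_maze_geometry(model.frame_shape)
    centers = {
        "left": _region_center(geometry.left),
        "right": _region_center(geometry.right),
        "bowl": _region_center(geometry.bowl),
    }
    n_frames = int(round(duration * model.frame_rate))
    rows = []
    counts = {"left": 0, "right": 0, "bowl": 0}
    for a in range(model.n_animals):
        # build the region occupancy timeline for this animal
        timeline = np.empty(n_frames, dtype=object)
        t = 0.0
        region = "bowl"
        while t < duration:
            if region == "bowl":
                dwell = _lognormal(rng, model.bowl_dwell_median_s, model.bowl_dwell_sigma)
            else:
                dwell = _lognormal(rng, model.arm_dwell_median_s, model.arm_dwell_sigma)
            f0 = int(np.floor(t * model.frame_rate))
            f1 = min(int(np.floor((t + dwell) * model.frame_rate)), n_frames)
            timeline[f0:f1] = region
            t += dwell
            if region == "bowl":
                region = "left" if rng.random() < model.p_left else "right"
            else:
                region = "bowl"
        jitter = rng.normal(0, 1.5, size=(n_frames, 2))
        for f in range(n_frames):
            reg = timeline[f] if timeline[f] is not None else region
            counts[reg] += 1
            cy, cx = centers[reg]
            rows.append(
                (f, f / model.frame_rate, a, cx + jitter[f, 1], cy + jitter[f, 0], True, reg)
            )
    track = pd.DataFrame(
        rows, columns=["frame", "time_s", "animal", "x", "y", "detected", "region"]
    )
    arm = counts["left"] + counts["right"]
    truth = {
        "p_left": model.p_left,
        "region_frame_counts": counts,
        "realized_occupancy": counts["left"] / arm if arm else float("nan"),
        "seed": seed,
    }
    return track, truth


def render_maze_frames(
    track: pd.DataFrame,
    shape: tuple[int, int],
    blob_sigma: float = 2.0,
    blob_amp: float = 0.8,
    background_level: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int | None = None,
) -> np.ndarray:
    """Render a track as a float frame stack with Gaussian blobs per animal
    on a flat background (optionally with pixel noise)."""
    rng = np.random.default_rng(seed)
    h, w = shape
    frames_idx = sorted(track["frame"].unique())
    if n_frames is not None:
        frames_idx = frames_idx[:n_frames]
    yy, xx = np.mgrid[0:h, 0:w]
    stack = np.full((len(frames_idx), h, w), background_level, dtype=np.float64)
    for k, f in enumerate(frames_idx):
        sub = track[track["frame"] == f]
        for _, row in sub.iterrows():
            g = blob_amp * np.exp(
                -((yy - row["y"]) ** 2 + (xx - row["x"]) ** 2) / (2 * blob_sigma**2)
            )
            stack[k] += g
        if noise_sd > 0:
            stack[k] += rng.normal(0, noise_sd, (h, w))
    return np.clip(stack, 0.0, 1.0)


def simulate_receptivity_cohort(
    n_females: int,
    doses: np.ndarray | list[float],
    oe_slope: float = 1.0,
    oe_intercept: float = -1.0,
    ws_slope: float = -1.0,
    ws_intercept: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Dose-response cohort of female receptivity displays.

    Per dose, each female's probability of wing spreading (acceptance)
    follows ``expit(ws_intercept + ws_slope * dose)`` and of ovipositor
    extrusion (rejection) ``expit(oe_intercept + oe_slope * dose)``. Every
    female gets a positive courting-male UWE time; a rejecting female's OE
    time is drawn comparable to it (so her normalized OE clears the -0.25
    binarization threshold), a non-rejecting female's is 0. Truth records
    the generating probabilities per dose.
    """
    from scipy.special import expit

    if n_females < 1:
        raise ValidationError("n_females must be >= 1")
    doses = np.asarray(doses, dtype=float)
    if doses.ndim != 1 or len(doses) == 0:
        raise ValidationError("need a 1-D dose vector")
    rng = np.random.default_rng(seed)
    rows = []
    truth_p = {}
    for d in doses:
        p_ws = float(expit(ws_intercept + ws_slope * d))
        p_oe = float(expit(oe_intercept + oe_slope * d))
        truth_p[float(d)] = {"p_ws": p_ws, "p_oe": p_oe}
        for i in range(n_females):
            ws = rng.exponential(3.0) if rng.random() < p_ws else 0.0
            uwe = rng.exponential(20.0) + 1.0
            oe = uwe * rng.uniform(0.8, 2.0) if rng.random() < p_oe else 0.0
            rows.append((float(d), i, ws, oe, uwe))
    df = pd.DataFrame(
        rows, columns=["dose", "female", "ws_time_s", "oe_time_s", "male_uwe_time_s"]
    )
    return df, {"probabilities": truth_p, "seed": seed}


def simulate_carryover_cohort(
    n_trios: int,
    q_carryover: float = 0.8,
    p_below_filter: float = 0.1,
    min_courtship_s: float = 20.0,
    seed: int = 0,
) -> tuple[list[tuple[BoutTable, BoutTable]], dict]:
    """Paired-then-trio cohorts with a known dominance carry-over probability.

    Each trio yields a phase-1 male-male bout table (one male dominates
    male-directed courtship) and a phase-2 trio table whose courtship bouts
    carry ``target_id`` of the female; with probability ``q_carryover`` the
    same male dominates female-directed courtship. A fraction
    ``p_below_filter`` of trios is constructed with total phase-1 courtship
    strictly below ``min_courtship_s`` (these should be excluded by the
    filter). Truth records, per trio, the constructed dominant identities,
    whether carry-over was drawn, and whether the trio was built below the
    filter threshold.
    """
    if not (0 <= q_carryover <= 1):
        raise ValidationError("q_carryover must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cohort: list[tuple[BoutTable, BoutTable]] = []
    truth_rows = []
    for i in range(n_trios):
        below = rng.random() < p_below_filter
        dom1 = rng.integers(2)  # index of phase-1 dominant male
        males = ("m1", "m2")
        if below:
            total = rng.uniform(2.0, min_courtship_s * 0.8)
        else:
            total = rng.uniform(min_courtship_s * 1.5, 300.0)
        share = rng.uniform(0.7, 0.95)  # dominant's share of courtship
        durs = {males[dom1]: total * share, males[1 - dom1]: total * (1 - share)}
        p1_bouts = []
        t0 = 1.0
        for m, dur in durs.items():
            if dur > 0:
                p1_bouts.append(Bout(m, "UWE", t0, t0 + dur, target_id=males[m == "m1"]))
                t0 += dur + 5.0
        phase1 = BoutTable(
            trial_id=f"trio{i}", bouts=p1_bouts, trial_duration=1200.0
        )
        carried = rng.random() < q_carryover
        dom2 = dom1 if carried else 1 - dom1
        total2 = rng.uniform(30.0, 200.0)
        share2 = rng.uniform(0.7, 0.95)
        durs2 = {males[dom2]: total2 * share2, males[1 - dom2]: total2 * (1 - share2)}
        p2_bouts = []
        t0 = 1.0
        for m, dur in durs2.items():
            p2_bouts.append(Bout(m, "UWE", t0, t0 + dur, target_id="f1"))
            t0 += dur + 5.0
        phase2 = BoutTable(
            trial_id=f"trio{i}", bouts=p2_bouts, trial_duration=600.0
        )
        cohort.append((phase1, phase2))
        truth_rows.append(
            {
                "trio": i,
                "dominant_phase1": males[dom1],
                "dominant_phase2": males[dom2],
                "carried": bool(carried),
                "below_filter": bool(below),
                "phase1_total_s": total,
            }
        )
    truth = {
        "q_carryover": q_carryover,
        "records": truth_rows,
        "n_below_filter": sum(r["below_filter"] for r in truth_rows),
        "seed": seed,
    }
    return cohort, truth
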