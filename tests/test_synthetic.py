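"""Ground-truth generators: determinism, schedule arithmetic, recovery."""

import numpy as np
import pytest

from socialetho.core import StimBlock, StimSchedule, ValidationError
from socialetho.ethogram import EthogramParams, build_ethogram
from socialetho.metrics import epoch_summary, peristimulus_fraction
from socialetho.synthetic import (
    DyadModel,
    MazeModel,
    PRESETS,
    SongModel,
    simulate_carryover_cohort,
    simulate_dyad,
    simulate_maze,
    simulate_ps_trial,
    simulate_receptivity_cohort,
    simulate_song,
)


def _two_action_model(**kw):
    return DyadModel(
        actions=("A", "B"),
        transition=np.array([[0.5, 0.5], [0.5, 0.5]]),
        **kw,
    )


class TestSimulateDyad:
    def test_deterministic_under_seed(self):
        m = PRESETS["courtship-dominated"]
        _, t1, _ = simulate_dyad(m, 120, seed=42)
        _, t2, _ = simulate_dyad(m, 120, seed=42)
        assert [(b.fly_id, b.action, b.start, b.stop) for b in t1.bouts] == [
            (b.fly_id, b.action, b.start, b.stop) for b in t2.bouts
        ]

    def test_degenerate_schedule_arithmetic(self):
        m = DyadModel(
            actions=("A",),
            transition=np.array([[1.0]]),
            dwell_median_s=1.0,
            dwell_sigma=0.0,
            gap_median_s=0.5,
            gap_sigma=0.0,
            n_flies=1,
        )
        _, table, _ = simulate_dyad(m, 10.0, seed=0)
        starts = [b.start for b in table.bouts]
        assert starts == pytest.approx([0.5, 2.0, 3.5, 5.0, 6.5, 8.0, 9.5])

    def test_symmetric_chain_edge_weights(self):
        m = _two_action_model(
            dwell_median_s=1.5, dwell_sigma=0.1, gap_median_s=0.25,
            gap_sigma=0.2, n_flies=1,
        )
        _, table, truth = simulate_dyad(m, 10_000.0, seed=9)
        assert truth["n_bouts"] > 4000
        eth = build_ethogram(table, EthogramParams(actor_scope="per-fly"))
        assert np.abs(eth.edge_weight - 0.5).max() < 0.05

    def test_invalid_transition_rejected(self):
        with pytest.raises(ValidationError):
            DyadModel(actions=("A", "B"), transition=np.array([[0.9, 0.0], [0.5, 0.5]]))

    def test_realized_counts_match_bout_count(self):
        _, table, truth = simulate_dyad(PRESETS["aggression-dominated"], 300, seed=1)
        # each fly's stream has one fewer transition than bouts
        n_trans = np.asarray(truth["realized_transition_counts"]).sum()
        n_flies_active = len(table.fly_ids)
        assert n_trans == truth["n_bouts"] - n_flies_active


def _schedule():
    blocks = [StimBlock(120 + i * 90, 150 + i * 90, 10.0) for i in range(6)]
    return StimSchedule(blocks, 660.0)


class TestSimulatePSTrial:
    def test_silenced_action_has_no_block_onsets(self):
        m = _two_action_model(n_flies=1, gap_median_s=1.0)
        _, table, _ = simulate_ps_trial(m, _schedule(), {"A": (0.0, 1.0)}, seed=3)
        df = epoch_summary(table, _schedule(), "A", "rate").set_index("epoch")
        assert df.loc["PS+blocks", "value"] == 0.0
        assert df.loc["PS-", "value"] > 0.0

    def test_certain_expression_fills_blocks(self):
        m = _two_action_model(n_flies=1, gap_median_s=2.0)
        frames, table, _ = simulate_ps_trial(
            m, _schedule(), {"B": (np.inf, 1.0)}, seed=4
        )
        df = peristimulus_fraction([(frames, _schedule())], "B")
        block = df[(df.time_s >= 0) & (df.time_s < 30.0)]
        assert (block["fraction"] == 1.0).all()

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValidationError):
            simulate_ps_trial(_two_action_model(), _schedule(), {"A": (-1.0, 1.0)})

    def test_null_multipliers_match_plain_dyad_distribution(self):
        """With all multipliers at 1 the stimulation generator reduces to the
        plain semi-Markov process: bout-count distributions agree by KS."""
        from socialetho.stats import ks_two_sample

        m = _two_action_model(n_flies=1, gap_median_s=1.0)
        sched = _schedule()
        counts_ps, counts_plain = [], []
        for s in range(50):
            _, t1, _ = simulate_ps_trial(m, sched, {"A": (1.0, 1.0)}, seed=1000 + s)
            _, t2, _ = simulate_dyad(m, 660.0, seed=2000 + s)
            counts_ps.append(len(t1.bouts))
            counts_plain.append(len(t2.bouts))
        assert ks_two_sample(counts_ps, counts_plain).p_value > 0.01


class TestSimulateSong:
    def test_noiseless_recovery(self):
        from socialetho.song import extract_event_peaks

        model = SongModel(noise_sd=0.0)
        signal, ann, truth = simulate_song(model, 60.0, seed=2)
        events = extract_event_peaks(
            signal, model.sample_rate, list(zip(ann["type"], ann["time_s"]))
        )
        for ev, t, a in zip(events, truth["event_times"], truth["amplitudes"]):
            assert abs(ev.peak_time - t) <= 1 / model.sample_rate
            assert ev.amplitude == pytest.approx(a)

    def test_zero_trains_empty(self):
        model = SongModel(n_trains=0)
        signal, ann, truth = simulate_song(model, 10.0, seed=0)
        assert len(ann) == 0 and truth["n_trains"] == 0

    def test_infeasible_placement_rejected(self):
        with pytest.raises(ValidationError):
            simulate_song(SongModel(n_trains=100), 5.0, seed=0)

    def test_gap_support_invariant_enforced(self):
        with pytest.raises(ValidationError):
            SongModel(ipi_range_s=(0.1, 0.5), gap_range_s=(0.4, 0.6))


class TestSimulateMaze:
    def test_always_left(self):
        from socialetho.placepref import arm_occupancy
        from socialetho.synthetic import make_y_maze_geometry

        track, truth = simulate_maze(MazeModel(p_left=1.0, n_animals=2), 60, seed=0)
        occ, _ = arm_occupancy(track, make_y_maze_geometry())
        assert occ == 1.0 and truth["realized_occupancy"] == 1.0

    def test_truth_counts_are_exact_recount(self):
        track, truth = simulate_maze(MazeModel(p_left=0.5), 30, seed=5)
        by_region = track.groupby("region").size().to_dict()
        for region in ("left", "right", "bowl"):
            assert truth["region_frame_counts"][region] == by_region.get(region, 0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            MazeModel(p_left=1.5)


class TestReceptivityCohort:
    def test_flat_dose_response_null(self):
        from socialetho.indices import normalized_oe, receptivity_index

        df, truth = simulate_receptivity_cohort(
            n_females=200, doses=[0, 1, 2], oe_slope=0.0, ws_slope=0.0, seed=0
        )
        idx = []
        for dose, sub in df.groupby("dose"):
            females = [
                (row.ws_time_s, normalized_oe(row.oe_time_s, row.male_uwe_time_s))
                for row in sub.itertuples()
            ]
            idx.append(receptivity_index(females))
        assert max(idx) - min(idx) < 0.15  # binomial error at n = 200

    def test_steep_slope_saturates_negative(self):
        from socialetho.indices import normalized_oe, receptivity_index

        df, _ = simulate_receptivity_cohort(
            n_females=100, doses=[0.0, 50.0], oe_slope=1.0, ws_slope=-1.0, seed=1
        )
        top = df[df.dose == 50.0]
        females = [
            (row.ws_time_s, normalized_oe(row.oe_time_s, row.male_uwe_time_s))
            for row in top.itertuples()
        ]
        assert receptivity_index(females) < -0.8

    def test_monotone_ordering_recovered(self):
        from socialetho.indices import normalized_oe, receptivity_index

        df, truth = simulate_receptivity_cohort(
            n_females=500, doses=[0.0, 1.0, 2.0, 4.0], seed=3
        )
        idx = {}
        for dose, sub in df.groupby("dose"):
            females = [
                (row.ws_time_s, normalized_oe(row.oe_time_s, row.male_uwe_time_s))
                for row in sub.itertuples()
            ]
            idx[dose] = receptivity_index(females)
        doses = sorted(idx)
        assert all(idx[a] >= idx[b] for a, b in zip(doses, doses[1:]))


class TestCarryoverCohort:
    def test_filter_excludes_exactly_constructed_trials(self):
        from socialetho.indices import dominance_carryover

        cohort, truth = simulate_carryover_cohort(100, seed=6)
        for (p1, p2), rec_truth in zip(cohort, truth["records"]):
            rec = dominance_carryover(p1, p2, "f1", male_ids=("m1", "m2"))
            assert rec.excluded == rec_truth["below_filter"]
            if not rec.excluded:
                assert rec.carried_over == (
                    rec_truth["dominant_phase1"] == rec_truth["dominant_phase2"]
                )

    def test_recovers_carryover_probability(self):
        from socialetho.indices import dominance_carryover

        q = 0.8
        cohort, _ = simulate_carryover_cohort(500, q_carryover=q, seed=17)
        outcomes = [
            dominance_carryover(p1, p2, "f1", male_ids=("m1", "m2"))
            for p1, p2 in cohort
        ]
        kept = [r for r in outcomes if not r.excluded and r.carried_over is not None]
        frac = np.mean([r.carried_over for r in kept])
        half_width = 1.96 * np.sqrt(q * (1 - q) / len(kept))
        assert abs(frac - q) <= half_width
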