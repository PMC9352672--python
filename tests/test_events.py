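"""Event layer: metrics, hysteresis, combinators, controller, occupancy."""

import numpy as np
import pytest

from motifscope.audio import AudioSignal
from motifscope.events import (Event, HysteresisParams, assemble_sequences,
                               combine_and, entropy_metric, frame_metrics,
                               hysteresis_events, perch_occupancy,
                               power_metric, read_events_jsonl,
                               spectral_flatness, stimulus_controller,
                               write_events_jsonl)

from _oracles import (controller_sim_oracle, gap_partition_oracle,
                      interval_and_oracle)


def iv(pairs, kind="x"):
    return [Event(kind, a, b) for a, b in pairs]


class TestMetrics:
    def test_power_of_zero_frame_is_zero(self):
        assert power_metric(np.zeros(256)) == 0.0

    def test_power_of_constant_half_is_quarter(self):
        assert power_metric(np.full(256, 0.5)) == pytest.approx(0.25)

    def test_power_matches_per_sample_oracle(self):
        rng = np.random.default_rng(0)
        fr = rng.normal(0, 0.3, 1024)
        assert power_metric(fr) == pytest.approx(sum(x * x for x in fr) / 1024)

    def test_flat_spectrum_has_unit_flatness(self):
        assert spectral_flatness(np.ones(64)) == pytest.approx(1.0)

    def test_hand_evaluated_flatness(self):
        # GM/AM of [4,2,1] = 2 / (7/3) = 6/7
        assert spectral_flatness(np.array([4.0, 2.0, 1.0])) == pytest.approx(6 / 7)

    def test_zero_spectrum_flatness_is_zero(self):
        assert spectral_flatness(np.zeros(16)) == 0.0

    def test_tone_vs_noise_limits(self):
        rng = np.random.default_rng(1)
        t = np.arange(1024) / 48000
        tone = np.sin(2 * np.pi * 2000 * t)
        noise = rng.normal(0, 1, 1024)
        # rectangular-window leakage keeps the tone's flatness above zero,
        # but well below noise
        assert entropy_metric(tone) < 0.3
        assert entropy_metric(noise) > 0.5
        assert entropy_metric(tone) < entropy_metric(noise)

    def test_frame_metrics_shapes(self):
        sig = AudioSignal(np.random.default_rng(0).normal(0, 0.1, 48000), 48000)
        times, power, entropy = frame_metrics(sig)
        assert len(times) == len(power) == len(entropy) == (48000 - 1024) // 512 + 1
        assert np.all(np.diff(times) > 0)


class TestHysteresis:
    P = HysteresisParams(on_threshold=0.6, off_threshold=0.3, metric="power")

    def test_subthreshold_stream_emits_nothing(self):
        t = np.arange(100.0)
        assert hysteresis_events(t, np.full(100, 0.5), self.P) == []

    def test_band_oscillation_does_not_chatter(self):
        t = np.arange(200.0)
        v = np.concatenate([[0.7], 0.45 + 0.1 * np.sin(np.arange(198)), [0.1]])
        evts = hysteresis_events(t, v, self.P)
        assert len(evts) == 1
        assert evts[0].onset == 0.0 and evts[0].offset == 199.0

    def test_square_wave_gives_one_event_per_period(self):
        t = np.arange(400.0)
        v = np.where((t // 50) % 2 == 0, 0.9, 0.1)
        evts = hysteresis_events(t, v, self.P)
        assert len(evts) == 4
        for a, b in zip(evts, evts[1:]):
            assert a.offset <= b.onset

    def test_open_event_is_closed_at_horizon_and_flagged(self):
        evts = hysteresis_events([0.0, 1.0], [0.9, 0.9], self.P, horizon=5.0)
        assert len(evts) == 1
        assert evts[0].offset == 5.0 and evts[0].payload.get("truncated")

    def test_inverted_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            HysteresisParams(on_threshold=0.1, off_threshold=0.5)


class TestCombineAnd:
    def test_disjoint_inputs_give_empty(self):
        assert combine_and(iv([(0, 1)]), iv([(2, 3)]), "bout") == []

    def test_contained_interval(self):
        out = combine_and(iv([(0, 10)]), iv([(4, 6)]), "bout")
        assert [(e.onset, e.offset) for e in out] == [(4, 6)]

    def test_matches_dense_boolean_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            def rand_ivs():
                edges = np.sort(rng.uniform(0, 10, rng.integers(2, 10) * 2))
                return list(zip(edges[::2], edges[1::2]))
            a, b = rand_ivs(), rand_ivs()
            got = [(e.onset, e.offset)
                   for e in combine_and(iv(a), iv(b), "bout")]
            expect = interval_and_oracle(a, b, horizon=10.0)
            assert len(got) == len(expect)
            for (g0, g1), (e0, e1) in zip(got, expect):
                assert abs(g0 - e0) < 2e-3 and abs(g1 - e1) < 2e-3

    def test_commutative(self):
        a, b = iv([(0, 3), (5, 9)]), iv([(1, 6)])
        ab = [(e.onset, e.offset) for e in combine_and(a, b, "bout")]
        ba = [(e.onset, e.offset) for e in combine_and(b, a, "bout")]
        assert ab == ba

    def test_overlapping_input_stream_rejected(self):
        with pytest.raises(ValueError):
            combine_and(iv([(0, 5), (3, 8)]), iv([(0, 1)]), "bout")


class TestSequences:
    def syl(self, pairs, bird="b1"):
        return [Event("syllable", a, b, bird, {"label": "A"}) for a, b in pairs]

    def test_small_gaps_form_one_sequence(self):
        evts = self.syl([(0, 0.1), (0.2, 0.3), (0.4, 0.5)])
        seqs = assemble_sequences(evts)
        assert len(seqs) == 1
        assert seqs[0].labels == ("A", "A", "A")

    def test_gap_beyond_window_splits(self):
        evts = self.syl([(0, 0.1), (0.7, 0.8)])  # gap 0.6 >= 0.5
        assert len(assemble_sequences(evts)) == 2

    def test_gap_exactly_at_window_splits(self):
        evts = self.syl([(0, 0.1), (0.6, 0.7)])
        assert len(assemble_sequences(evts)) == 2

    def test_emission_within_delay(self):
        evts = self.syl([(0, 0.1), (0.2, 0.4)])
        s = assemble_sequences(evts, emit_delay=3.0)[0]
        assert s.offset <= s.emitted_at <= s.offset + 3.0

    def test_random_schedules_match_gap_partition_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            onsets = np.cumsum(rng.uniform(0.05, 1.0, 30))
            pairs = [(o, o + 0.04) for o in onsets]
            seqs = assemble_sequences(self.syl(pairs))
            groups = gap_partition_oracle([(a, b) for a, b in pairs], 0.5)
            assert [len(s.labels) for s in seqs] == [len(g) for g in groups]


class TestStimulusController:
    def test_frequent_motifs_prevent_changes(self):
        motifs = [Event("motif", t, t) for t in np.arange(60, 7200, 60.0)]
        assert stimulus_controller(motifs, 3, horizon=7200.0) == []

    def test_no_motifs_cycle_through_videos_every_timeout(self):
        changes = stimulus_controller([], 3, timeout=180.0, horizon=7200.0)
        assert [c.onset for c in changes] == [180.0 * k for k in range(1, 41)]
        assert [c.payload["video"] for c in changes[:4]] == [1, 2, 0, 1]

    def test_arbitrary_schedule_matches_discrete_simulation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            times = np.sort(rng.uniform(0, 3600, rng.integers(0, 40)))
            times = np.round(times)  # align to the oracle's 1 s grid
            motifs = [Event("motif", float(t), float(t)) for t in times]
            got = [(c.onset, c.payload["video"])
                   for c in stimulus_controller(motifs, 3, timeout=180.0,
                                                horizon=3600.0)]
            expect = controller_sim_oracle(list(times), 3, 180.0, 3600.0)
            assert got == expect

    def test_no_motif_within_timeout_before_each_change(self):
        rng = np.random.default_rng(4)
        times = np.sort(rng.uniform(0, 3600, 15))
        motifs = [Event("motif", float(t), float(t)) for t in times]
        changes = stimulus_controller(motifs, 3, timeout=180.0, horizon=3600.0)
        for c in changes:
            # strict interior of (change - timeout, change]; the motif that
            # armed the timer sits exactly timeout before the change
            assert not np.any((times > c.onset - 180.0 + 1e-6)
                              & (times <= c.onset))

    def test_empty_video_list_rejected(self):
        with pytest.raises(ValueError):
            stimulus_controller([], 0)


class TestPerchOccupancy:
    def perch(self, triples, bird="b1"):
        return [Event("perch", a, b, bird, {"state": s}) for s, a, b in triples]

    def test_single_state_covering_horizon(self):
        occ = perch_occupancy(self.perch([("front", 0, 3600)]), 3600)
        assert occ == {"front": 1.0}

    def test_half_front_half_back(self):
        occ = perch_occupancy(
            self.perch([("front", 0, 1800), ("back", 1800, 3600)]), 3600)
        assert occ["front"] == pytest.approx(0.5)
        assert occ["back"] == pytest.approx(0.5)

    def test_gap_attributed_to_other(self):
        occ = perch_occupancy(self.perch([("front", 0, 900)]), 3600)
        assert occ["front"] == pytest.approx(0.25)
        assert occ["other"] == pytest.approx(0.75)

    def test_random_partitions_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            edges = np.sort(rng.uniform(0, 100, 8))
            states = rng.choice(["front", "back", "other"], 4)
            triples = [(s, a, b) for s, (a, b) in
                       zip(states, zip(edges[::2], edges[1::2]))]
            occ = perch_occupancy(self.perch(triples), 100.0)
            assert sum(occ.values()) == pytest.approx(1.0, abs=1e-9)

    def test_overlapping_states_rejected(self):
        with pytest.raises(ValueError):
            perch_occupancy(self.perch([("front", 0, 10), ("back", 5, 15)]), 20)


class TestSerialization:
    def test_jsonl_roundtrip(self, tmp_path):
        evts = [Event("power", 0.0, 1.5, "b1", {"truncated": False}),
                Event("perch", 2.0, 3.0, "b2", {"state": "front"})]
        write_events_jsonl(tmp_path / "e.jsonl", evts)
        assert read_events_jsonl(tmp_path / "e.jsonl") == evts
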