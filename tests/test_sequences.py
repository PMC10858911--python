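"""Unit and property tests for trajectorization, binarization and cleaning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fireflash import (
    FlashEvent,
    FlashSequence,
    SequenceDataset,
    Streak,
    Trajectory,
    clean_short_gaps,
    filter_rare_species,
    filter_single_flash,
    frames_to_seconds,
    link_streaks,
    link_trajectories,
    read_sequences,
    sequence_stats,
    trajectory_to_sequence,
    write_sequences,
)
from fireflash.sequences import read_localizations


def ev(frame, x=0.0, y=0.0, z=0.0, rec=""):
    return FlashEvent(frame=frame, position=(x, y, z), recording_id=rec)


def seq(bits, **kw):
    return FlashSequence.from_string(bits, **kw)


class TestFramesToSeconds:
    @pytest.mark.parametrize("n,fps,expected", [
        (30, 30, 1.0),
        (6, 30, 0.2),
        (0, 30, 0.0),
        (15, 30, 0.5),
    ])
    def test_conversions(self, n, fps, expected):
        assert frames_to_seconds(n, fps) == pytest.approx(expected)

    def test_longest_study_sequence_rounds_to_45_5(self):
        assert round(frames_to_seconds(1366, 30), 1) == 45.5

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            frames_to_seconds(10, 0)
        with pytest.raises(ValueError):
            frames_to_seconds(-1, 30)


class TestLinkStreaks:
    def test_consecutive_within_radius_one_streak(self):
        streaks = link_streaks([ev(0), ev(1, 0.05)], radius_m=0.2)
        assert len(streaks) == 1 and len(streaks[0]) == 2

    def test_outside_radius_two_streaks(self):
        streaks = link_streaks([ev(0), ev(1, 1.0)], radius_m=0.2)
        assert len(streaks) == 2

    def test_nonconsecutive_frames_two_streaks(self):
        streaks = link_streaks([ev(0), ev(5)], radius_m=100.0)
        assert len(streaks) == 2

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            link_streaks([ev(0)], radius_m=-1.0)

    def test_simultaneous_nearby_fireflies_stay_separate(self):
        # two detections per frame: each extends its own streak
        events = [ev(0, 0.0), ev(0, 0.15), ev(1, 0.0), ev(1, 0.15)]
        streaks = link_streaks(events, radius_m=0.2)
        assert sorted(len(s) for s in streaks) == [2, 2]

    def test_partition_no_event_lost(self):
        rng = np.random.default_rng(0)
        events = [ev(int(f), *rng.uniform(0, 5, 3))
                  for f in rng.integers(0, 50, size=80)]
        streaks = link_streaks(events, radius_m=0.3)
        assert sum(len(s) for s in streaks) == len(events)


class TestLinkTrajectories:
    def make_streak(self, start, end, pos):
        return Streak([ev(f, *pos) for f in range(start, end + 1)])

    def test_within_both_thresholds_linked(self):
        a = self.make_streak(0, 10, (0, 0, 0))
        b = self.make_streak(25, 30, (0.5, 0, 0))
        assert len(link_trajectories([a, b])) == 1

    def test_time_threshold_violated(self):
        a = self.make_streak(0, 10, (0, 0, 0))
        b = self.make_streak(56, 60, (0.5, 0, 0))  # 46 frames = 1.53 s gap
        assert len(link_trajectories([a, b])) == 2

    def test_distance_threshold_violated(self):
        a = self.make_streak(0, 10, (0, 0, 0))
        b = self.make_streak(25, 30, (2.0, 0, 0))
        assert len(link_trajectories([a, b])) == 2

    def test_transitive_closure(self):
        a = self.make_streak(0, 5, (0, 0, 0))
        b = self.make_streak(20, 25, (0.9, 0, 0))
        c = self.make_streak(40, 45, (1.8, 0, 0))  # far from a, near b
        trajs = link_trajectories([a, b, c])
        assert len(trajs) == 1 and len(trajs[0].streaks) == 3

    def test_empty_input(self):
        assert link_trajectories([]) == []

    def test_output_is_partition(self):
        rng = np.random.default_rng(1)
        streaks = []
        t = 0
        for _ in range(30):
            t += int(rng.integers(1, 60))
            length = int(rng.integers(1, 5))
            streaks.append(self.make_streak(t, t + length, rng.uniform(0, 4, 3)))
            t += length
        trajs = link_trajectories(streaks)
        linked = [s for traj in trajs for s in traj.streaks]
        assert len(linked) == len(streaks)
        assert {id(s) for s in linked} == {id(s) for s in streaks}


class TestTrajectoryToSequence:
    def test_two_streak_layout(self):
        streaks = [Streak([ev(f) for f in (100, 101, 102)]),
                   Streak([ev(f) for f in (110, 111)])]
        s = trajectory_to_sequence(Trajectory(streaks))
        assert s.bitstring() == "111000000011"
        assert len(s) == 12
        assert s.start_frame == 100

    def test_single_streak_no_gaps(self):
        s = trajectory_to_sequence(Trajectory([Streak([ev(f) for f in range(4)])]))
        assert s.bitstring() == "1111"

    def test_length_equals_frame_span(self):
        streaks = [Streak([ev(3)]), Streak([ev(17)])]
        s = trajectory_to_sequence(Trajectory(streaks))
        assert len(s) == 17 - 3 + 1


class TestCleanShortGaps:
    @pytest.mark.parametrize("raw,cleaned", [
        ("101", "111"),
        ("1001", "1111"),
        ("10001", "10001"),
        ("110110011000111", "111111111000111"),
    ])
    def test_examples(self, raw, cleaned):
        assert clean_short_gaps(seq(raw)).bitstring() == cleaned

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_idempotent_and_monotone(self, bits):
        bits = [1] + bits + [1]
        s = seq("".join(map(str, bits)))
        once = clean_short_gaps(s)
        twice = clean_short_gaps(once)
        assert once.bitstring() == twice.bitstring()
        assert once.bits.sum() >= s.bits.sum()
        assert len(once) == len(s)


class TestFilters:
    def test_single_flash_sequences_dropped(self):
        ds = SequenceDataset([seq("11011", species="a"), seq("111", species="a"),
                              seq("1", species="b")])
        kept = filter_single_flash(ds)
        assert [s.bitstring() for s in kept] == ["11011"]

    def test_all_ones_removed(self):
        assert len(filter_single_flash(SequenceDataset([seq("11111")]))) == 0

    def test_rare_species_dropped_and_labels_rebuilt(self):
        seqs = [seq("101", species="A") for _ in range(150)]
        seqs += [seq("101", species="B") for _ in range(99)]
        out = filter_rare_species(SequenceDataset(seqs), min_count=100)
        assert out.counts() == {"A": 150}
        assert out.label_map == {"A": 0}

    def test_min_count_one_is_identity(self):
        ds = SequenceDataset([seq("101", species="A"), seq("101", species="B")])
        assert len(filter_rare_species(ds, min_count=1)) == 2


class TestSequenceStats:
    def test_two_flash_layout(self):
        s = seq("111" + "0" * 9 + "1" * 6)
        stats = sequence_stats(s)
        assert stats.n_flashes == 2
        assert stats.flash_durations_s == pytest.approx([0.1, 0.2])
        assert stats.gaps_s == pytest.approx([0.3])

    def test_single_flash(self):
        stats = sequence_stats(seq("11111"))
        assert stats.n_flashes == 1
        assert stats.flash_durations_s == pytest.approx([5 / 30])
        assert stats.gaps_s == []

    @given(st.lists(st.integers(0, 1), min_size=0, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_invariants(self, bits):
        s = seq("".join(map(str, [1] + bits + [1])))
        stats = sequence_stats(s)
        assert len(stats.gaps_s) == stats.n_flashes - 1
        total_on = sum(stats.flash_durations_s)
        assert total_on == pytest.approx(s.bits.sum() / s.fps)

    @given(st.lists(st.integers(0, 1), min_size=0, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_stats_after_cleaning_match_pipeline_order(self, bits):
        s = seq("".join(map(str, [1] + bits + [1])))
        a = sequence_stats(clean_short_gaps(s))
        b = sequence_stats(clean_short_gaps(clean_short_gaps(s)))
        assert a == b


class TestSequenceValidity:
    def test_must_start_and_end_with_flash(self):
        with pytest.raises(ValueError):
            FlashSequence([0, 1, 1])
        with pytest.raises(ValueError):
            FlashSequence([1, 1, 0])

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            FlashSequence.from_string("10201")


class TestIO:
    def test_round_trip(self, tmp_path):
        ds = SequenceDataset([
            seq("110011", species="P. carolinus", recording_id="r1", start_frame=10),
            seq("101", species="P. knulli", recording_id="r2", start_frame=0),
            seq("11", species="P. carolinus"),
        ])
        path = tmp_path / "seqs.csv"
        write_sequences(ds, path)
        back = read_sequences(path)
        assert len(back) == 3
        for a, b in zip(ds.sequences, back.sequences):
            assert a.bitstring() == b.bitstring()
            assert a.species == b.species
            assert a.recording_id == b.recording_id
            assert a.start_frame == b.start_frame
        assert back.label_map == ds.label_map

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species,recording_id,start_frame,bits\na,r,0,1101\nb,r,x,101\n")
        with pytest.raises(ValueError, match="line 3"):
            read_sequences(path)

    def test_non_binary_bits_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("species,recording_id,start_frame,bits\na,r,0,10a01\n")
        with pytest.raises(ValueError):
            read_sequences(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert len(read_sequences(path)) == 0

    def test_localizations_round_trip_values(self, tmp_path):
        path = tmp_path / "loc.csv"
        path.write_text("recording_id,frame,x,y,z\nr1,0,0.1,0.2,0.3\nr1,1,0.1,0.2,0.35\n")
        events = read_localizations(path)
        assert [e.frame for e in events] == [0, 1]
        assert events[1].position == pytest.approx((0.1, 0.2, 0.35))
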