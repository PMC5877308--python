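"""Epoch reduction, merging and wear filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitstand.epochs import (
    ActivityLabel,
    EpochSeries,
    GridMismatchError,
    LabeledEpoch,
    MalformedWindowError,
    MergedPairSeries,
    SecondStream,
    align_and_merge,
    count_ambivalent,
    parse_label,
    reduce_seconds_to_epoch,
    reduce_stream,
    wear_filter,
)

from conftest import IDLE, SIT, STAND, WALK, brute_force_reduce, random_window


def make_stream(codes, start=0, subject="s1", source="ref"):
    codes = [c.value if isinstance(c, ActivityLabel) else c for c in codes]
    return SecondStream(
        subject, source, start + np.arange(len(codes), dtype=np.int64), codes
    )


class TestReduceSecondsToEpoch:
    @pytest.mark.parametrize(
        "composition, expected",
        [
            # (seconds of sit, stand, walk, idle) -> winner
            ((8, 11, 11, 0), STAND),  # two-way tie broken by priority
            ((10, 10, 10, 0), SIT),  # three-way tie: sitting wins
            ((30, 0, 0, 0), SIT),  # unanimous window
            ((0, 15, 15, 0), STAND),
            ((14, 0, 0, 16), IDLE),  # off strictly dominates
            ((15, 0, 0, 15), SIT),  # idle never wins a tie
            ((0, 0, 0, 30), IDLE),
            ((9, 10, 2, 9), STAND),
        ],
    )
    def test_dominance_and_priority(self, composition, expected):
        window = (
            [SIT] * composition[0]
            + [STAND] * composition[1]
            + [WALK] * composition[2]
            + [IDLE] * composition[3]
        )
        assert reduce_seconds_to_epoch(window) is expected

    def test_wrong_window_length_is_error(self):
        with pytest.raises(MalformedWindowError):
            reduce_seconds_to_epoch([SIT] * 29)
        with pytest.raises(MalformedWindowError):
            reduce_seconds_to_epoch([SIT] * 31)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(500):
            window = random_window(rng)
            assert reduce_seconds_to_epoch(window) is brute_force_reduce(window)

    @given(st.lists(st.sampled_from(list(ActivityLabel)), min_size=30, max_size=30))
    @settings(derandomize=True, max_examples=200)
    def test_permutation_invariant(self, window):
        shuffled = window[15:] + window[:15]
        assert reduce_seconds_to_epoch(window) is reduce_seconds_to_epoch(shuffled)

    @given(st.lists(st.sampled_from(list(ActivityLabel)), min_size=30, max_size=30))
    @settings(derandomize=True, max_examples=200)
    def test_winner_dominates_every_activity(self, window):
        winner = reduce_seconds_to_epoch(window)
        if winner is IDLE:
            return
        wins = window.count(winner)
        for other in (SIT, STAND, WALK):
            assert wins >= window.count(other)


class TestReduceStream:
    def test_unanimous_minute_gives_two_epochs(self):
        series = reduce_stream(make_stream([STAND] * 60))
        assert len(series) == 2
        assert series.labels == [STAND, STAND]
        assert list(series.starts) == [0, 30]

    def test_partial_trailing_epoch_dropped(self):
        series = reduce_stream(make_stream([SIT] * 45))
        assert len(series) == 1

    def test_partial_leading_epoch_dropped(self):
        series = reduce_stream(make_stream([SIT] * 60, start=15))
        # covers [15, 75): only [30, 60) is fully covered
        assert list(series.starts) == [30]

    def test_empty_stream_gives_empty_series(self):
        series = reduce_stream(make_stream([]))
        assert len(series) == 0

    def test_compositional_oracle(self, rng):
        codes = rng.choice(4, size=300)
        series = reduce_stream(make_stream(list(codes)))
        assert len(series) == 10
        for i, epoch in enumerate(series):
            window = [ActivityLabel(int(c)) for c in codes[i * 30 : (i + 1) * 30]]
            assert epoch.label is brute_force_reduce(window)

    def test_reduce_idempotence_on_epoch_constant_stream(self, rng):
        per_epoch = rng.choice(3, size=20)
        codes = np.repeat(per_epoch, 30)
        series = reduce_stream(make_stream(list(codes)))
        assert [c for c in series.codes] == list(per_epoch)

    def test_gap_splits_coverage(self):
        # 30 full seconds, a missing second, then 30 more: second epoch partial
        t = np.concatenate([np.arange(0, 30), np.arange(31, 61)])
        stream = SecondStream("s", "ref", t, np.zeros(60, dtype=np.int8))
        series = reduce_stream(stream)
        assert list(series.starts) == [0]


class TestCountAmbivalent:
    def test_unanimous_stream_has_none(self):
        assert count_ambivalent(make_stream([SIT] * 120)) == (0, 0.0)

    def test_one_tied_epoch_of_four(self):
        codes = [SIT] * 30 + [SIT] * 15 + [STAND] * 15 + [WALK] * 60
        count, pct = count_ambivalent(make_stream(codes))
        assert count == 1
        assert pct == pytest.approx(25.0)

    def test_thirteen_of_1789_is_073_percent(self):
        # any stream realizing 13 tied epochs among 1789 reduced epochs
        tied = [SIT] * 15 + [STAND] * 15
        codes = tied * 13 + [WALK] * 30 * (1789 - 13)
        count, pct = count_ambivalent(make_stream(codes))
        assert count == 13
        assert round(pct, 2) == 0.73


class TestAlignAndMerge:
    def make_series(self, starts, code=0, subject="s1", source="a"):
        starts = np.asarray(starts, dtype=np.int64)
        return EpochSeries(subject, source, starts, np.full(starts.size, code, np.int8))

    def test_identical_coverage_keeps_everything(self):
        a = self.make_series(np.arange(10) * 30)
        b = self.make_series(np.arange(10) * 30, code=1, source="b")
        merged = align_and_merge(a, b)
        assert len(merged) == 10
        assert merged.dropped_a_only == merged.dropped_b_only == 0

    def test_partial_overlap_drops_single_source_epochs(self):
        a = self.make_series(np.arange(10) * 30)  # epochs 0..9
        b = self.make_series(np.arange(2, 10) * 30, source="b")  # epochs 2..9
        merged = align_and_merge(a, b)
        assert len(merged) == 8
        assert merged.dropped_a_only == 2
        assert merged.dropped_b_only == 0

    def test_matches_set_intersection_oracle(self, rng):
        for _ in range(20):
            sa = np.flatnonzero(rng.random(50) < 0.7) * 30
            sb = np.flatnonzero(rng.random(50) < 0.7) * 30
            merged = align_and_merge(
                self.make_series(sa), self.make_series(sb, source="b")
            )
            assert set(merged.starts) == set(sa) & set(sb)

    def test_symmetric_membership(self, rng):
        sa = np.flatnonzero(rng.random(50) < 0.6) * 30
        sb = np.flatnonzero(rng.random(50) < 0.6) * 30
        ab = align_and_merge(self.make_series(sa), self.make_series(sb, source="b"))
        ba = align_and_merge(self.make_series(sb, source="b"), self.make_series(sa))
        assert list(ab.starts) == list(ba.starts)

    def test_subject_mismatch_is_error(self):
        a = self.make_series([0], subject="s1")
        b = self.make_series([0], subject="s2", source="b")
        with pytest.raises(GridMismatchError):
            align_and_merge(a, b)

    def test_off_grid_epoch_rejected_at_construction(self):
        with pytest.raises(GridMismatchError):
            LabeledEpoch(start=17, label=SIT)


class TestWearFilter:
    def make_day(self, n_epochs, day=0):
        starts = day * 86400 + np.arange(n_epochs, dtype=np.int64) * 30
        z = np.zeros(n_epochs, dtype=np.int8)
        return MergedPairSeries("s1", "a", "b", starts, z, z)

    def test_below_threshold_excluded(self):
        merged = self.make_day(599)  # 299.5 min
        retained, excluded = wear_filter(merged)
        assert retained == []
        assert excluded[0][1] == pytest.approx(299.5)

    def test_exactly_five_hours_retained(self):
        retained, excluded = wear_filter(self.make_day(600))  # 300.0 min
        assert len(retained) == 1 and excluded == []

    def test_typical_full_day_retained(self):
        retained, _ = wear_filter(self.make_day(1548))  # 774 min
        assert len(retained) == 1

    def test_days_filtered_independently(self):
        a, b = self.make_day(700, day=0), self.make_day(100, day=1)
        merged = MergedPairSeries(
            "s1", "a", "b",
            np.concatenate([a.starts, b.starts]),
            np.concatenate([a.codes_a, b.codes_a]),
            np.concatenate([a.codes_b, b.codes_b]),
        )
        retained, excluded = wear_filter(merged)
        assert [d for d, _ in retained] == [0]
        assert [d for d, _ in excluded] == [1]

    def test_timezone_offset_shifts_day_boundary(self):
        # epochs straddling UTC midnight belong to one local day at UTC+3
        starts = (86400 - 300 * 30) + np.arange(700, dtype=np.int64) * 30
        z = np.zeros(700, dtype=np.int8)
        merged = MergedPairSeries("s1", "a", "b", starts, z, z)
        split_utc, _ = wear_filter(merged, min_wear_minutes=0)
        split_local, _ = wear_filter(merged, min_wear_minutes=0, tz_offset_hours=3)
        assert len(split_utc) == 2
        assert len(split_local) == 1


def test_label_parsing_is_case_insensitive_and_strict():
    assert parse_label("Sitting") is SIT
    assert parse_label("OFF") is IDLE
    with pytest.raises(ValueError):
        parse_label("running")
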