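"""Episode detection: score mapping, window sweeps on constructed days,
the clean-up/join rules at their printed boundaries, major-episode
selection, button-constrained expansion, and bedrest growth."""

import numpy as np
import pytest

from actisleep.episodes import (
    CandidateEpisode,
    cleanup_join,
    detect_day,
    expand_bedrest,
    expand_with_buttons,
    provisional_sweep,
    select_major,
    sleep_scores,
)

N = 1440


def _classes(sleep=(330, 810), base=4, sleep_class=0):
    cls = np.full(N, base, dtype=np.int16)
    cls[sleep[0] : sleep[1]] = sleep_class
    return cls


def _scores_from_blocks(*blocks):
    """-1 everywhere except +1 inside the given [a, b) blocks."""
    s = np.full(N, -1.0)
    for a, b in blocks:
        s[a:b] = 1.0
    return s


class TestSleepScores:
    def test_mapping_and_missing(self):
        cls = np.array([0, 1, 2, 3, 4, -1])
        s = sleep_scores(cls)
        np.testing.assert_array_equal(s[:5], [1.0, 1.0, 0.0, -0.75, -1.0])
        assert np.isnan(s[5])


class TestProvisionalSweep:
    def test_single_night_recovered_within_five_minutes(self):
        s = _scores_from_blocks((330, 810))
        cands = provisional_sweep(s)
        assert len(cands) == 1
        assert abs(cands[0].start - 330) <= 5
        assert abs(cands[0].end - 810) <= 5

    def test_all_wake_day_yields_nothing(self):
        assert provisional_sweep(np.full(N, -1.0)) == []

    def test_two_separated_blocks_give_two_candidates(self):
        s = _scores_from_blocks((200, 380), (560, 740))
        cands = provisional_sweep(s)
        assert len(cands) == 2

    def test_missing_minutes_do_not_dilute_window_means(self):
        s = _scores_from_blocks((330, 810))
        s[500:560] = np.nan  # wrist-off inside the night
        cands = provisional_sweep(s)
        assert len(cands) == 1
        assert cands[0].start <= 340 and cands[0].end >= 800


class TestCleanupJoin:
    def test_short_gap_joined_unconditionally(self):
        s = _scores_from_blocks((300, 500), (520, 700))  # 20-min gap
        cands = [CandidateEpisode(300, 500), CandidateEpisode(520, 700)]
        out = cleanup_join(cands, s)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (300, 700)

    def test_gap_at_the_join_boundary(self):
        # 22 min <= 22.5 joins; 23 min with a hostile gap does not
        s = _scores_from_blocks((300, 500), (522, 700))
        out = cleanup_join([CandidateEpisode(300, 500), CandidateEpisode(522, 700)], s)
        assert len(out) == 1
        s2 = _scores_from_blocks((300, 500), (523, 700))
        out2 = cleanup_join([CandidateEpisode(300, 500), CandidateEpisode(523, 700)], s2)
        assert len(out2) == 2

    def test_dense_thirty_minute_gap_joined_by_cleanup_window(self):
        # all gap minutes +1: every spanning 90-min window holds 90 > 67.5
        s = _scores_from_blocks((300, 500), (500, 530), (530, 700))
        out = cleanup_join([CandidateEpisode(300, 500), CandidateEpisode(530, 700)], s)
        assert len(out) == 1

    def test_sparse_thirty_minute_gap_not_joined(self):
        s = _scores_from_blocks((300, 500), (530, 700))  # gap scored -1
        out = cleanup_join([CandidateEpisode(300, 500), CandidateEpisode(530, 700)], s)
        assert len(out) == 2


class TestSelectMajor:
    def test_longest_qualifying_candidate_wins(self):
        major, naps = select_major([CandidateEpisode(100, 190), CandidateEpisode(300, 700)])
        assert (major.start, major.end) == (300, 700)
        assert len(naps) == 1 and naps[0].kind == "nap"

    def test_ninety_nine_minutes_is_no_sleep(self):
        major, naps = select_major([CandidateEpisode(300, 399)])
        assert major is None
        assert len(naps) == 1

    def test_exactly_one_hundred_minutes_qualifies(self):
        major, _ = select_major([CandidateEpisode(300, 400)])
        assert major is not None

    def test_tie_breaks_to_earlier_start(self):
        major, _ = select_major([CandidateEpisode(500, 700), CandidateEpisode(100, 300)])
        assert major.start == 100


class TestExpandWithButtons:
    def test_expands_over_adjacent_low_activity(self):
        cls = _classes(sleep=(300, 810))
        major = CandidateEpisode(330, 810)
        onset, offset = expand_with_buttons(major, cls, presses=[])
        assert onset == 300
        assert offset == 810

    def test_evening_press_clamps_expansion(self):
        cls = _classes(sleep=(300, 810))
        major = CandidateEpisode(330, 810)
        onset, _ = expand_with_buttons(major, cls, presses=[320])
        assert onset == 320

    def test_press_beyond_sixty_minutes_is_unavailable(self):
        cls = _classes(sleep=(300, 810))
        major = CandidateEpisode(330, 810)
        onset, _ = expand_with_buttons(major, cls, presses=[330 - 90])
        assert onset == 300  # press ignored, full expansion

    def test_waking_press_clamps_offset(self):
        cls = _classes(sleep=(330, 840))
        major = CandidateEpisode(330, 810)
        _, offset = expand_with_buttons(major, cls, presses=[820])
        assert offset == 820

    def test_shrinks_past_high_activity_edge_minutes(self):
        cls = _classes(sleep=(330, 810))
        cls[330:340] = 3  # edge minutes above p25
        major = CandidateEpisode(330, 810)
        onset, _ = expand_with_buttons(major, cls, presses=[])
        assert onset == 340


class TestExpandBedrest:
    def test_grows_over_below_median_minutes(self):
        cls = _classes(sleep=(330, 810))
        cls[310:330] = 2
        cls[810:825] = 2
        b_on, b_off = expand_bedrest(330, 810, cls)
        assert (b_on, b_off) == (310, 825)

    def test_high_activity_neighbour_stops_growth(self):
        cls = _classes(sleep=(330, 810))  # A3 everywhere outside
        b_on, b_off = expand_bedrest(330, 810, cls)
        assert (b_on, b_off) == (330, 810)

    def test_never_crosses_another_candidate(self):
        cls = _classes(sleep=(330, 810))
        cls[200:330] = 2
        nap = CandidateEpisode(200, 260, kind="nap")
        b_on, _ = expand_bedrest(330, 810, cls, others=[nap])
        assert b_on == 260

    def test_bedrest_always_contains_sleep(self, rng):
        for _ in range(20):
            cls = rng.integers(0, 5, N)
            on = int(rng.integers(200, 600))
            off = int(rng.integers(on + 100, 1100))
            b_on, b_off = expand_bedrest(on, off, cls)
            assert b_on <= on and b_off >= off


class TestDetectDay:
    def test_constructed_day_end_to_end(self):
        cls = _classes(sleep=(330, 810))
        cls[310:330] = 1  # pre-sleep quiet minutes
        cls[810:830] = 2  # drowsy tail -> bedrest only
        episode = detect_day(cls, presses=[315], day_index=5)
        assert not episode.no_sleep
        assert episode.sleep_onset == 315  # clamped at the evening press
        assert episode.sleep_offset == 810
        assert episode.bedrest_offset == 830
        assert episode.day_index == 5

    def test_identical_input_identical_output(self, rng):
        cls = rng.integers(0, 5, N)
        cls[400:800] = 0
        a = detect_day(cls.copy(), presses=[390])
        b = detect_day(cls.copy(), presses=[390])
        assert (a.sleep_onset, a.sleep_offset) == (b.sleep_onset, b.sleep_offset)
        assert (a.bedrest_onset, a.bedrest_offset) == (b.bedrest_onset, b.bedrest_offset)

    def test_all_wake_day_is_no_sleep(self):
        episode = detect_day(np.full(N, 4, dtype=np.int16))
        assert episode.no_sleep

    def test_interior_wake_burst_cannot_extend_the_episode(self):
        cls = _classes(sleep=(330, 810))
        base = detect_day(cls)
        cls2 = cls.copy()
        cls2[550:600] = 4  # wake burst strictly inside the night
        split = detect_day(cls2)
        margin = 23  # join rule can bridge up to the 22.5-min convention
        if not split.no_sleep:
            assert split.sleep_onset >= base.sleep_onset - margin
            assert split.sleep_offset <= base.sleep_offset + margin

    def test_heavily_wrist_off_episode_flagged_low_confidence(self):
        cls = _classes(sleep=(330, 810))
        # scatter wrist-off over ~a third of the night without splitting it
        cls[330:810:3] = -1
        episode = detect_day(cls)
        assert not episode.no_sleep
        assert episode.low_confidence

    def test_parameter_recovery_on_synthetic_study(self, small_study):
        schedule, _, _, result = small_study
        onset_err, offset_err = [], []
        for day, episode, truth in zip(result.days, result.episodes, schedule.days):
            assert not episode.no_sleep
            onset_err.append(abs(episode.sleep_onset - truth.sleep_onset))
            offset_err.append(abs(episode.sleep_offset - truth.sleep_offset))
        assert np.median(onset_err) <= 10
        assert np.median(offset_err) <= 10
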