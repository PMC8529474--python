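"""Daily metrics: bout counting against a run-length oracle, the Box-1
variable relations, the average sleep day and STRI against brute force,
and the 14-day sliding summaries' missing-tolerance contract."""

import numpy as np
import pytest

from actisleep.activity import PercentileThresholds
from actisleep.episodes import SleepEpisode
from actisleep.ingest import DAY_MINUTES
from actisleep.metrics import (
    average_sleep_day,
    box1_metrics,
    count_bouts,
    sliding_summary,
    stri_day,
    stri_table,
)


def _rle_bouts(mask, tolerance):
    """Oracle: merge runs separated by <= tolerance, then count."""
    runs = []
    in_run = False
    for i, v in enumerate(mask):
        if v and not in_run:
            runs.append([i, i + 1])
            in_run = True
        elif v:
            runs[-1][1] = i + 1
        else:
            in_run = False
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= tolerance:
            merged[-1][1] = r[1]
        else:
            merged.append(list(r))
    return len(merged)


class TestCountBouts:
    @pytest.mark.parametrize(
        "mask,tol,expected",
        [
            ([1, 1, 0, 1, 1], 1, 1),
            ([1, 0, 0, 1], 1, 2),
            ([0, 0, 0], 1, 0),
            ([1], 0, 1),
            ([1, 0, 1, 0, 1], 0, 3),
        ],
    )
    def test_examples(self, mask, tol, expected):
        assert count_bouts(np.array(mask, dtype=bool), tol) == expected

    def test_matches_rle_oracle_on_random_masks(self, rng):
        for _ in range(1000):
            mask = rng.random(rng.integers(1, 60)) < 0.4
            tol = int(rng.integers(0, 3))
            assert count_bouts(mask, tol) == _rle_bouts(mask, tol)

    def test_reversal_invariance(self, rng):
        for _ in range(200):
            mask = rng.random(50) < 0.5
            tol = int(rng.integers(0, 3))
            assert count_bouts(mask, tol) == count_bouts(mask[::-1], tol)


def _episode(onset=330, offset=810, b_on=None, b_off=None):
    return SleepEpisode(
        0, onset, offset,
        bedrest_onset=onset if b_on is None else b_on,
        bedrest_offset=offset if b_off is None else b_off,
    )


def _thresholds():
    # pooled powers 0..1 uniform -> p40 = 0.4
    return PercentileThresholds(np.linspace(0, 1, 10001), (10.0, 25.0, 40.0, 50.0, 75.0))


class TestBox1Metrics:
    def _arrays(self, power_val=0.1):
        power = np.full(DAY_MINUTES, 0.9)
        power[330:810] = power_val
        classes = np.full(DAY_MINUTES, 4, dtype=np.int16)
        classes[330:810] = 0
        wrist_off = np.zeros(DAY_MINUTES, dtype=bool)
        light = np.full(DAY_MINUTES, 100.0)
        light[330:810] = 0.1
        return power, classes, wrist_off, light

    def test_quiet_dark_night(self):
        power, classes, wrist_off, light = self._arrays()
        m = box1_metrics(
            _episode(b_on=310, b_off=820), power, classes, wrist_off, _thresholds(),
            light=light, phone_mask=np.zeros(DAY_MINUTES, dtype=bool),
        )
        assert m.SleepDuration == 480
        assert m.ImmobileMinutes == 480
        assert m.ActiveMinutes == 0
        assert m.ActiveBouts == 0
        assert m.SleepImmobility == 100.0
        assert m.LightMinutes == 0 and m.PhoneMinutes == 0
        assert m.BedrestDuration == 510
        assert m.SleepOnsetLatency == 20
        assert m.SleepEfficiency == pytest.approx(100 * 480 / 510)
        assert m.SleepOnset == "23:30" and m.SleepOffset == "07:30"

    def test_light_burst_counts_minutes_and_one_bout(self):
        power, classes, wrist_off, light = self._arrays()
        light[340:343] = 2.0  # minutes 10-12 of sleep
        m = box1_metrics(
            _episode(), power, classes, wrist_off, _thresholds(), light=light
        )
        assert m.LightMinutes == 3
        assert m.LightBouts == 1

    def test_light_at_exactly_one_lux_not_counted(self):
        power, classes, wrist_off, light = self._arrays()
        light[400:410] = 1.0
        m = box1_metrics(_episode(), power, classes, wrist_off, _thresholds(), light=light)
        assert m.LightMinutes == 0

    def test_activity_at_p40_boundary_is_active(self):
        power, classes, wrist_off, _ = self._arrays()
        thr = _thresholds()
        power[400:420] = thr.threshold(40)  # exactly the cut
        m = box1_metrics(_episode(), power, classes, wrist_off, thr)
        assert m.ActiveMinutes == 20
        assert m.ImmobileMinutes == 460

    def test_planted_arousals_match_bout_oracle(self, rng):
        power, classes, wrist_off, _ = self._arrays()
        starts = [400, 500, 620]
        for s in starts:
            power[s : s + 5] = 0.95
        m = box1_metrics(_episode(), power, classes, wrist_off, _thresholds())
        assert m.ActiveBouts == 3
        assert m.ActiveMinutes == 15

    def test_missing_channels_leave_fields_none(self):
        power, classes, wrist_off, _ = self._arrays()
        m = box1_metrics(_episode(), power, classes, wrist_off, _thresholds())
        assert m.LightMinutes is None and m.PhoneMinutes is None
        assert m.ImmobileMinutes is not None

    def test_active_plus_immobile_equals_valid_sleep_minutes(self, rng):
        power = rng.random(DAY_MINUTES)
        classes = np.zeros(DAY_MINUTES, dtype=np.int16)
        wrist_off = rng.random(DAY_MINUTES) < 0.1
        power[wrist_off] = np.nan
        classes[wrist_off] = -1
        m = box1_metrics(_episode(), power, classes, wrist_off, _thresholds())
        valid = (~wrist_off[330:810]).sum()
        assert m.ActiveMinutes + m.ImmobileMinutes == valid
        assert 0 <= m.SleepImmobility <= 100

    def test_no_sleep_day_reports_offwrist_only(self):
        _, _, wrist_off, _ = self._arrays()
        wrist_off[:144] = True
        e = SleepEpisode(3, None, None, no_sleep=True)
        m = box1_metrics(e, np.zeros(DAY_MINUTES), np.zeros(DAY_MINUTES), wrist_off, _thresholds())
        assert m.no_sleep
        assert m.OffWrist == pytest.approx(10.0)
        assert m.SleepDuration is None


class TestAverageSleepDay:
    def test_identical_episodes_reproduce_their_mask(self):
        mask = np.zeros(DAY_MINUTES, dtype=bool)
        mask[330:810] = True
        avg = average_sleep_day(np.stack([mask] * 5))
        np.testing.assert_array_equal(avg, mask)

    def test_mask_cardinality_equals_rounded_mean_duration(self):
        a = np.zeros(DAY_MINUTES, dtype=bool)
        b = np.zeros(DAY_MINUTES, dtype=bool)
        a[300:780] = True  # 480
        b[420:900] = True  # 480
        avg = average_sleep_day(np.stack([a, b]))
        assert avg.sum() == 480

    def test_matches_brute_force_top_d_selection(self, rng):
        masks = rng.random((10, DAY_MINUTES)) < 0.3
        avg = average_sleep_day(masks)
        freq = masks.mean(axis=0)
        d = int(round(masks.sum(axis=1).mean()))
        order = sorted(range(DAY_MINUTES), key=lambda i: (-freq[i], i))
        expected = np.zeros(DAY_MINUTES, dtype=bool)
        expected[order[:d]] = True
        np.testing.assert_array_equal(avg, expected)

    def test_fewer_than_two_days_rejected(self):
        with pytest.raises(ValueError, match="2 valid days"):
            average_sleep_day(np.zeros((1, DAY_MINUTES), dtype=bool))


class TestStri:
    def test_identical_day_scores_one(self):
        mask = np.zeros(DAY_MINUTES, dtype=bool)
        mask[330:810] = True
        assert stri_day(mask, mask) == 1.0

    def test_complementary_twelve_hour_schedules_score_zero(self):
        day = np.zeros(DAY_MINUTES, dtype=bool)
        day[:720] = True
        assert stri_day(day, ~day) == 0.0

    def test_matches_brute_force_minute_comparison(self, rng):
        day = rng.random(DAY_MINUTES) < 0.3
        avg = rng.random(DAY_MINUTES) < 0.3
        expected = sum(bool(a) == bool(b) for a, b in zip(day, avg)) / DAY_MINUTES
        assert stri_day(day, avg) == pytest.approx(expected)

    def test_sleep_only_denominator_mode(self):
        avg = np.zeros(DAY_MINUTES, dtype=bool)
        avg[300:700] = True
        day = np.zeros(DAY_MINUTES, dtype=bool)
        day[300:500] = True
        assert stri_day(day, avg, denominator="sleep") == pytest.approx(0.5)

    def test_onset_shift_strictly_lowers_stri(self):
        base = np.zeros(DAY_MINUTES, dtype=bool)
        base[330:810] = True
        shifted = np.roll(base, 60)
        assert stri_day(shifted, base) < stri_day(base, base)

    def test_regular_schedule_scores_one_every_day(self):
        episodes = [
            SleepEpisode(d, 330, 810, bedrest_onset=330, bedrest_offset=810)
            for d in range(10)
        ]
        table = stri_table(episodes)
        np.testing.assert_allclose(table["stri"].to_numpy(), 1.0)


class TestSlidingSummary:
    def test_constant_series_is_constant_once_window_fills(self):
        out = sliding_summary(np.full(30, 5.0), window=14, max_missing=3)
        assert np.all(np.isnan(out[:10]))  # window still reaches before day 0
        np.testing.assert_allclose(out[10:], 5.0)

    def test_four_missing_days_blank_the_window(self):
        v = np.full(40, 2.0)
        v[20:24] = np.nan
        out = sliding_summary(v, window=14, max_missing=3)
        assert np.all(np.isnan(out[23:34]))  # windows holding all 4 gaps
        assert out[34] == pytest.approx(2.0)  # window [21, 34]: 3 gaps, tolerated

    def test_three_missing_days_tolerated(self):
        v = np.full(30, 2.0)
        v[20:23] = np.nan
        out = sliding_summary(v, window=14, max_missing=3)
        assert out[22] == pytest.approx(2.0)

    def test_matches_brute_force_with_random_gaps(self, rng):
        v = rng.normal(0, 1, 60)
        v[rng.random(60) < 0.2] = np.nan
        out = sliding_summary(v, window=14, max_missing=3)
        for d in range(60):
            window = [v[i] if i >= 0 else np.nan for i in range(d - 13, d + 1)]
            missing = sum(np.isnan(w) for w in window)
            if missing > 3:
                assert np.isnan(out[d])
            else:
                vals = [w for w in window if not np.isnan(w)]
                assert out[d] == pytest.approx(np.mean(vals))
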