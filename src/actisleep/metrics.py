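"""Daily sleep metrics, bout counts, and the Sleep Timing Regularity Index.

The per-day variable set comprises wrist-off percentage, sleep and bedrest
onset/offset/duration, sleep-onset latency, sleep efficiency
(100 * SleepDuration / BedrestDuration), active/immobile minutes split at
the within-individual 40th activity percentile, bout counts with a
1-minute tolerance, light exposure (> 1 lux) minutes and bouts during
sleep, and phone-event minutes and bouts during sleep.

The Sleep Timing Regularity Index (STRI) compares each day's minute-level
sleep/wake pattern with the participant's *average sleep day*: the D
clock minutes most frequently slept across the study, with D the rounded
mean daily sleep duration. By default the index is the proportion of all
1440 minutes on which the day agrees with the average day (1 = identical
timing, 0 = perfect 12-h-complement mismatch at D = 720).

Longitudinal series are smoothed with a backward 14-day sliding window
that goes missing when more than 3 of its days are missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import MISSING_CLASS, PercentileThresholds
from .episodes import SleepEpisode
from .ingest import DAY_MINUTES, slot_to_clock


def count_bouts(mask: np.ndarray, tolerance: int = 1) -> int:
    """Number of bouts: maximal runs of True where runs separated by at
    most ``tolerance`` False minutes count as one bout."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return 0
    idx = np.nonzero(m)[0]
    gaps = np.diff(idx) - 1
    return int(1 + np.sum(gaps > tolerance))


@dataclass
class SleepMetrics:
    """The daily variable set (Box-1 names)."""

    day_index: int
    OffWrist: float
    SleepOnset: str | None
    SleepOffset: str | None
    SleepDuration: float | None
    BedrestOnset: str | None
    BedrestOffset: str | None
    BedrestDuration: float | None
    SleepOnsetLatency: float | None
    SleepEfficiency: float | None
    ActiveMinutes: float | None
    ImmobileMinutes: float | None
    ActiveBouts: float | None
    SleepImmobility: float | None
    LightMinutes: float | None
    LightBouts: float | None
    PhoneMinutes: float | None
    PhoneBouts: float | None
    no_sleep: bool = False


def box1_metrics(
    episode: SleepEpisode,
    smoothed_power: np.ndarray,
    classes: np.ndarray,
    wrist_off: np.ndarray,
    thresholds: PercentileThresholds,
    light: np.ndarray | None = None,
    phone_mask: np.ndarray | None = None,
    immobility_percentile: float = 40.0,
    light_threshold_lux: float = 1.0,
    bout_tolerance: int = 1,
) -> SleepMetrics:
    """Compute the daily variable set for one finalized episode.

    ``smoothed_power``, ``classes``, ``wrist_off``, ``light`` and
    ``phone_mask`` are 1440-slot day arrays. Missing light or phone
    channels leave the corresponding fields None.
    """
    off_pct = 100.0 * float(np.asarray(wrist_off, dtype=bool).sum()) / DAY_MINUTES
    if episode.no_sleep:
        return SleepMetrics(
            episode.day_index, off_pct, None, None, None, None, None, None, None,
            None, None, None, None, None, None, None, None, None, no_sleep=True,
        )

    on, off = episode.sleep_onset, episode.sleep_offset
    b_on = episode.bedrest_onset if episode.bedrest_onset is not None else on
    b_off = episode.bedrest_offset if episode.bedrest_offset is not None else off
    duration = float(off - on)
    bedrest = float(b_off - b_on)
    latency = float(on - b_on)
    efficiency = 100.0 * duration / bedrest if bedrest > 0 else None

    power = np.asarray(smoothed_power, dtype=np.float64)[on:off]
    valid = ~np.isnan(power) & (np.asarray(classes)[on:off] != MISSING_CLASS)
    p40 = thresholds.threshold(immobility_percentile)
    # equality goes to active; "higher than p40" vs "lower than p40" leaves
    # the boundary unassigned in the definitions
    active_mask = valid & (power >= p40)
    active = float(active_mask.sum())
    immobile = float((valid & (power < p40)).sum())
    n_valid = active + immobile
    immobility = 100.0 * immobile / n_valid if n_valid > 0 else None
    active_bouts = float(count_bouts(active_mask, bout_tolerance))

    light_minutes = light_bouts = None
    if light is not None:
        lx = np.asarray(light, dtype=np.float64)[on:off]
        light_mask = ~np.isnan(lx) & (lx > light_threshold_lux)
        light_minutes = float(light_mask.sum())
        light_bouts = float(count_bouts(light_mask, bout_tolerance))

    phone_minutes = phone_bouts = None
    if phone_mask is not None:
        pm = np.asarray(phone_mask, dtype=bool)[on:off]
        phone_minutes = float(pm.sum())
        phone_bouts = float(count_bouts(pm, bout_tolerance))

    return SleepMetrics(
        day_index=episode.day_index,
        OffWrist=off_pct,
        SleepOnset=slot_to_clock(on),
        SleepOffset=slot_to_clock(off),
        SleepDuration=duration,
        BedrestOnset=slot_to_clock(b_on),
        BedrestOffset=slot_to_clock(b_off),
        BedrestDuration=bedrest,
        SleepOnsetLatency=latency,
        SleepEfficiency=efficiency,
        ActiveMinutes=active,
        ImmobileMinutes=immobile,
        ActiveBouts=active_bouts,
        SleepImmobility=immobility,
        LightMinutes=light_minutes,
        LightBouts=light_bouts,
        PhoneMinutes=phone_minutes,
        PhoneBouts=phone_bouts,
    )


def average_sleep_day(
    sleep_masks: np.ndarray, day_valid: np.ndarray | None = None
) -> np.ndarray:
    """The participant's average sleep day as a 1440-slot boolean mask.

    Per clock slot the asleep-frequency across valid days is computed; the
    mask selects the D most frequently slept slots, with D the rounded mean
    daily sleep duration over valid days. Frequency ties break to the
    earlier slot in the 6 PM -> 6 PM ordering. The mask is not forced to
    be contiguous.
    """
    masks = np.asarray(sleep_masks, dtype=bool)
    if masks.ndim != 2 or masks.shape[1] != DAY_MINUTES:
        raise ValueError("sleep_masks must be (n_days, 1440)")
    if day_valid is not None:
        masks = masks[np.asarray(day_valid, dtype=bool)]
    if len(masks) < 2:
        raise ValueError("average sleep day needs at least 2 valid days")
    freq = masks.mean(axis=0)
    d = int(round(float(masks.sum(axis=1).mean())))
    mask = np.zeros(DAY_MINUTES, dtype=bool)
    if d > 0:
        order = np.lexsort((np.arange(DAY_MINUTES), -freq))
        mask[order[:d]] = True
    return mask


def stri_day(
    day_mask: np.ndarray, average_mask: np.ndarray, denominator: str = "day"
) -> float:
    """Sleep Timing Regularity Index of one day against the average day.

    ``denominator="day"``: proportion of all 1440 minutes on which the
    day's asleep-state equals the average day's (sleep and wake minutes
    both count as agreement). ``denominator="sleep"``: proportion of the
    average day's sleep minutes the day also spent asleep.
    """
    day = np.asarray(day_mask, dtype=bool)
    avg = np.asarray(average_mask, dtype=bool)
    if day.shape != avg.shape:
        raise ValueError("masks must share the 1440-slot grid")
    if denominator == "day":
        return float((day == avg).mean())
    if denominator == "sleep":
        d = int(avg.sum())
        return float((day & avg).sum() / d) if d else math.nan
    raise ValueError(f"denominator must be day/sleep, got {denominator!r}")


def sliding_summary(
    series: np.ndarray | pd.Series,
    window: int = 14,
    max_missing: int = 3,
) -> np.ndarray:
    """Backward sliding-window mean of a daily series.

    ``value(d)`` is the mean of the present values over days
    ``[d - window + 1, d]``; the output is missing when more than
    ``max_missing`` of the window's days are missing (NaN), and at the
    start of the series while the window extends before day 0.
    """
    v = np.asarray(series, dtype=np.float64)
    n = len(v)
    out = np.full(n, np.nan)
    ok = ~np.isnan(v)
    csum = np.concatenate([[0.0], np.cumsum(np.where(ok, v, 0.0))])
    ccnt = np.concatenate([[0], np.cumsum(ok)])
    for d in range(n):
        lo = d - window + 1
        missing = window - (ccnt[d + 1] - ccnt[max(lo, 0)])
        if missing > max_missing:
            continue
        c = ccnt[d + 1] - ccnt[max(lo, 0)]
        if c > 0:
            out[d] = (csum[d + 1] - csum[max(lo, 0)]) / c
    return out


def metrics_table(metrics: list[SleepMetrics]) -> pd.DataFrame:
    """One row per day with the Box-1 column names."""
    return pd.DataFrame([m.__dict__ for m in metrics]).set_index("day_index")


def stri_table(
    episodes: list[SleepEpisode],
    day_valid: np.ndarray | None = None,
    denominator: str = "day",
    window: int = 14,
    max_missing: int = 3,
    immobility: np.ndarray | None = None,
) -> pd.DataFrame:
    """Daily STRI plus smoothed duration/STRI(/immobility) series.

    ``day_valid`` marks days with usable data (invalid days yield NaN and
    count as missing in the smoothing windows).
    """
    n = len(episodes)
    valid = np.ones(n, dtype=bool) if day_valid is None else np.asarray(day_valid, dtype=bool)
    masks = np.stack([e.sleep_mask() for e in episodes])
    durations = np.array(
        [float(e.duration) if (valid[i] and not e.no_sleep) else np.nan for i, e in enumerate(episodes)]
    )
    # the average day is formed from valid days that have a sleep episode
    avg = average_sleep_day(masks[valid & ~np.isnan(durations)])
    stri = np.array(
        [stri_day(masks[i], avg, denominator) if valid[i] else np.nan for i in range(n)]
    )
    out = pd.DataFrame(
        {
            "day_index": [e.day_index for e in episodes],
            "stri": stri,
            "smoothed_duration": sliding_summary(durations, window, max_missing),
            "smoothed_stri": sliding_summary(stri, window, max_missing),
        }
    ).set_index("day_index")
    if immobility is not None:
        out["smoothed_immobility"] = sliding_summary(
            np.asarray(immobility, dtype=np.float64), window, max_missing
        )
    return out


__all__ = [
    "count_bouts",
    "SleepMetrics",
    "box1_metrics",
    "average_sleep_day",
    "stri_day",
    "sliding_summary",
    "metrics_table",
    "stri_table",
]
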