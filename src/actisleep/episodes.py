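"""Major Sleep Episode detection for one 6 PM -> 6 PM analysis day.

The activity classes are first mapped to weighted sleep scores:

    A0, A1 (< p25)  -> +1        A2 (p25..p50) ->  0
    A3 (p50..p75)   -> -0.75     A4 (>= p75)   -> -1

A wide (100-min) centered moving mean of the scores seeds provisional
nocturnal episodes; a narrow (60-min) window refines each seed's edges. A
90-minute clean-up window connects adjacent short candidates whose joining
gap is densely sleep-scored, and candidates within 22.5 minutes of one
another are joined unconditionally. The longest candidate of at least 100
minutes becomes the day's major Sleep Episode (shorter ones are naps; none
qualifying flags the day no-sleep). The major episode is then expanded or
shrunk over adjacent below-25th-percentile minutes, constrained by the
evening and waking button presses when one was recorded within 60 minutes
of the estimate, and finally the surrounding bedrest interval extends over
adjacent below-median-activity minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import MISSING_CLASS
from .config import PipelineConfig, DEFAULT_CONFIG
from .ingest import DAY_MINUTES, slot_to_clock

#: sleep-score values per activity class A0..A4
SCORE_BY_CLASS = np.array([1.0, 1.0, 0.0, -0.75, -1.0])


@dataclass
class CandidateEpisode:
    """Half-open slot interval [start, end) within one analysis day."""

    start: int
    end: int
    kind: str = "major"  # "major" | "nap"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty candidate [{self.start}, {self.end})")

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class SleepEpisode:
    """Final sleep and bedrest bounds of one analysis day (slot units)."""

    day_index: int
    sleep_onset: int | None
    sleep_offset: int | None
    bedrest_onset: int | None = None
    bedrest_offset: int | None = None
    no_sleep: bool = False
    provenance: str = "auto"
    low_confidence: bool = False
    naps: list[CandidateEpisode] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.no_sleep:
            if self.sleep_onset is None or self.sleep_offset is None:
                raise ValueError("sleep bounds required unless no_sleep")
            if not self.sleep_onset < self.sleep_offset:
                raise ValueError("sleep_onset must precede sleep_offset")
            if self.bedrest_onset is not None and self.bedrest_onset > self.sleep_onset:
                raise ValueError("bedrest_onset must not follow sleep_onset")
            if self.bedrest_offset is not None and self.bedrest_offset < self.sleep_offset:
                raise ValueError("bedrest_offset must not precede sleep_offset")

    @property
    def duration(self) -> int:
        return 0 if self.no_sleep else self.sleep_offset - self.sleep_onset

    def clock(self, which: str) -> str | None:
        slot = getattr(self, which)
        return None if slot is None else slot_to_clock(slot)

    def sleep_mask(self) -> np.ndarray:
        mask = np.zeros(DAY_MINUTES, dtype=bool)
        if not self.no_sleep:
            mask[self.sleep_onset : self.sleep_offset] = True
        return mask


def sleep_scores(classes: np.ndarray) -> np.ndarray:
    """Weighted sleep score per slot; missing/wrist-off minutes yield NaN
    and are excluded from every window mean downstream."""
    cls = np.asarray(classes)
    scores = np.full(len(cls), np.nan)
    ok = cls != MISSING_CLASS
    scores[ok] = SCORE_BY_CLASS[cls[ok]]
    return scores


def _centered_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean over present slots, truncated at edges.

    For even windows the span is [t - W/2, t + W/2 - 1]. All-missing
    windows yield NaN.
    """
    v = np.asarray(values, dtype=np.float64)
    ok = ~np.isnan(v)
    csum = np.concatenate([[0.0], np.cumsum(np.where(ok, v, 0.0))])
    ccnt = np.concatenate([[0], np.cumsum(ok)])
    n = len(v)
    half = window // 2
    t = np.arange(n)
    lo = np.maximum(t - half, 0)
    hi = np.minimum(t + (window - half - 1), n - 1) + 1
    s = csum[hi] - csum[lo]
    c = ccnt[hi] - ccnt[lo]
    return np.where(c > 0, s / np.maximum(c, 1), np.nan)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    return list(zip(starts, ends))


def provisional_sweep(
    scores: np.ndarray,
    wide: int = 100,
    narrow: int = 60,
    seed_threshold: float = 0.5,
    edge_threshold: float = 0.0,
) -> list[CandidateEpisode]:
    """Seed candidate episodes with the wide window, refine edges with the
    narrow window.

    Slots whose centered ``wide``-minute score mean exceeds
    ``seed_threshold`` form seed runs. Each seed's edges then move outward
    while the centered ``narrow``-minute mean just outside stays above
    ``edge_threshold``, and inward while the mean at the edge has dropped
    to ``edge_threshold`` or below. Overlapping refined runs merge.
    """
    s = np.asarray(scores, dtype=np.float64)
    n = len(s)
    m_wide = _centered_mean(s, wide)
    m_narrow = _centered_mean(s, narrow)
    above = np.where(np.isnan(m_narrow), -np.inf, m_narrow) > edge_threshold

    refined: list[tuple[int, int]] = []
    with np.errstate(invalid="ignore"):
        seed_mask = np.nan_to_num(m_wide, nan=-np.inf) > seed_threshold
    for s0, e0 in _runs(seed_mask):
        start, end = s0, e0
        while start - 1 >= 0 and above[start - 1]:
            start -= 1
        while start < end and not above[start]:
            start += 1
        while end < n and above[end]:
            end += 1
        while end > start and not above[end - 1]:
            end -= 1
        if end > start:
            refined.append((start, end))

    refined.sort()
    merged: list[list[int]] = []
    for start, end in refined:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [CandidateEpisode(a, b) for a, b in merged]


def cleanup_join(
    candidates: list[CandidateEpisode],
    scores: np.ndarray,
    cleanup_window: int = 90,
    cleanup_fraction: float = 0.75,
    join_gap: float = 22.5,
) -> list[CandidateEpisode]:
    """Connect and join adjacent candidate episodes.

    Phase 1 (clean-up window): two neighbours merge when every
    ``cleanup_window``-minute window that spans their gap contains more
    than ``cleanup_fraction`` of the window in minutes scored +1.
    Phase 2 (convention): any remaining gap of at most ``join_gap`` minutes
    merges unconditionally.
    """
    s = np.asarray(scores, dtype=np.float64)
    n = len(s)
    plus = np.concatenate([[0], np.cumsum(s == 1.0)])
    need = cleanup_fraction * cleanup_window

    def dense(a_end: int, b_start: int) -> bool:
        if b_start - a_end >= cleanup_window:
            return False
        w_lo = max(b_start - cleanup_window, 0)
        w_hi = min(a_end, n - cleanup_window)
        if w_hi < w_lo:
            return False
        starts = np.arange(w_lo, w_hi + 1)
        counts = plus[starts + cleanup_window] - plus[starts]
        return bool(np.all(counts > need))

    def merge_pass(cands: list[CandidateEpisode], rule) -> list[CandidateEpisode]:
        out = [CandidateEpisode(c.start, c.end) for c in sorted(cands, key=lambda c: c.start)]
        i = 0
        while i + 1 < len(out):
            a, b = out[i], out[i + 1]
            if rule(a.end, b.start):
                out[i] = CandidateEpisode(a.start, max(a.end, b.end))
                del out[i + 1]
            else:
                i += 1
        return out

    cands = merge_pass(candidates, dense)
    cands = merge_pass(cands, lambda a_end, b_start: b_start - a_end <= join_gap)
    return cands


def select_major(
    candidates: list[CandidateEpisode], min_duration: int = 100
) -> tuple[CandidateEpisode | None, list[CandidateEpisode]]:
    """Pick the major episode: longest candidate of at least
    ``min_duration`` minutes; ties break to the earlier start. Returns
    ``(major, naps)``; major is None when no candidate qualifies."""
    if not candidates:
        return None, []
    ordered = sorted(candidates, key=lambda c: (-c.duration, c.start))
    major = ordered[0] if ordered[0].duration >= min_duration else None
    naps = [
        CandidateEpisode(c.start, c.end, kind="nap")
        for c in sorted(candidates, key=lambda c: c.start)
        if c is not major
    ]
    return major, naps


def _available_press(presses: list[int], estimate: int, avail: int) -> int | None:
    """Nearest press within ``avail`` minutes of the estimated slot."""
    close = [p for p in presses if abs(p - estimate) <= avail]
    return min(close, key=lambda p: (abs(p - estimate), p)) if close else None


def expand_with_buttons(
    major: CandidateEpisode,
    classes: np.ndarray,
    presses: list[int],
    button_avail: int = 60,
) -> tuple[int, int]:
    """Final sleep bounds: expand/shrink the major episode over adjacent
    below-25th-percentile (A0/A1) minutes, constrained by button presses.

    The onset moves earlier over contiguous A0/A1 minutes but never before
    an available evening press (one recorded within ``button_avail``
    minutes of the provisional onset); the offset mirrors this with the
    waking press. Edge minutes not below the 25th percentile are shrunk
    past first.
    """
    cls = np.asarray(classes)
    low = (cls == 0) | (cls == 1)
    n = len(cls)
    onset, offset = major.start, major.end

    evening = _available_press(presses, onset, button_avail)
    waking = _available_press(presses, offset, button_avail)

    while onset < offset - 1 and not low[onset]:
        onset += 1
    lo_bound = evening if evening is not None else 0
    while onset - 1 >= lo_bound and low[onset - 1]:
        onset -= 1
    if evening is not None:
        onset = max(onset, min(evening, offset - 1))

    while offset > onset + 1 and not low[offset - 1]:
        offset -= 1
    hi_bound = min(waking, n) if waking is not None else n
    while offset < hi_bound and low[offset]:
        offset += 1
    if waking is not None:
        offset = max(min(offset, waking), onset + 1)

    return onset, offset


def expand_bedrest(
    onset: int,
    offset: int,
    classes: np.ndarray,
    others: list[CandidateEpisode] | None = None,
) -> tuple[int, int]:
    """Bedrest bounds: extend over contiguous below-median (A0..A2)
    minutes beyond the sleep bounds, never crossing another candidate."""
    cls = np.asarray(classes)
    n = len(cls)
    below_median = (cls >= 0) & (cls <= 2)
    lo_limit, hi_limit = 0, n
    for c in others or []:
        if c.end <= onset:
            lo_limit = max(lo_limit, c.end)
        if c.start >= offset:
            hi_limit = min(hi_limit, c.start)
    b_on, b_off = onset, offset
    while b_on - 1 >= lo_limit and below_median[b_on - 1]:
        b_on -= 1
    while b_off < hi_limit and below_median[b_off]:
        b_off += 1
    return b_on, b_off


def detect_day(
    classes: np.ndarray,
    presses: list[int] | None = None,
    day_index: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> SleepEpisode:
    """Run the full per-day chain from activity classes to a SleepEpisode."""
    presses = presses or []
    scores = sleep_scores(classes)
    cands = provisional_sweep(
        scores,
        wide=config.wide_window_min,
        narrow=config.narrow_window_min,
        seed_threshold=config.seed_score_threshold,
        edge_threshold=config.edge_score_threshold,
    )
    cands = cleanup_join(
        cands,
        scores,
        cleanup_window=config.cleanup_window_min,
        cleanup_fraction=config.cleanup_fraction,
        join_gap=config.join_gap_min,
    )
    major, naps = select_major(cands, min_duration=config.min_major_min)
    if major is None:
        return SleepEpisode(day_index, None, None, no_sleep=True, naps=naps)
    onset, offset = expand_with_buttons(
        major, classes, presses, button_avail=config.button_avail_min
    )
    b_on, b_off = expand_bedrest(onset, offset, classes, naps)
    missing = np.asarray(classes)[onset:offset] == MISSING_CLASS
    low_conf = missing.mean() > config.low_confidence_offwrist if offset > onset else False
    return SleepEpisode(
        day_index,
        onset,
        offset,
        bedrest_onset=b_on,
        bedrest_offset=b_off,
        low_confidence=bool(low_conf),
        naps=naps,
    )


__all__ = [
    "SCORE_BY_CLASS",
    "CandidateEpisode",
    "SleepEpisode",
    "sleep_scores",
    "provisional_sweep",
    "cleanup_join",
    "select_major",
    "expand_with_buttons",
    "expand_bedrest",
    "detect_day",
]
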