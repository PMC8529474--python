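"""Synthetic multi-day actigraphy with known ground truth.

Generates raw triaxial recordings that emulate the features the pipeline
keys on: high-variance wake activity, a nightly low-variance sleep episode
with brief arousals, occasional naps, near-zero-variance non-wear
segments, a light channel that is dark during sleep, button presses near
the true onset/offset with configurable compliance and jitter, and
smartphone lock/unlock sessions confined to wakefulness.

The noise model is deliberately minimal: each sample is a constant gravity
projection plus independent zero-mean Gaussian noise whose SD is set by
the minute's behavioural state. The pipeline only consumes within-minute
variance and spectral power, so controlled-SD Gaussian noise is the
smallest stimulus that exercises every downstream stage; see
docs/methods.md for what this does and does not emulate.

Schedules are expressed on the 6 PM -> 6 PM analysis-day grid: minute 0 of
a day is 18:00 on the previous civil day, so a typical night
(23:30-07:30) is the interval [330, 810).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import DAY_MINUTES, RawActigraphy

#: behavioural state codes on the per-minute ground-truth grid
WAKE, SLEEP, AROUSAL, NAP, NONWEAR = 0, 1, 2, 3, 4

DEFAULT_START = "2023-03-06 18:00:00-05:00"


@dataclass(frozen=True)
class SimProfile:
    """Signal-level generator settings.

    SDs are per-axis Gaussian noise levels in g. The defaults keep sleep
    fluctuation (0.03 g) well above the 0.0185 g wrist-off threshold and
    wake (0.05 g) clearly above sleep, the ordering the detection chain
    relies on: nonwear < sleep < wake.
    """

    sampling_rate_hz: float = 10.0
    wake_sd_g: float = 0.05
    sleep_sd_g: float = 0.03
    nonwear_sd_g: float = 0.002
    arousal_sd_g: float = 0.05
    gravity_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    button_compliance: float = 0.85
    button_jitter_min: float = 20.0
    light_wake_lux: tuple[float, float] = (50.0, 300.0)
    light_sleep_lux: float = 0.1
    light_violation_rate: float = 0.0
    temp_wear_c: float = 32.0
    temp_offwrist_c: float = 26.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.nonwear_sd_g < self.sleep_sd_g < self.wake_sd_g):
            raise ValueError("profile requires nonwear_sd_g < sleep_sd_g < wake_sd_g")
        g = np.asarray(self.gravity_orientation, dtype=float)
        if abs(np.linalg.norm(g) - 1.0) > 1e-6:
            raise ValueError("gravity_orientation must be a unit vector")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")


@dataclass
class DaySchedule:
    """Ground-truth behaviour of one analysis day (slot units, 0 = 18:00)."""

    sleep_onset: int
    sleep_offset: int
    naps: list[tuple[int, int]] = field(default_factory=list)
    nonwear: list[tuple[int, int]] = field(default_factory=list)
    arousals: list[tuple[int, int]] = field(default_factory=list)
    timezone_offset_minutes: int = 0

    @property
    def sleep(self) -> tuple[int, int]:
        return (self.sleep_onset, self.sleep_offset)


@dataclass
class GroundTruthSchedule:
    """Per-day schedules for a whole study."""

    days: list[DaySchedule]

    def __post_init__(self) -> None:
        for d, day in enumerate(self.days):
            intervals = [day.sleep, *day.naps, *day.nonwear]
            for a, b in intervals:
                if not (0 <= a < b <= DAY_MINUTES):
                    raise ValueError(f"day {d}: interval ({a}, {b}) outside the day span")
            for a, b in day.arousals:
                if not (day.sleep_onset <= a < b <= day.sleep_offset):
                    raise ValueError(f"day {d}: arousal ({a}, {b}) outside the sleep interval")
            ordered = sorted(intervals)
            for (a0, b0), (a1, b1) in zip(ordered, ordered[1:]):
                if a1 < b0:
                    raise ValueError(
                        f"day {d}: overlapping intervals ({a0}, {b0}) and ({a1}, {b1})"
                    )
            if day.sleep_offset - day.sleep_onset < 100:
                raise ValueError(f"day {d}: sleep interval shorter than 100 minutes")

    @property
    def n_days(self) -> int:
        return len(self.days)

    def state_matrix(self) -> np.ndarray:
        """(n_days, 1440) matrix of behavioural state codes."""
        states = np.full((self.n_days, DAY_MINUTES), WAKE, dtype=np.int8)
        for d, day in enumerate(self.days):
            states[d, day.sleep_onset : day.sleep_offset] = SLEEP
            for a, b in day.arousals:
                states[d, a:b] = AROUSAL
            for a, b in day.naps:
                states[d, a:b] = NAP
            for a, b in day.nonwear:
                states[d, a:b] = NONWEAR
        return states

    def sleep_masks(self) -> np.ndarray:
        st = self.state_matrix()
        return (st == SLEEP) | (st == AROUSAL)


def regular_schedule(
    n_days: int,
    seed: int = 0,
    onset_slot: int = 330,
    duration_min: int = 480,
    onset_jitter_sd: float = 20.0,
    duration_jitter_sd: float = 25.0,
    arousals_per_night: int = 2,
    nap_every: int | None = 3,
    nap_slot: int = 1200,
    nap_duration: tuple[int, int] = (45, 70),
    nonwear_every: int | None = 5,
    nonwear_slot: int = 900,
    nonwear_duration: tuple[int, int] = (240, 360),
) -> GroundTruthSchedule:
    """A realistic regular sleeper: ~23:30 onset, ~8 h nights with brief
    arousals, an afternoon nap every ``nap_every`` days, and a daytime
    non-wear block of 4-6 h every ``nonwear_every`` days.

    Default interval placements (night ~[330, 810), non-wear from ~09:00,
    nap from 14:00) keep all intervals disjoint by construction.
    """
    rng = np.random.default_rng(seed)
    days = []
    for d in range(n_days):
        onset = int(np.clip(round(onset_slot + rng.normal(0, onset_jitter_sd)), 60, 600))
        dur = int(np.clip(round(duration_min + rng.normal(0, duration_jitter_sd)), 300, 660))
        offset = min(onset + dur, nonwear_slot - 30)
        arousals = []
        for _ in range(arousals_per_night):
            length = int(rng.integers(3, 11))
            start = int(rng.integers(onset + 30, offset - 30 - length))
            arousals.append((start, start + length))
        # keep arousals disjoint; drop colliders rather than re-draw
        arousals.sort()
        kept: list[tuple[int, int]] = []
        for a, b in arousals:
            if not kept or a >= kept[-1][1] + 2:
                kept.append((a, b))
        nonwear = []
        if nonwear_every and d % nonwear_every == nonwear_every - 2:
            length = int(rng.integers(*nonwear_duration))
            nonwear.append((nonwear_slot, min(nonwear_slot + length, nap_slot - 30)))
        naps = []
        # skip the nap on non-wear days so intervals stay disjoint
        if nap_every and d % nap_every == nap_every - 1 and not nonwear:
            length = int(rng.integers(*nap_duration))
            naps.append((nap_slot, nap_slot + length))
        days.append(
            DaySchedule(
                sleep_onset=onset,
                sleep_offset=offset,
                naps=naps,
                nonwear=nonwear,
                arousals=kept,
            )
        )
    return GroundTruthSchedule(days)


_STATE_SD_FIELDS = {
    WAKE: "wake_sd_g",
    SLEEP: "sleep_sd_g",
    AROUSAL: "arousal_sd_g",
    NAP: "sleep_sd_g",
    NONWEAR: "nonwear_sd_g",
}


def simulate_study(
    schedule: GroundTruthSchedule,
    profile: SimProfile = SimProfile(),
    start_time: str | pd.Timestamp = DEFAULT_START,
) -> RawActigraphy:
    """Generate a raw recording realizing a ground-truth schedule.

    Each sample is the gravity projection on the axis plus zero-mean
    Gaussian noise with the behavioural state's SD (exactly the gravity
    vector when ``nonwear_sd_g`` is 0). The light channel is bright during
    wake/non-wear and dark (<= 1 lux) during sleep and naps, except for
    ``light_violation_rate`` of sleep minutes. Button presses are emitted
    near the true sleep onset and offset with the profile's compliance
    probability and uniform jitter. Identical (schedule, profile) inputs
    reproduce bit-identical recordings.
    """
    start = pd.Timestamp(start_time)
    rng = np.random.default_rng(profile.seed)
    states = schedule.state_matrix().ravel()
    n_min = len(states)
    spm = int(round(profile.sampling_rate_hz * 60))

    sd_by_state = np.array([getattr(profile, _STATE_SD_FIELDS[s]) for s in range(5)])
    minute_sd = sd_by_state[states]
    sample_sd = np.repeat(minute_sd, spm)
    n = n_min * spm

    gravity = np.asarray(profile.gravity_orientation, dtype=np.float64)
    axes = []
    for i in range(3):
        noise = rng.standard_normal(n)
        axes.append((gravity[i] + sample_sd * noise).astype(np.float32))

    asleep = (states == SLEEP) | (states == AROUSAL) | (states == NAP)
    lo, hi = profile.light_wake_lux
    light_min = rng.uniform(lo, hi, n_min)
    light_min[asleep] = profile.light_sleep_lux
    if profile.light_violation_rate > 0:
        viol = asleep & (rng.random(n_min) < profile.light_violation_rate)
        light_min[viol] = rng.uniform(2.0, 50.0, int(viol.sum()))
    light = np.repeat(light_min, spm).astype(np.float32)

    temp_min = np.where(
        states == NONWEAR, profile.temp_offwrist_c, profile.temp_wear_c
    ) + rng.normal(0, 0.3, n_min)
    temp = np.repeat(temp_min, spm).astype(np.float32)

    presses: list[pd.Timestamp] = []
    j = profile.button_jitter_min
    for d, day in enumerate(schedule.days):
        for anchor in (day.sleep_onset, day.sleep_offset):
            if rng.random() < profile.button_compliance:
                slot = d * DAY_MINUTES + anchor + rng.uniform(-j, j)
                slot = float(np.clip(slot, 0, n_min - 1))
                presses.append(start + pd.Timedelta(minutes=slot))

    return RawActigraphy(
        start_time=start,
        sampling_rate_hz=profile.sampling_rate_hz,
        x=axes[0],
        y=axes[1],
        z=axes[2],
        light=light,
        temp=temp,
        button_presses=sorted(presses),
    )


def simulate_phone_events(
    schedule: GroundTruthSchedule,
    seed: int = 0,
    start_time: str | pd.Timestamp = DEFAULT_START,
    sessions_per_day: int = 25,
    mean_session_min: float = 4.0,
    violation_rate: float = 0.0,
) -> tuple[pd.DataFrame, list[pd.Timestamp]]:
    """Smartphone lock/unlock sessions confined to true wakefulness.

    Returns the ordered event log and the list of deliberately planted
    nighttime-use violations (empty at the default rate 0, so that no
    event falls inside any true sleep or nap interval).
    """
    start = pd.Timestamp(start_time)
    rng = np.random.default_rng(seed)
    states = schedule.state_matrix()
    events: list[tuple[pd.Timestamp, str]] = []
    violations: list[pd.Timestamp] = []
    for d in range(schedule.n_days):
        wake_slots = np.nonzero(states[d] == WAKE)[0]
        if len(wake_slots) == 0:
            continue
        for _ in range(sessions_per_day):
            s0 = int(rng.choice(wake_slots))
            length = max(1.0, rng.exponential(mean_session_min))
            # clip the session to the contiguous wake run it starts in
            end_slot = s0
            while (
                end_slot + 1 < DAY_MINUTES
                and states[d, end_slot + 1] == WAKE
                and end_slot + 1 - s0 < length
            ):
                end_slot += 1
            t0 = start + pd.Timedelta(minutes=d * DAY_MINUTES + s0 + rng.uniform(0, 0.5))
            t1 = t0 + pd.Timedelta(minutes=min(length, end_slot + 1 - s0) * rng.uniform(0.8, 1.0))
            events.append((t0, "unlocked"))
            events.append((t1, "locked"))
        if violation_rate > 0 and rng.random() < violation_rate:
            day = schedule.days[d]
            mid = (day.sleep_onset + day.sleep_offset) // 2
            t0 = start + pd.Timedelta(minutes=d * DAY_MINUTES + mid)
            events.append((t0, "unlocked"))
            events.append((t0 + pd.Timedelta(minutes=2), "locked"))
            violations.append(t0)
    events.sort(key=lambda e: e[0])
    log = pd.DataFrame(events, columns=["timestamp", "event"])
    return log, violations


def simulate_phone_accel(
    schedule: GroundTruthSchedule,
    seed: int = 0,
    start_time: str | pd.Timestamp = DEFAULT_START,
    rate_hz: float = 1.0,
    use_sd_g: float = 0.1,
    idle_sd_g: float = 0.005,
) -> pd.DataFrame:
    """Duty-cycled (10 s on / 10 s off) phone x-axis acceleration with
    high-variance bursts only during true wakefulness."""
    start = pd.Timestamp(start_time)
    rng = np.random.default_rng(seed)
    states = schedule.state_matrix().ravel()
    rows_t = []
    rows_x = []
    per_cycle = int(round(rate_hz * 10))
    for m, st in enumerate(states):
        sd = use_sd_g if st == WAKE and rng.random() < 0.3 else idle_sd_g
        for cyc in (0, 20, 40):  # three 10-s on-cycles per minute
            t0 = m * 60.0 + cyc
            rows_t.append(t0 + np.arange(per_cycle) / rate_hz)
            rows_x.append(rng.normal(0, sd, per_cycle))
    t = np.concatenate(rows_t)
    x = np.concatenate(rows_x)
    ts = start + pd.to_timedelta(t, unit="s")
    return pd.DataFrame({"timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f%z"), "x_g": x})


def write_annotations(schedule: GroundTruthSchedule, path: str | Path) -> None:
    """Ground-truth interval annotations as CSV (round-trippable)."""
    rows = []
    for d, day in enumerate(schedule.days):
        rows.append((d, "sleep", day.sleep_onset, day.sleep_offset, day.timezone_offset_minutes))
        for a, b in day.naps:
            rows.append((d, "nap", a, b, day.timezone_offset_minutes))
        for a, b in day.nonwear:
            rows.append((d, "nonwear", a, b, day.timezone_offset_minutes))
        for a, b in day.arousals:
            rows.append((d, "arousal", a, b, day.timezone_offset_minutes))
    pd.DataFrame(
        rows, columns=["day_index", "kind", "start_min", "end_min", "tz_offset_min"]
    ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> GroundTruthSchedule:
    df = pd.read_csv(path)
    days = []
    for d in sorted(df["day_index"].unique()):
        sub = df[df["day_index"] == d]
        sleep = sub[sub["kind"] == "sleep"].iloc[0]

        def _list(kind: str) -> list[tuple[int, int]]:
            rows = sub[sub["kind"] == kind]
            return [(int(r["start_min"]), int(r["end_min"])) for _, r in rows.iterrows()]

        days.append(
            DaySchedule(
                sleep_onset=int(sleep["start_min"]),
                sleep_offset=int(sleep["end_min"]),
                naps=_list("nap"),
                nonwear=_list("nonwear"),
                arousals=_list("arousal"),
                timezone_offset_minutes=int(sleep["tz_offset_min"]),
            )
        )
    return GroundTruthSchedule(days)


__all__ = [
    "WAKE",
    "SLEEP",
    "AROUSAL",
    "NAP",
    "NONWEAR",
    "DEFAULT_START",
    "SimProfile",
    "DaySchedule",
    "GroundTruthSchedule",
    "regular_schedule",
    "simulate_study",
    "simulate_phone_events",
    "simulate_phone_accel",
    "write_annotations",
    "read_annotations",
]
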