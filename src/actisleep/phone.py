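"""Smartphone ancillary data: use intervals, event minutes, acceleration.

Phone lock/unlock event logs provide independent evidence of wakefulness.
A phone is taken to be *in use* between a consecutive unlocked -> locked
pair lasting no more than 15 minutes (longer pairs contribute only their
event minutes, softening the assumption that an unlocked phone is in use
the whole time). Per-minute masks of any phone event feed the PhoneMinutes
and PhoneBouts metrics and validation overlays. Duty-cycled phone
accelerometer samples are scored by per-minute SD of the x-axis against
within-individual 75th/90th percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import DAY_MINUTES

LOCKED = "locked"
UNLOCKED = "unlocked"


@dataclass
class PhoneUseInterval:
    """Half-open in-use interval [start, end) in clock time."""

    start: pd.Timestamp
    end: pd.Timestamp


def parse_phone_events(path: str | Path) -> pd.DataFrame:
    """Read a phone event CSV (columns timestamp, event) into an ordered
    event log."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    bad = ~df["event"].isin([LOCKED, UNLOCKED])
    if bad.any():
        raise ValueError(f"unknown phone events: {sorted(df.loc[bad, 'event'].unique())}")
    if not df["timestamp"].is_monotonic_increasing:
        raise ValueError("phone event timestamps must be nondecreasing")
    return df.reset_index(drop=True)


def phone_use_intervals(
    log: pd.DataFrame, cap_minutes: float = 15.0
) -> list[PhoneUseInterval]:
    """In-use intervals from consecutive unlocked -> locked pairs lasting
    no more than ``cap_minutes``.

    Longer pairs yield no interval (their event minutes still flag via
    :func:`phone_event_minutes`). Unmatched events are skipped with a
    warning; an unlock never followed by a lock contributes only its event
    minute.
    """
    intervals: list[PhoneUseInterval] = []
    open_unlock: pd.Timestamp | None = None
    unmatched = 0
    for ts, kind in zip(log["timestamp"], log["event"]):
        if kind == UNLOCKED:
            if open_unlock is not None:
                unmatched += 1
            open_unlock = ts
        else:
            if open_unlock is None:
                unmatched += 1
                continue
            if (ts - open_unlock).total_seconds() <= cap_minutes * 60.0 and ts > open_unlock:
                intervals.append(PhoneUseInterval(open_unlock, ts))
            open_unlock = None
    if unmatched:
        warnings.warn(f"skipped {unmatched} unmatched phone events", stacklevel=2)
    return intervals


def phone_event_minutes(
    log: pd.DataFrame,
    intervals: list[PhoneUseInterval],
    window_start: pd.Timestamp,
    n_slots: int = DAY_MINUTES,
) -> pd.DataFrame:
    """Per-slot phone flags for one analysis window.

    A slot is ``event_present`` when any event timestamp falls in it or an
    in-use interval intersects it; ``locked``/``unlocked``/``in_use`` mark
    the contributing sources. Intervals crossing the window boundary are
    clipped to it.
    """
    flags = {
        "event_present": np.zeros(n_slots, dtype=bool),
        "locked": np.zeros(n_slots, dtype=bool),
        "unlocked": np.zeros(n_slots, dtype=bool),
        "in_use": np.zeros(n_slots, dtype=bool),
    }
    for ts, kind in zip(log["timestamp"], log["event"]):
        slot = int((ts - window_start).total_seconds() // 60)
        if 0 <= slot < n_slots:
            flags[kind][slot] = True
            flags["event_present"][slot] = True
    for iv in intervals:
        first = int(np.floor((iv.start - window_start).total_seconds() / 60.0))
        last = int(np.ceil((iv.end - window_start).total_seconds() / 60.0))
        lo = max(first, 0)
        hi = min(last, n_slots)
        if hi > lo:
            flags["in_use"][lo:hi] = True
            flags["event_present"][lo:hi] = True
    return pd.DataFrame(flags)


def phone_accel_score(
    accel: pd.DataFrame,
    percentiles: tuple[float, float] = (75.0, 90.0),
) -> pd.DataFrame:
    """Per-minute movement class from the phone's x-axis acceleration.

    The phone samples on a duty cycle, so each minute's SD uses whatever
    samples exist (minutes with fewer than 2 samples are missing). The
    study-level ``percentiles`` of the per-minute SDs (within-individual)
    split minutes into ``low`` / ``high75`` / ``high90``.
    """
    ts = pd.to_datetime(accel["timestamp"], format="ISO8601")
    x = accel["x_g"].to_numpy(dtype=np.float64)
    minute = ts.dt.floor("min")
    grouped = pd.Series(x, index=minute).groupby(level=0)
    sd = grouped.std(ddof=0)
    counts = grouped.count()
    sd[counts < 2] = np.nan

    valid = sd.dropna()
    p_lo, p_hi = (float(np.percentile(valid, p)) for p in percentiles)
    cls = pd.Series("low", index=sd.index, dtype=object)
    cls[sd > p_lo] = "high75"
    cls[sd > p_hi] = "high90"
    cls[sd.isna()] = None
    return pd.DataFrame({"sd_x": sd, "movement": cls})


__all__ = [
    "LOCKED",
    "UNLOCKED",
    "PhoneUseInterval",
    "parse_phone_events",
    "phone_use_intervals",
    "phone_event_minutes",
    "phone_accel_score",
]
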