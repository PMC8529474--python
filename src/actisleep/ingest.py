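"""Raw-recording ingestion.

Parses timestamped CSV exports of continuous triaxial wrist-accelerometer
data, verifies uniform sampling, splits recordings into civil-day segments,
merges overlapping recordings at watch changes, and assembles the
6 PM -> 6 PM analysis days on which all downstream sleep processing runs.

A recording is stored as a start timestamp plus a fixed sampling rate;
individual sample timestamps are implicit. Missing stretches (the gap
between two disjoint watches, unworn shipping days, ...) are represented as
NaN samples so the timeline stays uniform. Minute slot ``k`` of an analysis
day covers the half-open clock minute ``18:00 + k`` .. ``18:00 + k + 1`` of
the window running from 6 PM on the previous civil day to 6 PM on the day
itself.
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: minutes in one analysis day
DAY_MINUTES = 1440
#: slot 0 of an analysis day is 18:00 on the previous civil day
DAY_START_HOUR = 18

RAW_COLUMNS = ("timestamp", "x_g", "y_g", "z_g", "light_lux", "temp_c", "button")


def slot_to_clock(slot: int) -> str:
    """Clock time ``hh:mm`` of an analysis-day minute slot (0 = 18:00)."""
    total = (DAY_START_HOUR * 60 + int(slot)) % (24 * 60)
    return f"{total // 60:02d}:{total % 60:02d}"


def clock_to_slot(clock: str) -> int:
    """Inverse of :func:`slot_to_clock` (result in 0..1439)."""
    hh, mm = clock.split(":")
    return (int(hh) * 60 + int(mm) - DAY_START_HOUR * 60) % (24 * 60)


@dataclass
class RawActigraphy:
    """Uniformly sampled triaxial acceleration plus ancillary channels.

    Acceleration is in units of gravity (g). ``light`` (lux) and ``temp``
    (degrees C) are optional. ``button_presses`` are the rising-edge
    timestamps of the wristband key.
    """

    start_time: pd.Timestamp
    sampling_rate_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    light: np.ndarray | None = None
    temp: np.ndarray | None = None
    button_presses: list[pd.Timestamp] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_time.tzinfo is None:
            raise ValueError("start_time must be timezone-aware")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        n = len(self.x)
        if len(self.y) != n or len(self.z) != n:
            raise ValueError("x, y, z must have equal length")
        for name in ("light", "temp"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ValueError(f"{name} channel length differs from acceleration")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def step(self) -> pd.Timedelta:
        return pd.Timedelta(seconds=1.0 / self.sampling_rate_hz)

    @property
    def end_time(self) -> pd.Timestamp:
        """Exclusive end: timestamp just past the last sample."""
        return self.start_time + self.n_samples * self.step

    def sample_index(self, ts: pd.Timestamp) -> int:
        """Index of the sample at clock time ``ts`` (rounded to the grid)."""
        return int(round((ts - self.start_time).total_seconds() * self.sampling_rate_hz))

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_time + self.step * np.arange(self.n_samples)

    def slice(self, i0: int, i1: int, partial_presses: bool = True) -> "RawActigraphy":
        """Sub-recording covering sample indices ``[i0, i1)``."""
        i0 = max(0, i0)
        i1 = min(self.n_samples, i1)
        t0 = self.start_time + i0 * self.step
        t1 = self.start_time + i1 * self.step
        presses = [p for p in self.button_presses if t0 <= p < t1] if partial_presses else []
        return RawActigraphy(
            start_time=t0,
            sampling_rate_hz=self.sampling_rate_hz,
            x=self.x[i0:i1],
            y=self.y[i0:i1],
            z=self.z[i0:i1],
            light=None if self.light is None else self.light[i0:i1],
            temp=None if self.temp is None else self.temp[i0:i1],
            button_presses=presses,
        )


@dataclass
class DaySegment:
    """One civil day ([00:00, 24:00)) of a recording."""

    date: dt.date
    raw: RawActigraphy
    partial: bool


@dataclass
class StudyDay:
    """One 6 PM -> 6 PM analysis day.

    ``start_slot_global`` locates slot 0 of this day on the study-wide
    minute grid (may be negative when the recording starts mid-window).
    """

    day_index: int
    date: dt.date
    window_start: pd.Timestamp
    start_slot_global: int
    present: np.ndarray  # 1440 bool, sample coverage per slot
    partial: bool

    @property
    def n_present(self) -> int:
        return int(self.present.sum())


def _format_timestamps(start: pd.Timestamp, step: pd.Timedelta, n: int) -> np.ndarray:
    """Vectorised ISO-8601 strings with UTC offset for n uniform samples."""
    naive = start.tz_localize(None)
    t64 = np.datetime64(naive, "ms") + (np.arange(n) * step.total_seconds() * 1000).astype(
        "timedelta64[ms]"
    )
    body = np.datetime_as_string(t64, unit="ms")
    off = start.utcoffset()
    total = int(off.total_seconds() // 60)
    sign = "+" if total >= 0 else "-"
    suffix = f"{sign}{abs(total) // 60:02d}:{abs(total) % 60:02d}"
    return np.char.add(body, suffix)


def write_raw_csv(raw: RawActigraphy, path: str | Path) -> None:
    """Write a recording in the pipeline's raw CSV dialect."""
    n = raw.n_samples
    button = np.zeros(n, dtype=np.int8)
    for p in raw.button_presses:
        i = raw.sample_index(p)
        if 0 <= i < n:
            button[i] = 1
    df = pd.DataFrame(
        {
            "timestamp": _format_timestamps(raw.start_time, raw.step, n),
            "x_g": raw.x,
            "y_g": raw.y,
            "z_g": raw.z,
            "light_lux": raw.light if raw.light is not None else np.full(n, np.nan),
            "temp_c": raw.temp if raw.temp is not None else np.full(n, np.nan),
            "button": button,
        }
    )
    df.to_csv(path, index=False, float_format="%.5f")


def parse_raw(
    path: str | Path,
    rate_hz: float | None = None,
    tolerance_s: float = 2e-3,
    column_map: dict[str, str] | None = None,
) -> RawActigraphy:
    """Parse a raw CSV recording and verify its constant sampling rate.

    Parameters
    ----------
    rate_hz:
        Declared sampling rate; inferred from the median timestamp step
        when omitted.
    tolerance_s:
        Maximum tolerated deviation of any timestamp step from the nominal
        step. The first larger gap raises with its position.
    column_map:
        Optional mapping from the dialect's column names to the names used
        in the file, for device exports with different headers.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    unknown = [c for c in df.columns if c not in RAW_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns {unknown}", stacklevel=2)
    for col in ("timestamp", "x_g", "y_g", "z_g"):
        if col not in df.columns:
            raise ValueError(f"raw CSV is missing required column {col!r}")

    ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    if ts.dt.tz is None:
        raise ValueError("timestamps must carry a UTC offset")
    if len(ts) < 2:
        raise ValueError("recording too short to verify the sampling rate")

    steps = ts.diff().dt.total_seconds().to_numpy()[1:]
    nominal = 1.0 / rate_hz if rate_hz else float(np.median(steps))
    bad = np.nonzero(np.abs(steps - nominal) > tolerance_s)[0]
    if bad.size:
        i = int(bad[0]) + 1
        raise ValueError(
            f"non-uniform sampling: {steps[i - 1]:.3f} s gap before row {i} "
            f"({ts.iloc[i].isoformat()}), expected {nominal:.3f} s"
        )

    rate = 1.0 / nominal
    button_presses: list[pd.Timestamp] = []
    if "button" in df.columns:
        b = df["button"].to_numpy()
        b = np.nan_to_num(b).astype(np.int8)
        rising = np.nonzero((b[1:] == 1) & (b[:-1] == 0))[0] + 1
        if b[0] == 1:
            rising = np.concatenate([[0], rising])
        button_presses = [ts.iloc[int(i)] for i in rising]

    def _opt(col: str) -> np.ndarray | None:
        if col not in df.columns:
            return None
        arr = df[col].to_numpy(dtype=np.float32)
        return None if np.isnan(arr).all() else arr

    return RawActigraphy(
        start_time=ts.iloc[0],
        sampling_rate_hz=rate,
        x=df["x_g"].to_numpy(dtype=np.float32),
        y=df["y_g"].to_numpy(dtype=np.float32),
        z=df["z_g"].to_numpy(dtype=np.float32),
        light=_opt("light_lux"),
        temp=_opt("temp_c"),
        button_presses=button_presses,
    )


def split_daily(raw: RawActigraphy) -> list[DaySegment]:
    """Split a recording into per-civil-day segments (midnight to midnight).

    Partial first/last days are retained and flagged. Every sample of the
    input lands in exactly one segment.
    """
    if raw.n_samples == 0:
        return []
    segments: list[DaySegment] = []
    date = raw.start_time.date()
    while True:
        d0 = pd.Timestamp(dt.datetime.combine(date, dt.time(0)), tz=raw.start_time.tzinfo)
        d1 = d0 + pd.Timedelta(days=1)
        if d0 >= raw.end_time:
            break
        i0 = max(0, raw.sample_index(d0))
        i1 = min(raw.n_samples, raw.sample_index(d1))
        if i1 > i0:
            seg = raw.slice(i0, i1)
            partial = seg.start_time > d0 or seg.end_time < d1
            segments.append(DaySegment(date=date, raw=seg, partial=partial))
        date += dt.timedelta(days=1)
    return segments


def concat_segments(segments: list[DaySegment]) -> RawActigraphy:
    """Re-concatenate contiguous daily segments into one recording."""
    if not segments:
        raise ValueError("no segments to concatenate")
    raws = [s.raw for s in segments]
    for a, b in zip(raws, raws[1:]):
        if abs((b.start_time - a.end_time).total_seconds()) > 0.5 / a.sampling_rate_hz:
            raise ValueError(f"segments are not contiguous at {a.end_time}")
    presses = [p for r in raws for p in r.button_presses]

    def _cat(name: str) -> np.ndarray | None:
        parts = [getattr(r, name) for r in raws]
        if any(p is None for p in parts):
            return None
        return np.concatenate(parts)

    return RawActigraphy(
        start_time=raws[0].start_time,
        sampling_rate_hz=raws[0].sampling_rate_hz,
        x=np.concatenate([r.x for r in raws]),
        y=np.concatenate([r.y for r in raws]),
        z=np.concatenate([r.z for r in raws]),
        light=_cat("light"),
        temp=_cat("temp"),
        button_presses=presses,
    )


def merge_watch_change(old: RawActigraphy, new: RawActigraphy) -> RawActigraphy:
    """Merge two recordings around a watch change.

    Wherever both watches have samples at the same clock times, the new
    watch's samples win (the old watch keeps recording non-wrist data until
    it is docked). Disjoint recordings are concatenated with the gap marked
    missing (NaN samples).
    """
    if abs(old.sampling_rate_hz - new.sampling_rate_hz) > 1e-9:
        raise ValueError(
            f"sampling rates differ ({old.sampling_rate_hz} vs {new.sampling_rate_hz} Hz); "
            "resampling is out of scope"
        )
    step = old.step
    start = min(old.start_time, new.start_time)
    end = max(old.end_time, new.end_time)
    n = int(round((end - start).total_seconds() * old.sampling_rate_hz))

    has_light = old.light is not None and new.light is not None
    has_temp = old.temp is not None and new.temp is not None

    def _alloc() -> np.ndarray:
        return np.full(n, np.nan, dtype=np.float32)

    channels = {"x": _alloc(), "y": _alloc(), "z": _alloc()}
    if has_light:
        channels["light"] = _alloc()
    if has_temp:
        channels["temp"] = _alloc()

    for rec in (old, new):  # old first so new overwrites
        o = int(round((rec.start_time - start).total_seconds() * rec.sampling_rate_hz))
        for name, dest in channels.items():
            src = getattr(rec, name)
            if src is not None:
                # NaN samples inside a recording never overwrite real data
                valid = ~np.isnan(src)
                dest[o : o + rec.n_samples][valid] = src[valid]

    presses = sorted(set(old.button_presses) | set(new.button_presses))
    return RawActigraphy(
        start_time=start,
        sampling_rate_hz=old.sampling_rate_hz,
        x=channels["x"],
        y=channels["y"],
        z=channels["z"],
        light=channels.get("light"),
        temp=channels.get("temp"),
        button_presses=presses,
    )


def _minute_sample_counts(raw: RawActigraphy) -> tuple[pd.Timestamp, np.ndarray]:
    """Number of non-NaN samples per wall-clock minute.

    Returns the grid origin (start floored to the minute) and the counts.
    """
    origin = raw.start_time.floor("min")
    offset_s = (raw.start_time - origin).total_seconds()
    n = raw.n_samples
    total_minutes = int(np.ceil((offset_s + n / raw.sampling_rate_hz) / 60.0 - 1e-9))
    counts = np.zeros(max(total_minutes, 1), dtype=np.int64)
    chunk = 4_000_000
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        idx = ((offset_s + np.arange(lo, hi) / raw.sampling_rate_hz) / 60.0).astype(np.int64)
        valid = ~np.isnan(raw.x[lo:hi])
        counts += np.bincount(idx[valid], minlength=len(counts))
    return origin, counts


def assemble_analysis_days(
    segments: list[DaySegment],
    consent_date: dt.date,
    present_fraction: float = 0.8,
    minute_counts: tuple[pd.Timestamp, np.ndarray] | None = None,
) -> list[StudyDay]:
    """Assemble 6 PM -> 6 PM analysis days from civil-day segments.

    Each analysis day stitches the 18:00-24:00 span of civil day ``d - 1``
    with the 00:00-18:00 span of day ``d``. Minute slots with fewer than
    ``present_fraction`` of their expected samples are marked missing.
    ``day_index`` counts days since ``consent_date``.
    """
    if not segments:
        return []
    raw = concat_segments(segments) if len(segments) > 1 else segments[0].raw
    if minute_counts is None:
        minute_counts = _minute_sample_counts(raw)
    origin, counts = minute_counts
    spm = raw.sampling_rate_hz * 60.0
    need = int(np.ceil(present_fraction * spm))
    present_all = counts >= need

    days: list[StudyDay] = []
    first_date = segments[0].date
    # the first window that can overlap the recording ends at 18:00 of
    # first_date unless the recording begins at/after 18:00
    if raw.start_time.hour >= DAY_START_HOUR:
        first_date = first_date + dt.timedelta(days=1)
    date = first_date
    while True:
        ws = pd.Timestamp(
            dt.datetime.combine(date - dt.timedelta(days=1), dt.time(DAY_START_HOUR)),
            tz=raw.start_time.tzinfo,
        )
        if ws >= raw.end_time:
            break
        g0 = int(round((ws - origin).total_seconds() / 60.0))
        present = np.zeros(DAY_MINUTES, dtype=bool)
        lo = max(0, -g0)
        hi = min(DAY_MINUTES, len(present_all) - g0)
        if hi > lo:
            present[lo:hi] = present_all[g0 + lo : g0 + hi]
        covered = (ws >= raw.start_time) and (ws + pd.Timedelta(minutes=DAY_MINUTES) <= raw.end_time)
        days.append(
            StudyDay(
                day_index=(date - consent_date).days,
                date=date,
                window_start=ws,
                start_slot_global=g0,
                present=present,
                partial=not covered,
            )
        )
        date += dt.timedelta(days=1)
    return days


def write_day_slots(
    days: list[StudyDay], minutes: pd.DataFrame, out_dir: str | Path
) -> None:
    """Write per-day CSVs of minute slots plus a JSON sidecar.

    ``minutes`` is the study-wide minute frame (one row per grid minute).
    Each day file carries 1440 rows indexed by slot; slots outside the
    recording are empty. The sidecar maps day files to day_index and flags
    partial days.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {}
    n = len(minutes)
    for day in days:
        rows = []
        for slot in range(DAY_MINUTES):
            g = day.start_slot_global + slot
            if 0 <= g < n:
                rows.append(minutes.iloc[g])
            else:
                rows.append(pd.Series(np.nan, index=minutes.columns))
        df = pd.DataFrame(rows).reset_index(drop=True)
        df.insert(0, "slot", np.arange(DAY_MINUTES))
        df.insert(1, "clock", [slot_to_clock(s) for s in range(DAY_MINUTES)])
        name = f"day_{day.day_index:04d}.csv"
        df.to_csv(out / name, index=False)
        sidecar[name] = {
            "day_index": day.day_index,
            "date": day.date.isoformat(),
            "partial": day.partial,
            "missing_slots": int((~day.present).sum()),
        }
    (out / "days.json").write_text(json.dumps(sidecar, indent=2))


__all__ = [
    "DAY_MINUTES",
    "DAY_START_HOUR",
    "RawActigraphy",
    "DaySegment",
    "StudyDay",
    "slot_to_clock",
    "clock_to_slot",
    "write_raw_csv",
    "parse_raw",
    "split_daily",
    "concat_segments",
    "merge_watch_change",
    "assemble_analysis_days",
    "write_day_slots",
]
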