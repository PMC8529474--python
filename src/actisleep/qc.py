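"""Quality control: time-zone/DST correction, manual adjustment records,
per-day report data, and the two study-level visualizations.

The watch records clock-agnostic continuous data, so travel across time
zones and standard/daylight-saving transitions shift the apparent sleep
band. Correction is a pure relabeling of clock times per day from a
supplied itinerary; travel days and DST transition nights carry too much
uncertainty and are marked missing instead. Automatic episode estimates
can be revised by raters through adjustment records that preserve the auto
values in provenance and can be reverted exactly.
"""

from __future__ import annotations

import bisect
import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap

from .activity import MISSING_CLASS
from .episodes import SleepEpisode
from .ingest import DAY_MINUTES, clock_to_slot, slot_to_clock

#: activity band colors A0..A4 (blue, cyan, green, orange, red); gray = missing
CLASS_COLORS = ("#2166ac", "#00e5ee", "#2ca02c", "#ff7f0e", "#d62728")
MISSING_COLOR = "#bdbdbd"

ADJUSTABLE_FIELDS = ("SleepOnset", "SleepOffset", "BedrestOnset", "BedrestOffset", "no_sleep")


@dataclass
class TimezoneItinerary:
    """UTC offsets over the study span plus travel and DST dates.

    ``entries`` are (date, utc_offset_minutes) pairs, each applying from
    its date until the next entry. The offset of the first entry is the
    study's reference zone; days in other zones have their clock labels
    shifted by the offset difference.
    """

    entries: list[tuple[dt.date, int]] = field(default_factory=list)
    dst_transition_dates: list[dt.date] = field(default_factory=list)
    travel_dates: list[dt.date] = field(default_factory=list)

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.entries]
        if dates != sorted(dates):
            raise ValueError("itinerary entry dates must be nondecreasing")

    def offset_on(self, date: dt.date) -> int:
        if not self.entries:
            return 0
        dates = [d for d, _ in self.entries]
        i = bisect.bisect_right(dates, date) - 1
        if i < 0:
            raise ValueError(f"itinerary does not cover {date} (starts {dates[0]})")
        return self.entries[i][1]

    def shift_on(self, date: dt.date) -> int:
        """Clock shift in minutes relative to the reference zone."""
        if not self.entries:
            return 0
        return self.offset_on(date) - self.entries[0][1]

    def is_missing(self, date: dt.date) -> bool:
        return date in self.travel_dates or date in self.dst_transition_dates


def episodes_table(episodes: list[SleepEpisode], dates: list[dt.date] | None = None) -> pd.DataFrame:
    """Flatten SleepEpisodes into the output table (slot + hh:mm fields)."""
    rows = []
    for i, e in enumerate(episodes):
        rows.append(
            {
                "day_index": e.day_index,
                "date": dates[i] if dates else None,
                "SleepOnset": e.clock("sleep_onset"),
                "SleepOffset": e.clock("sleep_offset"),
                "BedrestOnset": e.clock("bedrest_onset"),
                "BedrestOffset": e.clock("bedrest_offset"),
                "onset_slot": e.sleep_onset,
                "offset_slot": e.sleep_offset,
                "bedrest_onset_slot": e.bedrest_onset,
                "bedrest_offset_slot": e.bedrest_offset,
                "no_sleep": e.no_sleep,
                "missing": False,
                "low_confidence": e.low_confidence,
                "provenance": e.provenance,
                "n_naps": len(e.naps),
            }
        )
    return pd.DataFrame(rows).set_index("day_index")


def apply_timezone(episodes: pd.DataFrame, itinerary: TimezoneItinerary) -> pd.DataFrame:
    """Shift per-day clock labels to the local zone and mark travel days
    and DST transition nights missing.

    Durations of retained days are untouched (the correction is a pure
    relabeling); an empty itinerary changes nothing. Requires a ``date``
    column on the episode table.
    """
    out = episodes.copy()
    if not itinerary.entries and not itinerary.travel_dates and not itinerary.dst_transition_dates:
        return out
    if out["date"].isna().any():
        raise ValueError("episode table needs dates to apply an itinerary")
    for idx, row in out.iterrows():
        date = row["date"]
        if isinstance(date, pd.Timestamp):
            date = date.date()
        if itinerary.is_missing(date):
            out.loc[idx, "missing"] = True
            continue
        shift = itinerary.shift_on(date)
        if shift == 0:
            continue
        for slot_col, clock_col in (
            ("onset_slot", "SleepOnset"),
            ("offset_slot", "SleepOffset"),
            ("bedrest_onset_slot", "BedrestOnset"),
            ("bedrest_offset_slot", "BedrestOffset"),
        ):
            slot = row[slot_col]
            if pd.notna(slot):
                out.loc[idx, slot_col] = int(slot) + shift
                out.loc[idx, clock_col] = slot_to_clock(int(slot) + shift)
    return out


def shift_day_matrix(matrix: np.ndarray, shifts: list[int]) -> np.ndarray:
    """Roll each day's 1440-slot row by its clock shift (for plotting)."""
    out = np.array(matrix)
    for i, s in enumerate(shifts):
        if s:
            out[i] = np.roll(out[i], s % DAY_MINUTES)
    return out


@dataclass
class AdjustmentRecord:
    """One manual QC edit of one field of one day."""

    day_index: int
    field: str
    old: object
    new: object
    rater: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.field not in ADJUSTABLE_FIELDS:
            raise ValueError(f"field must be one of {ADJUSTABLE_FIELDS}, got {self.field!r}")


_FIELD_TO_SLOT = {
    "SleepOnset": "onset_slot",
    "SleepOffset": "offset_slot",
    "BedrestOnset": "bedrest_onset_slot",
    "BedrestOffset": "bedrest_offset_slot",
}


def apply_adjustments(
    episodes: pd.DataFrame, records: list[AdjustmentRecord]
) -> pd.DataFrame:
    """Apply manual adjustment records to an episode table.

    Clock fields take ``hh:mm`` values (mapped onto the day's 6 PM -> 6 PM
    slot grid); ``no_sleep`` takes a boolean. Edited days get provenance
    ``adjusted`` and keep their auto values in ``auto_*`` columns, so a
    record restoring the auto value reverts the day exactly. Adjustments
    violating onset < offset are rejected; a bedrest bound left outside
    the new sleep bounds only warns, since raters edit one bound at a time.
    """
    out = episodes.copy()
    for col in _FIELD_TO_SLOT.values():
        auto_col = f"auto_{col}"
        if auto_col not in out.columns:
            out[auto_col] = out[col]
    if "auto_no_sleep" not in out.columns:
        out["auto_no_sleep"] = out["no_sleep"]

    for rec in records:
        if rec.day_index not in out.index:
            raise KeyError(f"adjustment references unknown day_index {rec.day_index}")
        row = out.loc[rec.day_index].copy()
        if rec.field == "no_sleep":
            row["no_sleep"] = bool(rec.new)
        else:
            slot_col = _FIELD_TO_SLOT[rec.field]
            row[slot_col] = clock_to_slot(str(rec.new))
            row[rec.field] = str(rec.new)
        on, off = row["onset_slot"], row["offset_slot"]
        b_on, b_off = row["bedrest_onset_slot"], row["bedrest_offset_slot"]
        if not row["no_sleep"]:
            if pd.notna(on) and pd.notna(off) and not on < off:
                raise ValueError(
                    f"day {rec.day_index}: adjusted {rec.field}={rec.new} violates onset < offset"
                )
            # bedrest containment can break transiently while a rater edits
            # one bound at a time; surface it without rejecting the edit
            if (pd.notna(b_on) and pd.notna(on) and b_on > on) or (
                pd.notna(b_off) and pd.notna(off) and b_off < off
            ):
                warnings.warn(
                    f"day {rec.day_index}: bedrest bounds no longer contain the "
                    "sleep bounds after this adjustment",
                    stacklevel=2,
                )
        row["provenance"] = "adjusted"
        out.loc[rec.day_index] = row

    # a day whose fields all match its auto values reverts to provenance auto
    for idx in out.index:
        row = out.loc[idx]
        if row["provenance"] != "adjusted":
            continue
        same = all(
            (pd.isna(row[c]) and pd.isna(row[f"auto_{c}"])) or row[c] == row[f"auto_{c}"]
            for c in _FIELD_TO_SLOT.values()
        ) and bool(row["no_sleep"]) == bool(row["auto_no_sleep"])
        if same:
            out.loc[idx, "provenance"] = "auto"
    return out


def adjustments_from_csv(path: str | Path) -> list[AdjustmentRecord]:
    df = pd.read_csv(path)
    return [
        AdjustmentRecord(
            day_index=int(r["day_index"]),
            field=str(r["field"]),
            old=r.get("old"),
            new=r["new"],
            rater=str(r.get("rater", "")),
            note=str(r.get("note", "")),
        )
        for _, r in df.iterrows()
    ]


def render_daily_map(
    class_matrix: np.ndarray,
    path: str | Path | None = None,
    episodes: list[SleepEpisode] | None = None,
) -> np.ndarray:
    """Lateral daily map: one column per day, 6 PM at the bottom to 6 PM
    at the top, activity bands colored blue/cyan/green/orange/red and
    missing minutes gray.

    Returns the index matrix actually drawn (values -1..4, day x slot) so
    callers can verify pixel-level content; saves a PNG/SVG when ``path``
    is given. With ``episodes`` an overlay variant marks the sleep bounds.
    """
    cm = np.asarray(class_matrix)
    if cm.ndim != 2 or cm.shape[1] != DAY_MINUTES:
        raise ValueError("class_matrix must be (n_days, 1440)")
    cmap = ListedColormap([MISSING_COLOR, *CLASS_COLORS])
    fig, ax = plt.subplots(figsize=(max(4, cm.shape[0] * 0.12), 6))
    ax.imshow(
        cm.T + 1,
        origin="lower",
        aspect="auto",
        interpolation="none",
        cmap=cmap,
        vmin=0,
        vmax=5,
        extent=(-0.5, cm.shape[0] - 0.5, 0, DAY_MINUTES),
    )
    if episodes:
        for i, e in enumerate(episodes):
            if not e.no_sleep:
                ax.plot([i, i], [e.sleep_onset, e.sleep_offset], color="k", lw=1.2)
    ax.set_xlabel("study day")
    ax.set_ylabel("minutes from 6 PM")
    ax.set_yticks([0, 360, 720, 1080, 1440])
    ax.set_yticklabels(["18:00", "00:00", "06:00", "12:00", "18:00"])
    if path is not None:
        fig.savefig(path, dpi=110)
    plt.close(fig)
    return cm.copy()


def render_actogram(
    episodes: list[SleepEpisode], path: str | Path | None = None
) -> np.ndarray:
    """48-hour double-plot actogram: row d shows days d and d+1 side by
    side, so the second half of each row repeats as the first half of the
    next. Returns the (n_days - 1, 2880) sleep matrix drawn."""
    if len(episodes) < 2:
        raise ValueError("actogram needs at least 2 days")
    masks = np.stack([e.sleep_mask() for e in episodes])
    rows = np.concatenate([masks[:-1], masks[1:]], axis=1)
    fig, ax = plt.subplots(figsize=(8, max(2, rows.shape[0] * 0.14)))
    ax.imshow(
        rows,
        origin="upper",
        aspect="auto",
        interpolation="none",
        cmap=ListedColormap(["#f5f5f5", "#08306b"]),
        extent=(0, 48, rows.shape[0] - 0.5, -0.5),
    )
    ax.set_xlabel("clock time (h, double-plotted from 6 PM)")
    ax.set_ylabel("study day")
    ax.set_xticks([0, 12, 24, 36, 48])
    if path is not None:
        fig.savefig(path, dpi=110)
    plt.close(fig)
    return rows


def daily_report(
    day_index: int,
    classes: np.ndarray,
    scores: np.ndarray,
    episode: SleepEpisode,
    adjusted: SleepEpisode | None = None,
    light: np.ndarray | None = None,
    presses: list[int] | None = None,
    phone_mask: pd.DataFrame | None = None,
) -> dict:
    """Structured per-day QC record: everything a rater needs to judge the
    estimate — classes, scores, auto and corrected bounds, light trace,
    button presses and phone masks when available."""
    rec = {
        "day_index": day_index,
        "no_sleep": episode.no_sleep,
        "low_confidence": episode.low_confidence,
        "classes": np.asarray(classes).tolist(),
        "scores": [None if np.isnan(v) else v for v in np.asarray(scores, dtype=float)],
        "auto": {
            "SleepOnset": episode.clock("sleep_onset"),
            "SleepOffset": episode.clock("sleep_offset"),
            "BedrestOnset": episode.clock("bedrest_onset"),
            "BedrestOffset": episode.clock("bedrest_offset"),
        },
        "adjusted": None
        if adjusted is None
        else {
            "SleepOnset": adjusted.clock("sleep_onset"),
            "SleepOffset": adjusted.clock("sleep_offset"),
            "BedrestOnset": adjusted.clock("bedrest_onset"),
            "BedrestOffset": adjusted.clock("bedrest_offset"),
        },
        "naps": [[c.start, c.end] for c in episode.naps],
        "button_presses": [slot_to_clock(p) for p in (presses or [])],
        "light": None if light is None else np.asarray(light, dtype=float).tolist(),
        "phone": None if phone_mask is None else phone_mask.to_dict(orient="list"),
        "missing_minutes": int(np.sum(np.asarray(classes) == MISSING_CLASS)),
    }
    return rec


__all__ = [
    "CLASS_COLORS",
    "MISSING_COLOR",
    "TimezoneItinerary",
    "AdjustmentRecord",
    "episodes_table",
    "apply_timezone",
    "shift_day_matrix",
    "apply_adjustments",
    "adjustments_from_csv",
    "render_daily_map",
    "render_actogram",
    "daily_report",
]
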