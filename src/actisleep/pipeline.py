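"""End-to-end orchestration: raw recording -> episodes, metrics, STRI.

Runs the stages in order on a study-wide minute grid (per-minute SDs,
wrist-off detection, Welch power, within-individual thresholds,
classification), then detects each 6 PM -> 6 PM day's major Sleep Episode
and derives the daily metrics and regularity series.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity, episodes as ep, metrics as mx, nonwear, phone as ph, qc
from .config import DEFAULT_CONFIG, PipelineConfig
from .ingest import DAY_MINUTES, RawActigraphy, StudyDay, assemble_analysis_days, split_daily


@dataclass
class StudyResult:
    """Everything the pipeline derives for one participant."""

    minutes: pd.DataFrame
    thresholds: activity.PercentileThresholds
    days: list[StudyDay]
    episodes: list[ep.SleepEpisode]
    episode_table: pd.DataFrame
    metrics: pd.DataFrame
    stri: pd.DataFrame
    config: PipelineConfig

    @property
    def n_days(self) -> int:
        return len(self.days)

    def day_array(self, column: str, day: StudyDay, fill: float = np.nan) -> np.ndarray:
        """A 1440-slot view of one minute-frame column for one day."""
        values = self.minutes[column].to_numpy()
        out = np.full(DAY_MINUTES, fill, dtype=np.float64)
        g0 = day.start_slot_global
        lo = max(0, -g0)
        hi = min(DAY_MINUTES, len(values) - g0)
        if hi > lo:
            out[lo:hi] = values[g0 + lo : g0 + hi]
        return out

    def class_matrix_day(self, day: StudyDay) -> np.ndarray:
        """Activity classes of one day with -1 for missing minutes."""
        arr = self.day_array("activity_class", day)
        return np.where(np.isnan(arr), activity.MISSING_CLASS, arr).astype(np.int16)

    def class_matrix(self) -> np.ndarray:
        """(n_days, 1440) activity classes with -1 for missing."""
        cls = self.minutes["activity_class"].to_numpy(dtype=np.float64)
        rows = []
        for day in self.days:
            arr = np.full(DAY_MINUTES, activity.MISSING_CLASS, dtype=np.int8)
            g0 = day.start_slot_global
            lo = max(0, -g0)
            hi = min(DAY_MINUTES, len(cls) - g0)
            if hi > lo:
                chunk = cls[g0 + lo : g0 + hi]
                arr[lo:hi] = np.where(np.isnan(chunk), activity.MISSING_CLASS, chunk).astype(
                    np.int8
                )
            rows.append(arr)
        return np.stack(rows)


def _press_slots(raw: RawActigraphy, day: StudyDay) -> list[int]:
    slots = []
    for p in raw.button_presses:
        slot = int((p - day.window_start).total_seconds() // 60)
        if 0 <= slot < DAY_MINUTES:
            slots.append(slot)
    return slots


def run_study(
    raw: RawActigraphy,
    consent_date: dt.date | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    phone_log: pd.DataFrame | None = None,
    min_valid_minutes: int | None = None,
) -> StudyResult:
    """Run the full pipeline on one participant's recording."""
    cfg = config
    floor = cfg.min_valid_minutes if min_valid_minutes is None else min_valid_minutes
    if consent_date is None:
        consent_date = raw.start_time.date()

    # --- minute grid: SDs, presence, wrist-off ---
    minutes = nonwear.minute_sd(raw, present_fraction=cfg.present_fraction)
    minutes = nonwear.wrist_off_mask(
        minutes,
        window=cfg.nonwear_window_min,
        threshold=cfg.nonwear_threshold_g,
        combine=cfg.nonwear_combine,
        square=cfg.nonwear_square,
    )
    present = minutes["present"].to_numpy()
    wrist_off = minutes["wrist_off"].to_numpy()
    valid = present & ~wrist_off

    # --- per-minute spectral power ---
    origin = raw.start_time.floor("min")
    head = int(round((raw.start_time - origin).total_seconds() * raw.sampling_rate_hz))
    n_min = len(minutes)
    powers = {}
    for axis in ("x", "y", "z"):
        powers[axis] = activity.minute_powers(
            getattr(raw, axis).astype(np.float64),
            raw.sampling_rate_hz,
            head,
            n_min,
            valid,
            segment=cfg.welch_segment,
        )
        minutes[f"power_{axis}"] = powers[axis]
    combined = activity.combine_axes(powers["x"], powers["y"], powers["z"])
    minutes["combined_power"] = combined
    smoothed = activity.smooth_power(combined, valid, window=cfg.power_smooth_min)
    minutes["smoothed_power"] = smoothed

    # --- within-individual thresholds and classes ---
    series = smoothed if cfg.classify_on == "smoothed" else combined
    thresholds = activity.percentile_thresholds(
        series[valid], p_list=cfg.percentiles, min_valid_minutes=floor
    )
    cls = activity.classify_minutes(np.where(valid, series, np.nan), thresholds)
    minutes["activity_class"] = cls
    minutes["score"] = ep.sleep_scores(cls)

    # --- analysis days and episode detection ---
    segments = split_daily(raw)
    days = assemble_analysis_days(
        segments, consent_date, present_fraction=cfg.present_fraction
    )
    episode_list: list[ep.SleepEpisode] = []
    cls_f = minutes["activity_class"].to_numpy(dtype=np.int16)
    for day in days:
        arr = np.full(DAY_MINUTES, activity.MISSING_CLASS, dtype=np.int16)
        g0 = day.start_slot_global
        lo = max(0, -g0)
        hi = min(DAY_MINUTES, n_min - g0)
        if hi > lo:
            arr[lo:hi] = cls_f[g0 + lo : g0 + hi]
        episode_list.append(
            ep.detect_day(arr, _press_slots(raw, day), day_index=day.day_index, config=cfg)
        )

    episode_table = qc.episodes_table(episode_list, dates=[d.date for d in days])

    # --- daily metrics ---
    phone_masks: dict[int, np.ndarray] = {}
    if phone_log is not None:
        intervals = ph.phone_use_intervals(phone_log, cap_minutes=cfg.phone_use_cap_min)
        for i, day in enumerate(days):
            mask = ph.phone_event_minutes(phone_log, intervals, day.window_start)
            phone_masks[i] = mask["event_present"].to_numpy()

    has_light = "light" in minutes.columns
    metric_rows = []
    result = StudyResult(
        minutes, thresholds, days, episode_list, episode_table, pd.DataFrame(), pd.DataFrame(), cfg
    )
    for i, (day, episode) in enumerate(zip(days, episode_list)):
        metric_rows.append(
            mx.box1_metrics(
                episode,
                smoothed_power=result.day_array("smoothed_power", day),
                classes=result.class_matrix_day(day),
                wrist_off=result.day_array("wrist_off", day, fill=0.0).astype(bool),
                thresholds=thresholds,
                light=result.day_array("light", day) if has_light else None,
                phone_mask=phone_masks.get(i),
                immobility_percentile=cfg.immobility_percentile,
                light_threshold_lux=cfg.light_threshold_lux,
                bout_tolerance=cfg.bout_tolerance_min,
            )
        )
    metrics_df = mx.metrics_table(metric_rows)
    result.metrics = metrics_df

    day_valid = np.array(
        [not (e.no_sleep or d.partial) for e, d in zip(episode_list, days)], dtype=bool
    )
    if day_valid.sum() >= 2:
        immobility = metrics_df["SleepImmobility"].to_numpy(dtype=np.float64)
        result.stri = mx.stri_table(
            episode_list,
            day_valid=day_valid,
            denominator=cfg.stri_denominator,
            window=cfg.smooth_window_days,
            max_missing=cfg.smooth_max_missing,
            immobility=immobility,
        )
    return result


def write_outputs(result: StudyResult, out_dir: str | Path) -> None:
    """Write the standard output files of one run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.episode_table.to_csv(out / "sleep_episodes.csv")
    result.metrics.to_csv(out / "sleep_metrics.csv")
    if len(result.stri):
        result.stri.to_csv(out / "stri.csv")
    (out / "thresholds.json").write_text(
        json.dumps({str(k): v for k, v in result.thresholds.thresholds.items()}, indent=2)
    )


__all__ = ["StudyResult", "run_study", "write_outputs"]
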