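"""Pipeline configuration.

Every tunable of the processing chain lives here with its default. The
defaults reproduce the published processing constants (150-min non-wear
window, 0.0185 g wrist-off threshold, 100/60-min sweep windows, 90-min
clean-up window, 22.5-min join gap, 100-min minimum major episode, 60-min
button-press availability, 15-min phone-in-use cap, 1-lux light boundary,
40th-percentile immobility cut-off, 14-day smoothing with 3-missing-day
tolerance).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # --- minute presence ---
    #: a minute slot is "present" if at least this fraction of its expected
    #: samples exist (tolerates small clock jitter at recording edges)
    present_fraction: float = 0.8

    # --- non-wear (wrist-off) detection ---
    nonwear_window_min: int = 150
    nonwear_threshold_g: float = 0.0185
    #: how the forward and backward one-sided window means are combined
    #: before the RMS comparison: "min", "mean" or "max"
    nonwear_combine: str = "min"
    #: if True, square the smoothed SDs (true variances) before the RMS
    nonwear_square: bool = False

    # --- per-minute spectral power ---
    welch_segment: int = 256
    power_smooth_min: int = 15
    percentiles: tuple[float, ...] = (10.0, 25.0, 50.0, 75.0)
    min_valid_minutes: int = 1000
    #: classify on the 15-min smoothed combined power ("smoothed") or the
    #: raw per-minute combined power ("raw")
    classify_on: str = "smoothed"

    # --- episode detection ---
    wide_window_min: int = 100
    narrow_window_min: int = 60
    seed_score_threshold: float = 0.5
    edge_score_threshold: float = 0.0
    cleanup_window_min: int = 90
    cleanup_fraction: float = 0.75
    join_gap_min: float = 22.5
    min_major_min: int = 100
    button_avail_min: int = 60
    #: episodes overlapping more than this fraction of wrist-off minutes are
    #: flagged low-confidence for QC
    low_confidence_offwrist: float = 0.25

    # --- metrics ---
    immobility_percentile: float = 40.0
    light_threshold_lux: float = 1.0
    bout_tolerance_min: int = 1
    smooth_window_days: int = 14
    smooth_max_missing: int = 3
    #: STRI denominator: "day" (agreement over all 1440 sleep+wake minutes)
    #: or "sleep" (overlap with the average-day sleep set only)
    stri_denominator: str = "day"

    # --- phone ---
    phone_use_cap_min: float = 15.0
    phone_accel_percentiles: tuple[float, float] = (75.0, 90.0)

    def __post_init__(self) -> None:
        if self.nonwear_combine not in ("min", "mean", "max"):
            raise ValueError(f"nonwear_combine must be min/mean/max, got {self.nonwear_combine!r}")
        if self.classify_on not in ("smoothed", "raw"):
            raise ValueError(f"classify_on must be smoothed/raw, got {self.classify_on!r}")
        if self.stri_denominator not in ("day", "sleep"):
            raise ValueError(f"stri_denominator must be day/sleep, got {self.stri_denominator!r}")
        if not 0 < self.present_fraction <= 1:
            raise ValueError("present_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a flat YAML key-value file.

        Unknown keys raise so typos never silently fall back to defaults.
        """
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name in ("percentiles", "phone_accel_percentiles"):
            if name in data and isinstance(data[name], list):
                data[name] = tuple(data[name])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["percentiles"] = list(self.percentiles)
        data["phone_accel_percentiles"] = list(self.phone_accel_percentiles)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


DEFAULT_CONFIG = PipelineConfig()
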