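"""Per-minute activity scoring from spectral power.

Each minute's activity level is the area under its Welch power density
spectrum (per axis, mean-removed, zero-frequency bin excluded), which for
band-limited signals approximates the within-minute signal variance while
automatically discounting the constant gravity component. The three axis
powers are combined by an RMS, smoothed with a centered 15-minute window,
and referred to within-individual percentile thresholds (10/25/50/75 by
default) pooled over every valid minute of the whole study. Each minute is
then classified into one of five bands:

    A0: < p10    A1: [p10, p25)    A2: [p25, p50)    A3: [p50, p75)    A4: >= p75

Only the relative (percentile) position of a minute matters downstream, so
the Welch estimator settings affect precision but not the scale of the
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: activity-class codes; MISSING marks wrist-off or absent minutes
A0, A1, A2, A3, A4 = 0, 1, 2, 3, 4
MISSING_CLASS = -1

DEFAULT_PERCENTILES = (10.0, 25.0, 50.0, 75.0)
#: fewest samples for which a spectrum is still estimated
MIN_WELCH_SAMPLES = 16


def _nperseg(n: int, segment: int = 256) -> int:
    # cap at half the samples so at least ~3 half-overlapping segments exist
    return min(segment, max(n // 2, MIN_WELCH_SAMPLES // 2))


def welch_power_minute(
    samples: np.ndarray, rate_hz: float, segment: int = 256
) -> np.ndarray | float:
    """Spectral power of one minute (or a batch of minutes) of one axis.

    ``samples`` is 1-D (one minute) or 2-D ``(n_minutes, samples_per_min)``.
    The power density spectrum is estimated by Welch's method (Hann window,
    50% overlap, per-segment mean removal) and integrated over frequency by
    the trapezoid rule, excluding the zero-frequency bin. Minutes with too
    few samples for two segments yield NaN.
    """
    arr = np.asarray(samples, dtype=np.float64)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    n = arr.shape[1]
    if n < MIN_WELCH_SAMPLES:
        out = np.full(arr.shape[0], np.nan)
        return float(out[0]) if squeeze else out
    # a constant minute has exactly zero variance; short-circuit so the
    # result is an exact 0.0 rather than mean-removal rounding noise
    constant = np.ptp(arr, axis=1) == 0.0
    nps = _nperseg(n, segment)
    f, pxx = signal.welch(
        arr,
        fs=rate_hz,
        window="hann",
        nperseg=nps,
        noverlap=nps // 2,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    power = np.trapezoid(pxx[:, 1:], f[1:], axis=-1)
    power[constant] = 0.0
    return float(power[0]) if squeeze else power


def minute_powers(
    raw_axis: np.ndarray,
    rate_hz: float,
    origin_offset_samples: int,
    n_minutes: int,
    valid: np.ndarray,
    segment: int = 256,
) -> np.ndarray:
    """Per-minute Welch power for one axis of a whole recording.

    ``origin_offset_samples`` aligns the first sample onto the minute grid;
    ``valid`` marks the minutes worth scoring (present and not wrist-off).
    Complete minutes are batched through a single vectorised Welch call;
    minutes with interior missing samples are scored on their remaining
    samples individually.
    """
    spm = int(round(rate_hz * 60))
    padded = np.full(n_minutes * spm, np.nan)
    lo = origin_offset_samples
    padded[lo : lo + len(raw_axis)] = raw_axis
    m = padded.reshape(n_minutes, spm)

    powers = np.full(n_minutes, np.nan)
    n_ok = np.sum(~np.isnan(m), axis=1)
    full = valid & (n_ok == spm)
    if full.any():
        chunk = 8192
        idx = np.nonzero(full)[0]
        for s in range(0, len(idx), chunk):
            sel = idx[s : s + chunk]
            powers[sel] = welch_power_minute(m[sel], rate_hz, segment)
    partial = valid & ~full & (n_ok >= MIN_WELCH_SAMPLES)
    for i in np.nonzero(partial)[0]:
        row = m[i]
        powers[i] = welch_power_minute(row[~np.isnan(row)], rate_hz, segment)
    return powers


def combine_axes(
    power_x: np.ndarray | float, power_y: np.ndarray | float, power_z: np.ndarray | float
) -> np.ndarray | float:
    """RMS combination of the three per-axis powers:
    ``sqrt((px^2 + py^2 + pz^2) / 3)``."""
    px, py, pz = (np.asarray(p, dtype=np.float64) for p in (power_x, power_y, power_z))
    out = np.sqrt((px**2 + py**2 + pz**2) / 3.0)
    return float(out) if out.ndim == 0 else out


def smooth_power(
    combined: np.ndarray, valid: np.ndarray | None = None, window: int = 15
) -> np.ndarray:
    """Centered moving mean over valid slots, truncated at the edges.

    Slots outside ``valid`` (or NaN) contribute nothing and receive NaN
    output. An isolated valid slot keeps its own value.
    """
    v = np.asarray(combined, dtype=np.float64).copy()
    if valid is not None:
        v[~np.asarray(valid, dtype=bool)] = np.nan
    ok = ~np.isnan(v)
    filled = np.where(ok, v, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0], np.cumsum(ok)])
    n = len(v)
    half = window // 2
    t = np.arange(n)
    lo = np.maximum(t - half, 0)
    hi = np.minimum(t + (window - half - 1), n - 1) + 1
    s = csum[hi] - csum[lo]
    c = ccnt[hi] - ccnt[lo]
    out = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    out[~ok] = np.nan
    return out


@dataclass
class PercentileThresholds:
    """Within-individual power thresholds.

    Holds the pooled distribution of valid smoothed powers for the whole
    study so any percentile in (0, 100) can be queried (the immobility
    metric needs the 40th). Empirical percentiles use linear interpolation.
    """

    values: np.ndarray
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    participant: str | None = None
    thresholds: dict[float, float] = field(init=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        vals = np.sort(vals[~np.isnan(vals)])
        object.__setattr__(self, "values", vals)
        self.thresholds = {p: float(np.percentile(vals, p)) for p in self.percentiles}

    def threshold(self, p: float) -> float:
        if not 0 < p < 100:
            raise ValueError("percentile must be in (0, 100)")
        if p in self.thresholds:
            return self.thresholds[p]
        return float(np.percentile(self.values, p))

    @property
    def cuts(self) -> np.ndarray:
        """The classification cut-offs in ascending percentile order."""
        return np.array([self.thresholds[p] for p in sorted(self.thresholds)])


def percentile_thresholds(
    smoothed: np.ndarray,
    p_list: tuple[float, ...] = DEFAULT_PERCENTILES,
    min_valid_minutes: int = 1000,
    participant: str | None = None,
) -> PercentileThresholds:
    """Within-individual thresholds over all valid minutes of the study.

    Raises when fewer than ``min_valid_minutes`` valid minutes exist;
    pass a lower floor explicitly to proceed on short recordings.
    """
    vals = np.asarray(smoothed, dtype=np.float64)
    vals = vals[~np.isnan(vals)]
    if len(vals) < min_valid_minutes:
        raise ValueError(
            f"only {len(vals)} valid minutes (< {min_valid_minutes}); thresholds would be "
            "unstable — pass min_valid_minutes explicitly to lower the floor"
        )
    return PercentileThresholds(vals, tuple(p_list), participant)


def classify_minutes(
    smoothed: np.ndarray, thresholds: PercentileThresholds
) -> np.ndarray:
    """Classify minutes into the A0..A4 percentile bands.

    Bands are left-closed on the lower edge; a value equal to the top
    cut-off lands in A4. Missing minutes get MISSING_CLASS (-1).
    """
    v = np.asarray(smoothed, dtype=np.float64)
    cuts = thresholds.cuts
    if len(cuts) != 4:
        raise ValueError("classification needs exactly four percentile cut-offs")
    cls = np.searchsorted(cuts, np.nan_to_num(v, nan=-np.inf), side="right").astype(np.int8)
    cls[np.isnan(v)] = MISSING_CLASS
    return cls


__all__ = [
    "A0",
    "A1",
    "A2",
    "A3",
    "A4",
    "MISSING_CLASS",
    "DEFAULT_PERCENTILES",
    "welch_power_minute",
    "minute_powers",
    "combine_axes",
    "smooth_power",
    "PercentileThresholds",
    "percentile_thresholds",
    "classify_minutes",
]
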