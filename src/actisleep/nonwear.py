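"""Non-wear (wrist-off) detection.

The device keeps recording when it is taken off, producing nearly flat
traces, unlike sleep which retains residual low-level fluctuation. Wrist-off
minutes are found from the per-minute standard deviation of each
acceleration axis, smoothed with a 150-minute forward-and-backward moving
window, by comparing the RMS of the three smoothed axis values against a
fixed threshold of 0.0185 g (strictly below = wrist-off). Flagged minutes
are removed from all downstream analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest import RawActigraphy

WRIST_OFF_THRESHOLD_G = 0.0185
NONWEAR_WINDOW_MIN = 150


def minute_sd(raw: RawActigraphy, present_fraction: float = 0.8) -> pd.DataFrame:
    """Per-minute population SD of each acceleration axis.

    Returns a frame indexed by wall-clock minute starts with columns
    ``sd_x, sd_y, sd_z`` (g), ``n_samples``, ``present`` and, when the
    channels exist, per-minute means ``light`` (lux) and ``temp`` (C).
    Missing slots (below ``present_fraction`` sample coverage) carry NaN
    SDs, never 0.
    """
    origin = raw.start_time.floor("min")
    head = int(round((raw.start_time - origin).total_seconds() * raw.sampling_rate_hz))
    spm_f = raw.sampling_rate_hz * 60.0
    spm = int(round(spm_f))
    if abs(spm - spm_f) > 1e-6:
        raise ValueError("sampling rate must yield an integer number of samples per minute")

    n = raw.n_samples
    n_min = int(np.ceil((head + n) / spm))
    padded_len = n_min * spm

    def _padded(arr: np.ndarray | None) -> np.ndarray | None:
        if arr is None:
            return None
        out = np.full(padded_len, np.nan, dtype=np.float64)
        out[head : head + n] = arr
        return out.reshape(n_min, spm)

    data: dict[str, np.ndarray] = {}
    counts = None
    with np.errstate(invalid="ignore"):  # all-NaN minutes
        for axis in ("x", "y", "z"):
            m = _padded(getattr(raw, axis))
            data[f"sd_{axis}"] = np.nanstd(m, axis=1, ddof=0)
            if counts is None:
                counts = np.sum(~np.isnan(m), axis=1)
        for name in ("light", "temp"):
            m = _padded(getattr(raw, name))
            if m is not None:
                data[name] = np.nanmean(m, axis=1)

    need = int(np.ceil(present_fraction * spm))
    present = counts >= max(need, 2)
    for axis in ("x", "y", "z"):
        data[f"sd_{axis}"][~present] = np.nan
    data["n_samples"] = counts
    data["present"] = present

    index = origin + pd.to_timedelta(np.arange(n_min), unit="min")
    return pd.DataFrame(data, index=index)


def _one_sided_means(values: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Backward ([t-W+1, t]) and forward ([t, t+W-1]) means over present
    slots only, truncated at the series boundaries."""
    v = np.asarray(values, dtype=np.float64)
    ok = ~np.isnan(v)
    filled = np.where(ok, v, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0], np.cumsum(ok)])
    n = len(v)
    t = np.arange(n)

    lo = np.maximum(t - window + 1, 0)
    s = csum[t + 1] - csum[lo]
    c = ccnt[t + 1] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        back = np.where(c > 0, s / np.maximum(c, 1), np.nan)

    hi = np.minimum(t + window, n)
    s = csum[hi] - csum[t]
    c = ccnt[hi] - ccnt[t]
    fwd = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    return back, fwd


def fb_moving_average(
    values: np.ndarray | pd.Series,
    window: int = NONWEAR_WINDOW_MIN,
    combine: str = "mean",
) -> np.ndarray:
    """Forward-and-backward moving average of a per-slot series.

    For slot ``t`` the backward mean covers ``[t-W+1, t]`` and the forward
    mean ``[t, t+W-1]``, each over present (non-NaN) slots only and
    truncated at the series boundaries. ``combine`` selects how the two
    one-sided means merge into one value: ``"mean"`` (arithmetic mean,
    symmetric smoother), ``"min"`` (quietest direction — used by the
    wrist-off detector) or ``"max"``. A slot whose both windows are fully
    missing yields NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    back, fwd = _one_sided_means(np.asarray(values, dtype=np.float64), window)
    if combine == "mean":
        both = (back + fwd) / 2.0
    elif combine == "min":
        both = np.minimum(back, fwd)
    elif combine == "max":
        both = np.maximum(back, fwd)
    else:
        raise ValueError(f"combine must be mean/min/max, got {combine!r}")
    # a slot with one all-missing window falls back to the defined side
    out = np.where(np.isnan(back), fwd, np.where(np.isnan(fwd), back, both))
    return out


def detect_wrist_off(
    smoothed_sd: pd.DataFrame | np.ndarray,
    threshold: float = WRIST_OFF_THRESHOLD_G,
    square: bool = False,
) -> np.ndarray:
    """Flag wrist-off minutes from smoothed per-axis SDs.

    A present slot is wrist-off iff the RMS of the three smoothed axis
    values is strictly below ``threshold``. With ``square=True`` the
    smoothed SDs are squared (true variances) before the RMS; the default
    compares in SD (g) units, matching the magnitude of the 0.0185
    threshold. Missing slots are neither on nor off (False, with NaN
    input propagating to not-off).
    """
    if isinstance(smoothed_sd, pd.DataFrame):
        arr = smoothed_sd[["sd_x", "sd_y", "sd_z"]].to_numpy(dtype=np.float64)
    else:
        arr = np.asarray(smoothed_sd, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("expected an (n, 3) array of smoothed per-axis SDs")
    vals = arr**2 if square else arr
    with np.errstate(invalid="ignore"):
        rms = np.sqrt(np.mean(vals**2, axis=1))
        mask = rms < threshold
    mask[np.isnan(rms)] = False
    return mask


def wrist_off_mask(
    minutes: pd.DataFrame,
    window: int = NONWEAR_WINDOW_MIN,
    threshold: float = WRIST_OFF_THRESHOLD_G,
    combine: str = "min",
    square: bool = False,
) -> pd.DataFrame:
    """Full wrist-off chain on a minute-SD frame.

    Adds ``smooth_sd_x/y/z`` and boolean ``wrist_off`` columns. ``combine``
    defaults to ``"min"`` for detection: a minute is quiet when either its
    past or its future 150-minute window is flat, which recovers non-wear
    segments down to ~window length instead of requiring both windows to
    sit inside the segment.
    """
    out = minutes.copy()
    smoothed = np.empty((len(out), 3))
    for j, axis in enumerate(("sd_x", "sd_y", "sd_z")):
        smoothed[:, j] = fb_moving_average(out[axis].to_numpy(), window, combine=combine)
        out[f"smooth_{axis}"] = smoothed[:, j]
    off = detect_wrist_off(smoothed, threshold=threshold, square=square)
    off &= out["present"].to_numpy()
    out["wrist_off"] = off
    return out


__all__ = [
    "WRIST_OFF_THRESHOLD_G",
    "NONWEAR_WINDOW_MIN",
    "minute_sd",
    "fb_moving_average",
    "detect_wrist_off",
    "wrist_off_mask",
]
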