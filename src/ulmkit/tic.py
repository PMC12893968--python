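"""Time–intensity-curve (TIC) extraction and quantitative bolus descriptors.

A contrast bolus passing through a lesion ROI traces a characteristic curve:
flat pre-contrast baseline, wash-in rise to a peak, slower wash-out decay.
The descriptors computed here are the standard contrast-enhanced ultrasound
quantities: peak intensity (PI, baseline-relative and therefore
dimensionless), time to peak (TTP, peak time minus contrast arrival), area
under the curve (AUC), and wash-in / wash-out slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TICurve", "TICParams", "extract_tic", "tic_parameters"]


@dataclass
class TICurve:
    """ROI-mean intensity versus time.

    ``baseline`` is the pre-contrast mean; ``arrival_time_s`` is None when no
    contrast arrival was detected.  ``truth`` optionally carries generator
    ground truth (synthetic curves only).
    """

    time_s: np.ndarray
    intensity: np.ndarray
    baseline: float
    arrival_time_s: float | None = None
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


@dataclass
class TICParams:
    """Bolus descriptors.  PI is (peak - baseline)/baseline, dimensionless;
    ``pi_db`` is the same ratio as 10 log10(peak/baseline).  Slopes in
    intensity units per second; wash_out_rate <= 0 on a valid bolus.
    ``ratio`` = wash_in / wash_out (negative).  Fields are NaN when the
    corresponding quantity is undefined (flags list why)."""

    pi: float
    pi_db: float
    ttp_s: float
    auc: float
    wash_in_rate: float
    wash_out_rate: float
    ratio: float
    peak_time_s: float
    arrival_time_s: float
    flags: list = field(default_factory=list)


def extract_tic(stack, roi_mask: np.ndarray, baseline_frames: int = 10,
                arrival_k_sd: float = 2.0, arrival_run: int = 3) -> TICurve:
    """ROI-mean intensity per frame, with automatic arrival detection.

    The baseline is the mean over the first ``baseline_frames`` frames.
    Contrast arrival is the first time the curve exceeds
    ``baseline + arrival_k_sd * sd(pre-contrast)`` sustained for at least
    ``arrival_run`` consecutive frames; if never exceeded, the curve is
    returned with ``arrival_time_s=None``.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != stack.frames.shape[1:]:
        raise ValueError("ROI mask shape must match the frame grid")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    y = stack.frames[:, roi_mask].mean(axis=1)
    t = np.arange(stack.n_frames) / stack.frame_rate_hz
    nb = min(baseline_frames, len(y))
    baseline = float(y[:nb].mean())
    sd = float(y[:nb].std(ddof=1)) if nb > 1 else 0.0
    thr = baseline + arrival_k_sd * sd
    above = y > thr
    arrival = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= arrival_run:
            arrival = t[i - arrival_run + 1]
            break
    if baseline <= 0:
        baseline = max(baseline, np.finfo(float).tiny)
    return TICurve(t, y, baseline, arrival_time_s=arrival)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    out = np.convolve(ypad, kernel, mode="same")[pad:pad + len(y)]
    return out


def tic_parameters(tic: TICurve, smooth_window: int = 5) -> TICParams:
    """Compute PI / TTP / AUC / wash-in / wash-out from a TIC.

    Peak finding uses an optional moving-average smoothing (the raw curve is
    kept for the AUC).  The wash-in rate is the least-squares slope of the
    ascending limb between 10% and 90% of (peak - baseline); the wash-out
    rate is the chord slope from the peak to 50% decay (or the end of the
    record, flagged ``washout_truncated``).  The AUC is the trapezoid over
    the whole acquisition.
    """
    if tic.arrival_time_s is None:
        raise ValueError("contrast arrival undefined; cannot compute parameters")
    t, y = tic.time_s, tic.intensity
    flags: list[str] = []
    ys = _moving_average(y, smooth_window)
    post = t >= tic.arrival_time_s
    if post.sum() < 3:
        raise ValueError("need >= 3 post-arrival samples")
    i_peak = int(np.flatnonzero(post)[0] + np.argmax(ys[post]))
    peak = float(ys[i_peak])  # smoothed peak value; raw max is noise-biased
    t_peak = float(t[i_peak])
    b = tic.baseline
    pi = (peak - b) / b
    pi_db = 10.0 * np.log10(max(peak, np.finfo(float).tiny) / b)
    ttp = t_peak - tic.arrival_time_s
    auc = float(np.trapezoid(y, t))

    # wash-in: least squares on ascending limb between 10% and 90% of rise
    amp = peak - b
    asc = (t >= tic.arrival_time_s) & (t <= t_peak)
    lo, hi = b + 0.1 * amp, b + 0.9 * amp
    sel = asc & (y >= lo) & (y <= hi)
    if sel.sum() >= 2:
        wash_in = float(np.polyfit(t[sel], y[sel], 1)[0])
    elif asc.sum() >= 2:
        ta, ya = t[asc], y[asc]
        wash_in = float((ya[-1] - ya[0]) / (ta[-1] - ta[0]))
        flags.append("wash_in_two_point")
    else:
        wash_in = np.nan
        flags.append("wash_in_undefined")

    # wash-out: chord from peak to 50% decay (or end of record), on the
    # smoothed curve — noise would otherwise trigger the crossing early
    if i_peak == len(y) - 1:
        wash_out = np.nan
        flags.append("washout_undefined_peak_at_end")
    else:
        target = b + 0.5 * amp
        after = np.flatnonzero((np.arange(len(ys)) > i_peak) & (ys <= target))
        if len(after):
            j = int(after[0])
        else:
            j = len(ys) - 1
            flags.append("washout_truncated")
        wash_out = float((ys[j] - peak) / (t[j] - t_peak))
    ratio = wash_in / wash_out if (np.isfinite(wash_in) and np.isfinite(wash_out)
                                   and wash_out != 0) else np.nan
    return TICParams(pi=pi, pi_db=pi_db, ttp_s=ttp, auc=auc,
                     wash_in_rate=wash_in, wash_out_rate=wash_out,
                     ratio=ratio, peak_time_s=t_peak,
                     arrival_time_s=tic.arrival_time_s, flags=flags)
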