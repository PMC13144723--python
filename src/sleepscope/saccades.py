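"""Conjugate-saccade detection and kinematic scoring from eye-angle traces.

The chain is: detrend (200 s running mean subtracted) -> 1.5 s running
median -> fused-lasso (total-variation) denoising (lambda = 0.25) ->
candidate detection on the product of left/right eye velocities -> selection
by interocular correlation and fused-lasso residuals -> kinematic scoring
(post-saccadic decay slope, fixation duration, peak speed) on the raw trace.

Angles are radians throughout; slopes and speeds are reported in deg/s as is
conventional for oculomotor kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import find_peaks

from sleepscope import presets
from sleepscope.presets import DEG
from sleepscope.tvdenoise import tv_denoise


@dataclass
class EyeAngleTrace:
    """Paired left/right eye-angle series on a uniform time grid (radians)."""

    left_rad: np.ndarray
    right_rad: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.left_rad = np.asarray(self.left_rad, dtype=float)
        self.right_rad = np.asarray(self.right_rad, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if self.left_rad.shape != self.right_rad.shape or self.left_rad.ndim != 1:
            raise ValueError("left/right series must be 1-D and equal length")
        for a in (self.left_rad, self.right_rad):
            if np.isnan(a).any():
                _interp_nan_inplace(a)

    @property
    def n(self) -> int:
        return self.left_rad.size

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.n) / self.fs_hz


def _interp_nan_inplace(a: np.ndarray) -> None:
    """Linear ingest-interpolation of NaN runs (edges held)."""
    bad = np.isnan(a)
    if bad.all():
        raise ValueError("trace is all-NaN")
    idx = np.arange(a.size)
    a[bad] = np.interp(idx[bad], idx[~bad], a[~bad])


@dataclass
class FilteredTrace:
    """Detrended / denoised (piecewise-constant) series and their residuals."""

    detrended_left: np.ndarray
    detrended_right: np.ndarray
    denoised_left: np.ndarray
    denoised_right: np.ndarray
    fs_hz: float

    @property
    def residual_left(self) -> np.ndarray:
        return self.detrended_left - self.denoised_left

    @property
    def residual_right(self) -> np.ndarray:
        return self.detrended_right - self.denoised_right

    @property
    def n(self) -> int:
        return self.denoised_left.size


@dataclass
class SaccadeEvent:
    """One detected conjugate saccade and its kinematic scores."""

    onset_s: float
    offset_s: float
    peak_index: int
    direction: int
    amplitude_left_rad: float = np.nan
    amplitude_right_rad: float = np.nan
    peak_speed_deg_s: float = np.nan
    decay_slope_deg_s: float = np.nan
    fixation_s: float = np.nan
    censored: bool = False
    rejected_reason: str | None = None

    @property
    def amplitude_rad(self) -> float:
        return 0.5 * (abs(self.amplitude_left_rad) + abs(self.amplitude_right_rad))


def _odd_window(seconds: float, fs: float) -> int:
    w = int(round(seconds * fs))
    return max(3, w + (w + 1) % 2)


def preprocess(
    trace: EyeAngleTrace,
    lam: float = presets.FUSED_LASSO_LAMBDA,
    mean_window_s: float = presets.MEAN_WINDOW_S,
    median_window_s: float = presets.MEDIAN_WINDOW_S,
) -> FilteredTrace:
    """Detrend, median-filter and fused-lasso denoise both eye traces.

    The 200 s running mean is a slow-drift baseline and is subtracted (a
    literal 200 s smoother would erase saccades).  Residuals are defined as
    detrended minus denoised, so residual + denoised == detrended exactly.
    """
    fs = trace.fs_hz
    med_w = _odd_window(median_window_s, fs)
    if trace.n < med_w:
        raise ValueError("trace shorter than the median-filter window")
    mean_w = max(1, int(round(mean_window_s * fs)))
    out = {}
    for side, raw in (("left", trace.left_rad), ("right", trace.right_rad)):
        baseline = uniform_filter1d(raw, size=mean_w, mode="nearest")
        detr = raw - baseline
        med = median_filter(detr, size=med_w, mode="nearest")
        out[f"detrended_{side}"] = detr
        out[f"denoised_{side}"] = tv_denoise(med, lam)
    return FilteredTrace(fs_hz=fs, **out)


def _central_velocity(x: np.ndarray, fs: float) -> np.ndarray:
    v = np.zeros_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * (fs / 2.0)
    return v


def detect_candidates(
    filtered: FilteredTrace,
    threshold_rad2_s2: float = presets.VPROD_THRESHOLD_MULTI,
    min_isi_s: float = presets.MIN_ISI_S,
) -> np.ndarray:
    """Indices of candidate saccade peaks in the velocity-product series.

    Local maxima of v_left * v_right (central differences of the denoised
    series) above threshold, greedily pruned so surviving peaks are at least
    ``min_isi_s`` apart (larger peak wins).
    """
    if threshold_rad2_s2 <= 0:
        raise ValueError("threshold must be > 0")
    fs = filtered.fs_hz
    v_l = _central_velocity(filtered.denoised_left, fs)
    v_r = _central_velocity(filtered.denoised_right, fs)
    prod = v_l * v_r
    peaks, props = find_peaks(prod, height=threshold_rad2_s2, plateau_size=1)
    if peaks.size == 0:
        return peaks
    heights = props["peak_heights"]
    order = np.argsort(heights)[::-1]
    min_gap = min_isi_s * fs
    kept: list[int] = []
    for i in order:
        p = peaks[i]
        if all(abs(p - q) >= min_gap for q in kept):
            kept.append(int(p))
    return np.array(sorted(kept), dtype=int)


def _rolling_window(center: int, half: int, n: int) -> slice:
    return slice(max(0, center - half), min(n, center + half + 1))


def _locate_onset_offset(
    vbar: np.ndarray, peak: int, fs: float, vfrac: float = presets.ONSET_OFFSET_VFRAC
) -> tuple[int, int, float, int]:
    """Onset/offset by the 10%-of-peak rule on raw binocular velocity.

    Returns (onset index, offset index, peak |velocity|, refined peak index).
    The peak is refined to the local |velocity| maximum near the candidate.
    """
    n = vbar.size
    lo, hi = max(1, peak - 5), min(n - 1, peak + 6)
    k = lo + int(np.argmax(np.abs(vbar[lo:hi])))
    vpk = abs(vbar[k])
    thr = vfrac * vpk
    onset = k
    limit = max(0, k - int(round(1.0 * fs)))
    while onset > limit and abs(vbar[onset - 1]) >= thr:
        onset -= 1
    onset = max(0, onset - 1)
    offset = k
    limit = min(n - 1, k + int(round(2.0 * fs)))
    while offset < limit and abs(vbar[offset]) >= thr:
        offset += 1
    return onset, offset, vpk, k


def select_saccades(
    candidates: np.ndarray,
    filtered: FilteredTrace,
    corr_win_s: float = presets.CORR_WINDOW_S,
    corr_min: float = presets.CORR_MIN,
    resid_win_s: float = presets.RESID_WINDOW_S,
    resid_max_rad: float = presets.RESID_MAX_RAD,
) -> tuple[list[SaccadeEvent], list[SaccadeEvent]]:
    """Apply the interocular-correlation and residual criteria.

    A candidate is accepted iff the rolling Pearson correlation between the
    detrended eye traces in a window centered on the peak exceeds
    ``corr_min`` and the rolling mean absolute fused-lasso residual (both
    eyes pooled) is below ``resid_max_rad``.  Returns (accepted, rejected);
    rejected events carry a reason.
    """
    fs = filtered.fs_hz
    n = filtered.n
    for w in (corr_win_s, resid_win_s):
        if int(w * fs) > n:
            raise ValueError("selection window longer than trace")
    half_c = int(round(corr_win_s * fs / 2))
    half_r = int(round(resid_win_s * fs / 2))
    dl, dr = filtered.detrended_left, filtered.detrended_right
    resid = 0.5 * (np.abs(filtered.residual_left) + np.abs(filtered.residual_right))
    vbar = 0.5 * (
        _central_velocity(filtered.detrended_left, fs)
        + _central_velocity(filtered.detrended_right, fs)
    )
    accepted: list[SaccadeEvent] = []
    rejected: list[SaccadeEvent] = []
    for p in np.atleast_1d(candidates).astype(int):
        sl = _rolling_window(p, half_c, n)
        a, b = dl[sl], dr[sl]
        sa, sb = a.std(), b.std()
        corr = float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)) if sa > 0 and sb > 0 else 0.0
        mean_resid = float(resid[_rolling_window(p, half_r, n)].mean())
        onset, offset, vpk, k = _locate_onset_offset(vbar, p, fs)
        direction = int(np.sign(vbar[k])) or 1
        ev = SaccadeEvent(
            onset_s=onset / fs, offset_s=offset / fs, peak_index=k, direction=direction
        )
        if corr <= corr_min:
            ev.rejected_reason = "correlation"
            rejected.append(ev)
        elif mean_resid >= resid_max_rad:
            ev.rejected_reason = "residual"
            rejected.append(ev)
        else:
            accepted.append(ev)
    return accepted, rejected


def score_kinematics(
    event: SaccadeEvent,
    trace: EyeAngleTrace,
    next_onset_s: float | None = None,
    period_end_s: float | None = None,
    decay_fraction: float = presets.FIXATION_DECAY_FRACTION,
) -> SaccadeEvent:
    """Complete a saccade event with amplitude, slope, fixation and speed.

    Per eye: baseline = median of the raw angle over 1 s pre-onset;
    post-saccadic amplitude A = raw(offset) - baseline; the fixation ends at
    the first crossing of baseline + ``decay_fraction`` * A; the decay slope
    is the absolute OLS slope of the raw angle from offset to that crossing.
    Events whose decay is cut short by the next saccade or by the end of the
    quiescent period are censored at that boundary.  Binocular values are
    the mean of the two eyes; peak speed is the largest absolute
    central-difference velocity between onset and offset.
    """
    fs = trace.fs_hz
    n = trace.n
    i_on = int(round(event.onset_s * fs))
    i_off = int(round(event.offset_s * fs))
    limit = n - 1
    censored = False
    if period_end_s is not None:
        limit = min(limit, int(round(period_end_s * fs)))
    if next_onset_s is not None:
        limit = min(limit, int(round(next_onset_s * fs)))
    if i_off >= limit:
        return replace(
            event, censored=True, fixation_s=0.0, decay_slope_deg_s=np.nan,
            peak_speed_deg_s=np.nan,
        )
    slopes, fixations, amps, speeds, cens = [], [], [], [], []
    for raw in (trace.left_rad, trace.right_rad):
        base = float(np.median(raw[max(0, i_on - int(round(fs))) : max(1, i_on)]))
        amp = raw[i_off] - base
        seg = raw[i_off : limit + 1]
        thr = base + decay_fraction * amp
        if amp >= 0:
            crossed = np.nonzero(seg <= thr)[0]
        else:
            crossed = np.nonzero(seg >= thr)[0]
        if crossed.size:
            j = int(crossed[0])
            c = False
        else:
            j = seg.size - 1
            c = True
        fix = j / fs
        # regress up to the last sample still above the threshold; the first
        # sub-threshold sample already belongs to whatever movement ended the
        # fixation and would bias the decay estimate
        k_end = j if (not c and j >= 3) else j + 1
        if j >= 2:
            t = np.arange(k_end) / fs
            slope = abs(float(np.polyfit(t, seg[:k_end], 1)[0])) * DEG
        else:
            slope = 0.0
        v = _central_velocity(raw, fs)[max(1, i_on) : i_off + 1]
        speeds.append(float(np.max(np.abs(v))) * DEG if v.size else np.nan)
        slopes.append(slope)
        fixations.append(fix)
        amps.append(amp)
        cens.append(c)
    return replace(
        event,
        amplitude_left_rad=amps[0],
        amplitude_right_rad=amps[1],
        decay_slope_deg_s=float(np.mean(slopes)),
        fixation_s=float(np.mean(fixations)),
        peak_speed_deg_s=float(np.mean(speeds)),
        censored=censored or any(cens),
    )


def detect_and_score(
    trace: EyeAngleTrace,
    variant: str = "multi",
    period_end_s: float | None = None,
    lam: float = presets.FUSED_LASSO_LAMBDA,
) -> tuple[list[SaccadeEvent], FilteredTrace]:
    """Full chain: preprocess, detect, select and score all saccades.

    ``variant`` selects the detection threshold ("single": 0.32,
    "multi": 0.60 rad^2/s^2).  Accepted events are returned sorted by onset,
    each scored with the following accepted event's onset as the censoring
    boundary.
    """
    thr = {
        "single": presets.VPROD_THRESHOLD_SINGLE,
        "multi": presets.VPROD_THRESHOLD_MULTI,
    }[variant]
    filtered = preprocess(trace, lam=lam)
    cands = detect_candidates(filtered, threshold_rad2_s2=thr)
    accepted, _ = select_saccades(cands, filtered)
    accepted.sort(key=lambda e: e.onset_s)
    scored = []
    for i, ev in enumerate(accepted):
        nxt = accepted[i + 1].onset_s if i + 1 < len(accepted) else None
        scored.append(
            score_kinematics(ev, trace, next_onset_s=nxt, period_end_s=period_end_s)
        )
    return scored, filtered


def events_to_dataframe(events: list[SaccadeEvent]):
    """Tabulate events (one row per saccade) as a pandas DataFrame."""
    import pandas as pd

    cols = [
        "onset_s", "offset_s", "direction", "amplitude_left_rad",
        "amplitude_right_rad", "peak_speed_deg_s", "decay_slope_deg_s",
        "fixation_s", "censored", "rejected_reason",
    ]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events])
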