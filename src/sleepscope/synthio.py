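"""Synthetic behavior, head-image and neural data generators.

Raw recordings behind this analysis are tens of terabytes and not
redistributable, so every downstream stage is exercised on synthetic data
carrying the statistical structure the analysis assumes: semi-Markov state
schedules over circadian time, per-substate conjugate-saccade processes with
the published rate/fixation/slope/peak-speed kinematics, wake swim bouts,
sub-threshold quiescent locomotion, rendered two-eye head frames, and neural
populations containing suppressed, ramping and event-firing cells with
bleaching and missing samples.

Every generator is deterministic for a fixed seed and emits a log of ground
truth (injected saccade times and kinematics, neuron class labels, event
times); recovery tests compare against these logs.

Saccade waveform
----------------
A saccade is injected as a yoked linear rise at the sampled peak speed to an
overshoot peak, a fast settle onto the plateau amplitude A, a slow linear
per-eye decay at the sampled slope for a hold time, and a fast per-eye
return plunge to baseline, staggered across the eyes.  The hold time is
solved per eye so the angle first crosses baseline + 0.33 A exactly at the
sampled fixation duration after saccade offset; the gap to the next saccade
is drawn so the realized rate approaches the preset rate (subject to a
minimum ~1 s of baseline between events, which the downstream 1.5 s running
median needs to reset).  See docs/methods.md for why the published
kinematics force this waveform at finite sampling rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sleepscope import presets
from sleepscope.presets import DEG, SubstateKinematics
from sleepscope.neuro_prep import NeuronMatrix
from sleepscope.saccades import EyeAngleTrace
from sleepscope.states import SpeedTrace

RETURN_DRIFT_DEG_S = 400.0     # per-eye return plunge; staggered across eyes
SETTLE_SPEED_FRACTION = 0.4    # settle speed as a fraction of peak speed
AMPLITUDE_PAD_DEG = 3.0        # overshoot margin above the plateau amplitude


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass
class StateSchedule:
    """Contiguous behavioral-state segments plus light/loading context.

    ``segments`` is a list of (start_s, end_s, state); ``lights`` is either
    {"constant": 0|1} or {"on_h": h1, "off_h": h2} in clock hours;
    ``clock_offset_h`` is the clock time (hours from midnight) at t = 0.
    """

    segments: list
    lights: dict
    clock_offset_h: float = 9.0
    loading_day: bool = True

    def __post_init__(self) -> None:
        t = 0.0
        for s, e, state in self.segments:
            if abs(s - t) > 1e-6 or e <= s:
                raise ValueError("segments must be contiguous and non-empty")
            if state not in presets.STATES:
                raise ValueError(f"unknown state {state!r}")
            if state in ("QEM1", "QEM2", "QEM3", "QNEM") and e - s < 60.0:
                raise ValueError("quiescent segments must last >= 60 s")
            t = e
        if not self.segments:
            raise ValueError("schedule is empty")

    @property
    def duration_s(self) -> float:
        return self.segments[-1][1]

    def clock_h(self, t_s) -> np.ndarray:
        return (np.asarray(t_s, dtype=float) / 3600.0 + self.clock_offset_h) % 24.0

    def lights_at(self, t_s) -> np.ndarray:
        t_s = np.asarray(t_s, dtype=float)
        if "constant" in self.lights:
            return np.full(t_s.shape, float(self.lights["constant"]))
        h = self.clock_h(t_s)
        on, off = self.lights["on_h"], self.lights["off_h"]
        if on <= off:
            lit = (h >= on) & (h < off)
        else:
            lit = (h >= on) | (h < off)
        return lit.astype(float)

    def day1_at(self, t_s) -> np.ndarray:
        t_s = np.asarray(t_s, dtype=float)
        if not self.loading_day:
            return np.zeros(t_s.shape)
        end = (24.0 - self.clock_offset_h % 24.0) * 3600.0
        return (t_s < end).astype(float)

    def state_at(self, t_s: float) -> str:
        for s, e, state in self.segments:
            if s <= t_s < e:
                return state
        return self.segments[-1][2]

    def periods_of(self, state: str) -> list:
        return [(s, e) for s, e, st in self.segments if st == state]

    def occupancy(self) -> dict:
        tot = self.duration_s
        out = {s: 0.0 for s in presets.STATES}
        for s, e, state in self.segments:
            out[state] += (e - s) / tot
        return out

    def labels_per_minute(self) -> np.ndarray:
        mins = int(self.duration_s // 60)
        return np.array([self.state_at(60.0 * m + 30.0) for m in range(mins)],
                        dtype=object)


def make_schedule(
    duration_s: float,
    light_cycle_spec: dict | None = None,
    occupancy_targets: dict | None = None,
    seed: int = 0,
    clock_offset_h: float = 9.0,
    segment_s: tuple[float, float] = (120.0, 360.0),
) -> StateSchedule:
    """Semi-Markov schedule whose per-phase state fractions approach targets.

    ``occupancy_targets`` maps state -> fraction (remainder is Wake), either
    flat or keyed per phase as {"day": {...}, "night": {...}}.  Segment
    durations are uniform on ``segment_s`` and are truncated at phase
    boundaries, so empirical fractions converge as the duration grows.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    lights = light_cycle_spec or {"on_h": 9.0, "off_h": 23.0}
    targets = occupancy_targets or {"QEM1": 0.3}
    per_phase = "day" in targets or "night" in targets
    for t in (targets.values() if per_phase else [targets]):
        if per_phase and not isinstance(t, dict):
            raise ValueError("mixed flat/per-phase targets")
        tt = t if per_phase else targets
        if sum(tt.values()) > 1.0 + 1e-9:
            raise ValueError("occupancy targets must sum to <= 1")
        if per_phase is False:
            break
    rng = np.random.default_rng(seed)
    probe = StateSchedule(
        segments=[(0.0, duration_s, "Wake")], lights=lights,
        clock_offset_h=clock_offset_h,
    )
    segments: list = []
    t = 0.0
    while t < duration_s:
        phase = "day" if probe.lights_at(t) > 0.5 else "night"
        tgt = targets[phase] if per_phase else targets
        states = list(tgt.keys()) + ["Wake"]
        p = np.array(list(tgt.values()) + [max(0.0, 1.0 - sum(tgt.values()))])
        if p.sum() <= 0:
            raise ValueError("degenerate occupancy targets")
        state = rng.choice(states, p=p / p.sum())
        dur = float(rng.uniform(*segment_s))
        end = min(t + dur, duration_s)
        # truncate at the next lights transition so per-phase targets hold
        if "constant" not in lights:
            h = probe.clock_h(t)
            for edge in (lights["on_h"], lights["off_h"]):
                dt_h = (edge - h) % 24.0
                if 1e-9 < dt_h * 3600.0 < end - t:
                    end = t + dt_h * 3600.0
        if end - t < 60.0 and state != "Wake":
            state = "Wake"
        if segments and segments[-1][2] == state:
            segments[-1] = (segments[-1][0], end, state)
        else:
            segments.append((t, end, state))
        t = end
    return StateSchedule(
        segments=segments, lights=lights, clock_offset_h=clock_offset_h
    )


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be > 0")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _sym_trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                      n_sd: float = 2.5) -> float:
    """Normal draw truncated symmetrically (mean-preserving)."""
    while True:
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sd * sd:
            return float(x)


@dataclass
class BehaviorLog:
    """Ground truth emitted by :func:`synth_behavior`."""

    saccades: pd.DataFrame
    bouts: pd.DataFrame
    schedule: StateSchedule


@dataclass
class BehaviorSynthesis:
    trace: EyeAngleTrace
    speed: SpeedTrace
    heading_rad: np.ndarray
    roll_rad: np.ndarray
    pitch_rad: np.ndarray
    log: BehaviorLog

    def __iter__(self):  # allow (trace, speed, log) unpacking
        return iter((self.trace, self.speed, self.log))


def _mean_event_span_s(kin: SubstateKinematics, fs: float) -> float:
    """Expected duration of one injected saccade event (rise to baseline)."""
    a = kin.amplitude_deg[0]
    v = max(kin.peak_speed_deg_s[0], 1.0)
    d = v / fs
    rise = max(2, math.ceil((a + AMPLITUDE_PAD_DEG) / d))
    settle = math.ceil(max(rise * d - a, 0.0) / (SETTLE_SPEED_FRACTION * v / fs))
    f, s = kin.fixation_s[0], kin.decay_slope_deg_s[0]
    vr = RETURN_DRIFT_DEG_S
    hold = max(0.0, (f - (1 - presets.FIXATION_DECAY_FRACTION) * a / vr)
               / (1.0 - min(s / vr, 0.9)))
    drift = max(a - s * hold, 0.0) / vr
    return (rise + settle) / fs + hold + drift


def _one_eye_wave(
    fs: float, amp_deg: float, vpeak_deg: float, slope_deg: float, fix_s: float,
    vr: float = RETURN_DRIFT_DEG_S,
) -> tuple[np.ndarray, float]:
    """One eye's saccade waveform (degrees) and its realized fixation.

    Linear rise at the peak speed to an overshoot, fast settle onto the
    plateau ``amp_deg``, linear decay at ``slope_deg`` for a hold time solved
    so the 33% amplitude crossing lands ``fix_s`` after saccade offset, then
    a return drift to baseline (clamped at zero hold for short fixations).
    """
    d = vpeak_deg / fs
    n_rise = max(2, math.ceil((amp_deg + AMPLITUDE_PAD_DEG) / d))
    dec = SETTLE_SPEED_FRACTION * vpeak_deg / fs
    cross_frac = 1.0 - presets.FIXATION_DECAY_FRACTION
    hold = (fix_s - cross_frac * amp_deg / vr) / (1.0 - min(slope_deg / vr, 0.9))
    if hold < 0.0:
        hold = 0.0
    if slope_deg * hold >= cross_frac * amp_deg and slope_deg > 0:
        # steep decays cross the 33% threshold during the hold itself
        realized_fix = cross_frac * amp_deg / slope_deg
    else:
        realized_fix = hold + (
            amp_deg - slope_deg * hold
            - presets.FIXATION_DECAY_FRACTION * amp_deg
        ) / vr
    out = []
    level = 0.0
    for _ in range(n_rise):
        level += d
        out.append(level)
    while level - dec > amp_deg:
        level -= dec
        out.append(level)
    out.append(amp_deg)
    n_hold = int(round(hold * fs))
    for k in range(1, n_hold + 1):
        out.append(amp_deg - slope_deg * k / fs)
    level = amp_deg - slope_deg * n_hold / fs
    while level > 0.0:
        level -= vr / fs
        out.append(max(level, 0.0))
    return np.array(out), realized_fix


def _inject_saccade(
    left_deg: np.ndarray, right_deg: np.ndarray, i0: int, fs: float,
    amp_deg: float, vpeak_deg: float, slope_deg: float, fix_s: float,
    rng: np.random.Generator, sign: float, limit_index: int | None = None,
) -> tuple[int, float] | None:
    """Write one conjugate saccade into both eye traces starting at i0.

    The rapid rise is yoked; the plateau amplitude, decay slope and
    return-drift speed carry small independent mean-preserving per-eye
    jitters, so the slow phases are similar but not sample-identical across
    eyes (real eyes are not perfectly conjugate; identical slow ramps would
    also create spurious conjugate velocity events once the fused lasso
    quantizes them into time-aligned steps).  The hold time is solved per
    eye so both eyes cross their 33% threshold at the sampled fixation
    duration regardless of the jitter.

    Returns (index just past the event in either eye, realized binocular
    fixation duration), or None when the event would extend past
    ``limit_index`` (nothing is written in that case).
    """
    ja = float(np.clip(rng.normal(0.0, 0.08), -0.2, 0.2))
    js = float(rng.uniform(0.1, 0.3)) * (1.0 if rng.random() < 0.5 else -1.0)
    jv = float(rng.uniform(0.15, 0.3)) * (1.0 if rng.random() < 0.5 else -1.0)
    stagger = float(rng.uniform(0.2, 0.35)) * (1.0 if rng.random() < 0.5 else -1.0)
    waves, fixes = [], []
    for sa, ss, sv, df in ((1.0 + ja, 1.0 + js, 1.0 + jv, stagger),
                           (1.0 - ja, 1.0 - js, 1.0 - jv, -stagger)):
        wave, rf = _one_eye_wave(
            fs, amp_deg * sa, vpeak_deg, slope_deg * ss,
            max(fix_s + df / 2.0, 0.5),
            vr=RETURN_DRIFT_DEG_S * sv,
        )
        waves.append(wave)
        fixes.append(rf)
    i_end = i0 + max(w.size for w in waves)
    if limit_index is not None and i_end > limit_index:
        return None
    for angle, wave in zip((left_deg, right_deg), waves):
        hi = min(i0 + wave.size, angle.size)
        angle[i0:hi] += sign * wave[: hi - i0]
    return i_end, float(np.mean(fixes))


def synth_behavior(
    schedule: StateSchedule,
    kinematics_per_state: dict | None = None,
    fs_hz: float = 50.0,
    noise_sd_rad: float = 0.01,
    seed: int = 0,
) -> BehaviorSynthesis:
    """Synthesize eye-angle and speed traces following a state schedule.

    Within each quiescent segment, conjugate saccades follow that state's
    kinematics; wake segments carry swim bouts (~1 s interbout) with
    bout-coupled saccades and heading turns; quiescent locomotor speed stays
    below 0.5 mm/s.  Gaussian angle noise of ``noise_sd_rad`` is added to
    each eye independently.
    """
    if fs_hz < 10:
        raise ValueError("fs_hz must be >= 10")
    kin = dict(presets.KINEMATICS)
    if kinematics_per_state:
        kin.update(kinematics_per_state)
    rng = np.random.default_rng(seed)
    n = int(round(schedule.duration_s * fs_hz))
    left_deg = np.zeros(n)
    right_deg = np.zeros(n)
    speed = np.abs(rng.normal(0.0, 0.08, n))
    heading = np.zeros(n)
    sacc_rows = []
    bout_rows = []
    turn_bias_state = 0.0
    for seg_start, seg_end, state in schedule.segments:
        i_lo = int(round(seg_start * fs_hz))
        i_hi = min(int(round(seg_end * fs_hz)), n)
        if state == "Wake":
            # swim bouts: ~1 s interbout, 0.4 s bouts, speed bursts
            t = seg_start + float(rng.uniform(0.1, 0.5))
            while t < seg_end - 0.5:
                dur = 0.4
                pk = float(rng.uniform(5.0, 30.0))
                j0 = int(round(t * fs_hz))
                j1 = min(int(round((t + dur) * fs_hz)), i_hi)
                m = j1 - j0
                if m > 1:
                    prof = pk * np.sin(np.pi * (np.arange(m) + 0.5) / m)
                    speed[j0:j1] = np.maximum(speed[j0:j1], prof)
                # sustained turn bias: AR(1) over bouts
                turn_bias_state = 0.97 * turn_bias_state + rng.normal(0, 0.08)
                dhead = turn_bias_state + rng.normal(0, 0.05)
                heading[j0:] += dhead
                bout_rows.append({"t_s": t, "peak_mm_s": pk, "dheading_rad": dhead})
                if rng.random() < 0.25:
                    sgn = -1.0 if rng.random() < 0.5 else 1.0
                    amp = _sym_trunc_normal(rng, 20.0, 5.0)
                    vpk = _sym_trunc_normal(rng, 700.0, 150.0)
                    res = _inject_saccade(
                        left_deg, right_deg, j0, fs_hz, amp, vpk, 8.0,
                        float(_lognormal(rng, 1.2, 0.5)), rng, sgn,
                        limit_index=i_hi,
                    )
                    if res is not None:
                        sacc_rows.append({
                            "onset_s": j0 / fs_hz, "state": "Wake",
                            "direction": sgn, "amplitude_deg": amp,
                            "peak_speed_deg_s": vpk,
                            "decay_slope_deg_s": 8.0, "fixation_s": res[1],
                        })
                t += dur + 0.15 + float(rng.exponential(0.5))
            continue
        k = kin[state]
        if k.rate_per_min <= 0:
            continue
        mean_isi = 60.0 / k.rate_per_min
        gap0 = max(mean_isi - _mean_event_span_s(k, fs_hz), 0.3)

        def draw_gap() -> float:
            u = (1.0 - k.regularity) * float(rng.exponential(1.0)) + k.regularity
            return gap0 * u

        t = seg_start + 1.0 + draw_gap()
        while True:
            amp = _sym_trunc_normal(rng, *k.amplitude_deg)
            vpk = _sym_trunc_normal(rng, *k.peak_speed_deg_s)
            slope = float(_lognormal(rng, *k.decay_slope_deg_s))
            # fixations below ~2 s are unresolvable once the 1.5 s running
            # median has absorbed the plateau
            fix = max(float(_lognormal(rng, *k.fixation_s)), 2.0)
            sgn = -1.0 if rng.random() < 0.5 else 1.0
            i0 = int(round(t * fs_hz))
            res = _inject_saccade(
                left_deg, right_deg, i0, fs_hz, amp, vpk, slope, fix,
                rng, sgn, limit_index=min(i_hi, n) - int(0.3 * fs_hz),
            )
            if res is None:
                break
            i_end, rf = res
            sacc_rows.append({
                "onset_s": i0 / fs_hz, "state": state, "direction": sgn,
                "amplitude_deg": amp, "peak_speed_deg_s": vpk,
                "decay_slope_deg_s": slope, "fixation_s": rf,
            })
            # leave >= 1 s of baseline so the running median can
            # return between consecutive plateaus
            t = i_end / fs_hz + max(draw_gap(), 1.0)
    left = left_deg / DEG + rng.normal(0.0, noise_sd_rad, n)
    right = right_deg / DEG + rng.normal(0.0, noise_sd_rad, n)
    roll = rng.normal(0.0, 0.05, n)
    pitch = rng.normal(0.0, 0.05, n)
    log = BehaviorLog(
        saccades=pd.DataFrame(
            sacc_rows, columns=["onset_s", "state", "direction", "amplitude_deg",
                                "peak_speed_deg_s", "decay_slope_deg_s",
                                "fixation_s"]
        ),
        bouts=pd.DataFrame(bout_rows, columns=["t_s", "peak_mm_s", "dheading_rad"]),
        schedule=schedule,
    )
    return BehaviorSynthesis(
        trace=EyeAngleTrace(left, right, fs_hz),
        speed=SpeedTrace(speed, fs_hz),
        heading_rad=heading, roll_rad=roll, pitch_rad=pitch, log=log,
    )


# ---------------------------------------------------------------------------
# head-ROI image rendering
# ---------------------------------------------------------------------------

def render_head_frames(
    left_angle_rad: np.ndarray,
    right_angle_rad: np.ndarray,
    px_per_mm: float = 20.0,
    seed: int = 0,
    roi_mm: float = 0.9,
    noise_sd: float = 0.015,
) -> tuple[np.ndarray, dict]:
    """Render frames with two dark elliptical eyes at commanded orientations.

    The head ROI is ``roi_mm`` square, body axis along image rows (anterior
    at row 0); an eye angle of 0 aligns the major axis with the body axis,
    positive angles rotate counter-clockwise in the egocentric view.
    Returns (stack [n, H, W] float32 in [0, 1], sidecar dict with the
    commanded ground truth).
    """
    left_angle_rad = np.atleast_1d(np.asarray(left_angle_rad, dtype=float))
    right_angle_rad = np.atleast_1d(np.asarray(right_angle_rad, dtype=float))
    if left_angle_rad.size == 0 or left_angle_rad.shape != right_angle_rad.shape:
        raise ValueError("angle series must be non-empty and equal length")
    rng = np.random.default_rng(seed)
    size = int(round(roi_mm * px_per_mm))
    mid = (size - 1) / 2.0          # pixel-grid center, so mirroring is exact
    cy = 0.38 * size
    cx_l = mid - 0.18 * px_per_mm
    cx_r = mid + 0.18 * px_per_mm
    a_px = 0.10 * px_per_mm   # semi-major (mm -> px), fits the 0.3 mm mask
    b_px = 0.05 * px_per_mm
    edge = 1.0 / b_px         # ~1 px soft skirt (sub-pixel orientation cue)
    ii, jj = np.mgrid[0:size, 0:size].astype(float)
    frames = np.empty((left_angle_rad.size, size, size), dtype=np.float32)
    for f, (al, ar) in enumerate(zip(left_angle_rad, right_angle_rad)):
        img = 0.75 + rng.normal(0.0, noise_sd, (size, size))
        for cx, th in ((cx_l, al), (cx_r, ar)):
            dx = jj - cx
            dy = ii - cy
            # major axis along body (rows) at angle 0; positive = CCW in view
            u = dx * np.sin(th) + dy * np.cos(th)
            w = dx * np.cos(th) - dy * np.sin(th)
            r = np.sqrt((u / a_px) ** 2 + (w / b_px) ** 2)
            # smooth darkening toward the eye center (sub-pixel orientation)
            depth = 0.5 * np.clip((1.0 + edge - r) / edge, 0.0, 1.0)
            img -= depth
        frames[f] = np.clip(img, 0.0, 1.0)
    sidecar = {
        "angles_left_rad": left_angle_rad.tolist(),
        "angles_right_rad": right_angle_rad.tolist(),
        "px_per_mm": px_per_mm,
        "centers_px": {"left": [cx_l, cy], "right": [cx_r, cy]},
        "axes_px": [a_px, b_px],
    }
    return frames, sidecar


# ---------------------------------------------------------------------------
# neural data
# ---------------------------------------------------------------------------

REGION_POOL = (
    "dorsal_raphe", "inferior_raphe", "hindbrain", "tectum",
    "telencephalon", "cerebellum", "habenula", "other",
)


@dataclass
class SyntheticNeuralSpec:
    """Composition of a synthetic neural population."""

    n_suppressed: int = 0
    n_ramp_down: int = 0
    n_ramp_up: int = 0
    n_event_cells: int = 0
    n_noise: int = 0
    tau: float = 0.91               # relative-time constant of ramp cells
    noise_sd: float = 0.05
    bleach_amp: float = 0.0
    bleach_tau_s: float = 3000.0
    missing_fraction: float = 0.0
    event_rate_hz: float = 0.01
    amp: float = 0.5
    base: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_suppressed, self.n_ramp_down, self.n_ramp_up,
                  self.n_event_cells, self.n_noise)
        if any(c < 0 for c in counts):
            raise ValueError("neuron counts must be >= 0")
        if sum(counts) == 0:
            raise ValueError("at least one neuron class must be non-empty")
        if not 0.0 <= self.missing_fraction <= 0.5:
            raise ValueError("missing_fraction must lie in [0, 0.5]")


@dataclass
class NeuralLog:
    classes: np.ndarray
    taus: np.ndarray
    event_onsets: list
    bleach: tuple


def synth_neural(
    spec: SyntheticNeuralSpec,
    schedule: StateSchedule,
    fs_hz: float = 2.0,
) -> tuple[NeuronMatrix, NeuralLog]:
    """Neural population with QEM-1-locked dynamics per the class spec.

    Ramp-down cells follow exp(-t~/tau) of relative time t~ within each
    QEM-1 period, ramp-up cells 1 - exp(-t~/tau); suppressed cells drop
    their mean in QEM-1; event cells emit boxcar transients; a multiplicative
    bleach and a random missing-sample mask are applied last.
    """
    qem1 = [(a, b) for a, b in schedule.periods_of("QEM1") if b - a >= 180.0]
    if len(qem1) < 2:
        raise ValueError("schedule must contain >= 2 QEM-1 periods of >= 3 min")
    rng = np.random.default_rng(spec.seed)
    T = int(round(schedule.duration_s * fs_hz))
    t = np.arange(T) / fs_hz
    classes = (
        ["suppressed"] * spec.n_suppressed + ["ramp_down"] * spec.n_ramp_down
        + ["ramp_up"] * spec.n_ramp_up + ["event"] * spec.n_event_cells
        + ["noise"] * spec.n_noise
    )
    n = len(classes)
    F = np.full((n, T), spec.base)
    taus = np.full(n, np.nan)
    in_qem1 = np.zeros(T, dtype=bool)
    rel_time = np.zeros(T)
    for a, b in qem1:
        i0, i1 = int(round(a * fs_hz)), int(round(b * fs_hz))
        in_qem1[i0:i1] = True
        rel_time[i0:i1] = (t[i0:i1] - a) / (b - a)
    event_onsets: list = []
    for i, cls in enumerate(classes):
        if cls == "suppressed":
            F[i, ~in_qem1] += spec.amp
        elif cls == "ramp_down":
            tau = max(rng.normal(spec.tau, 0.03), 0.05)
            taus[i] = tau
            F[i, in_qem1] += spec.amp * np.exp(-rel_time[in_qem1] / tau)
        elif cls == "ramp_up":
            tau = max(rng.normal(spec.tau, 0.03), 0.05)
            taus[i] = tau
            F[i, in_qem1] += spec.amp * (1.0 - np.exp(-rel_time[in_qem1] / tau))
        elif cls == "event":
            n_ev = rng.poisson(spec.event_rate_hz * schedule.duration_s)
            ons = np.sort(rng.uniform(0, schedule.duration_s - 4.0, n_ev))
            # enforce generator-side separation so ground truth is unambiguous
            ons = ons[np.concatenate(([True], np.diff(ons) > 12.0))]
            for o in ons:
                j0 = int(round(o * fs_hz))
                j1 = min(j0 + int(round(3.0 * fs_hz)), T)
                F[i, j0:j1] += spec.amp * 4.0
            event_onsets.append((i, ons))
    F += rng.normal(0.0, spec.noise_sd, (n, T))
    if spec.bleach_amp > 0:
        F *= 1.0 + spec.bleach_amp * np.exp(-t / spec.bleach_tau_s)
    mask = rng.random((n, T)) >= spec.missing_fraction
    F = np.where(mask, F, np.nan)
    centroids = rng.uniform((0, 0, 0), (500, 1000, 250), (n, 3))
    regions = np.array([
        "dorsal_raphe" if classes[i] == "ramp_down" and rng.random() < 0.6
        else REGION_POOL[rng.integers(len(REGION_POOL))]
        for i in range(n)
    ], dtype=object)
    mat = NeuronMatrix(
        F=F, mask=mask, fs_hz=fs_hz, centroids_um=centroids, regions=regions,
        meta={"classes": list(classes)},
    )
    log = NeuralLog(
        classes=np.array(classes, dtype=object), taus=taus,
        event_onsets=event_onsets, bleach=(spec.bleach_amp, spec.bleach_tau_s),
    )
    return mat, log
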