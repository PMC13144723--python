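"""State-restricted population dynamics: PCA, entanglement, time decoding.

QEM-1 population activity evolves along a stereotyped low-dimensional
trajectory.  Three analyses quantify this:

* state PCA — each state period is reduced to a neuron x 10 decile matrix,
  averaged across periods; the top two principal components of that mean
  matrix define a 2-D plane onto which the full experiment is projected;
* entanglement — the number of times the smoothed 2-D trajectory of one
  period crosses itself, normalized by duration (organized ramps barely
  cross; wake meanders cross often);
* relative-time decoding — an elastic-net readout of normalized position
  (0 -> 1) within a state period from population activity, evaluated by
  leave-one-period-out cross-validation with a cross-fish gain correction,
  against circular-shift and behavior-only controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import ElasticNet

from sleepscope.states import StateLabelSeries


def zscore_rows(F: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Row-wise z-score, optionally restricted to ``mask`` columns."""
    F = np.asarray(F, dtype=float)
    cols = slice(None) if mask is None else mask
    mu = F[:, cols].mean(axis=1, keepdims=True)
    sd = F[:, cols].std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (F - mu) / sd


@dataclass
class StatePCA:
    state: str
    mean_matrix: np.ndarray          # neurons x 10
    loadings: np.ndarray             # neurons x 2, orthonormal
    projection: np.ndarray           # T x 2 full-experiment trajectory
    explained_variance_ratio: np.ndarray
    n_periods: int


def state_pca(
    F: np.ndarray,
    series: StateLabelSeries,
    state: str,
    fs_hz: float,
    n_deciles: int = 10,
) -> StatePCA:
    """PCA of the decile-averaged mean activity of one state.

    ``F`` must be interpolated and z-scored (neurons x time).  Periods with
    fewer than ``n_deciles`` samples are skipped with a warning.  The sign
    convention fixes each loading so the projection correlates positively
    with within-period time.
    """
    periods = series.periods_of(state)
    mats = []
    for a, b in periods:
        i0, i1 = int(round(a * fs_hz)), int(round(b * fs_hz))
        if i1 - i0 < n_deciles:
            warnings.warn(f"{state} period at {a:.0f}s too short; skipped")
            continue
        idx = np.array_split(np.arange(i0, i1), n_deciles)
        mats.append(np.column_stack([F[:, j].mean(axis=1) for j in idx]))
    if not mats:
        raise ValueError(f"no usable {state} periods")
    M = np.mean(mats, axis=0)                      # neurons x 10
    Mc = M - M.mean(axis=1, keepdims=True)
    # PCA over the 10 decile observations
    U, S, Vt = np.linalg.svd(Mc, full_matrices=False)
    loadings = U[:, :2]
    evr = S**2 / np.sum(S**2)
    # fix signs: scores increase with decile time
    scores = loadings.T @ Mc
    tgrid = np.arange(n_deciles)
    for k in range(2):
        if np.corrcoef(scores[k], tgrid)[0, 1] < 0:
            loadings[:, k] *= -1.0
    proj = F.T @ loadings
    return StatePCA(state, M, loadings, proj, evr[:2], len(mats))


@dataclass
class Entanglement:
    crossings: int
    duration_s: float
    normalized: float       # crossings per second
    flagged: bool = False


def _cross2(u, v):
    """z-component of the 2-D cross product (supports broadcasting)."""
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def _segments_cross(p: np.ndarray, q: np.ndarray, r: np.ndarray,
                    s: np.ndarray) -> bool:
    """Proper intersection test for segments pq and rs (shared endpoints
    excluded by the caller)."""
    d1 = _cross2(q - p, r - p)
    d2 = _cross2(q - p, s - p)
    d3 = _cross2(s - r, p - r)
    d4 = _cross2(s - r, q - r)
    return bool((d1 * d2 < 0) and (d3 * d4 < 0))


def count_self_crossings(traj: np.ndarray) -> int:
    """Number of unordered pairs of polyline segments that cross.

    Pairs sharing an endpoint (adjacent segments) never count.  Each
    unordered pair is examined once, which matches halving a double-counted
    enumeration.
    """
    P = np.asarray(traj, dtype=float)
    n_seg = P.shape[0] - 1
    if n_seg < 3:
        return 0
    a = P[:-1]
    b = P[1:]
    count = 0
    for i in range(n_seg - 2):
        # vectorized orientation tests against all later non-adjacent segments
        j = np.arange(i + 2, n_seg)
        p, q = a[i], b[i]
        r, s = a[j], b[j]
        d1 = _cross2(q - p, r - p)
        d2 = _cross2(q - p, s - p)
        d3 = _cross2(s - r, p - r)
        d4 = _cross2(s - r, q - r)
        count += int(np.sum((d1 * d2 < 0) & (d3 * d4 < 0)))
    return count


def entanglement(
    projection: np.ndarray,
    period: tuple,
    fs_hz: float,
    sigma_s: float = 12.5,
) -> Entanglement:
    """Self-crossing rate of one period's smoothed 2-D trajectory.

    The projected trajectory within ``period`` is smoothed with a Gaussian
    kernel (sigma in seconds), treated as a polyline of N-1 segments, and
    scored by its unique self-crossing count divided by the period duration.
    Invariant to rigid rotation of the plane.
    """
    a, b = period
    i0, i1 = int(round(a * fs_hz)), int(round(b * fs_hz))
    traj = np.asarray(projection, dtype=float)[i0:i1]
    if traj.shape[0] < 3:
        return Entanglement(0, b - a, np.nan, flagged=True)
    if sigma_s * fs_hz > 0:
        sm = gaussian_filter1d(traj, sigma_s * fs_hz, axis=0, mode="nearest")
    else:
        sm = traj
    c = count_self_crossings(sm)
    dur = b - a
    return Entanglement(c, dur, c / dur)


def shuffle_control(
    F: np.ndarray,
    series: StateLabelSeries,
    state: str,
    fs_hz: float,
    seed: int = 0,
) -> np.ndarray:
    """Circularly shift each neuron's activity within each state period.

    Shift offsets are independent per neuron and period and uniform over
    the full period (zero excluded), preserving local autocorrelation while
    destroying cross-neuron temporal alignment.  The distribution must be
    uniform on the whole circle: excluding a band of small shifts leaves the
    ensemble mean of shifted traces time-dependent, which a linear decoder
    can exploit across periods.
    """
    rng = np.random.default_rng(seed)
    out = np.array(F, dtype=float, copy=True)
    for a, b in series.periods_of(state):
        i0, i1 = int(round(a * fs_hz)), int(round(b * fs_hz))
        L = i1 - i0
        if L < 2:
            continue
        shifts = rng.integers(1, L, size=F.shape[0])
        for i in range(F.shape[0]):
            out[i, i0:i1] = np.roll(F[i, i0:i1], int(shifts[i]))
    return out


@dataclass
class DecoderResult:
    r2: float                       # pooled held-out R^2 vs the true ramp
    predictions: list               # per period: gain-corrected predictions
    truths: list                    # per period: linear 0->1 ramp
    median_weights: np.ndarray      # per neuron, median over period fits
    gain: float
    n_periods: int
    hyperparams: dict = field(default_factory=dict)


def _period_bins(F, a, b, fs_hz, n_bins=100):
    i0, i1 = int(round(a * fs_hz)), int(round(b * fs_hz))
    idx = np.array_split(np.arange(i0, i1), n_bins)
    return np.column_stack([F[:, j].mean(axis=1) for j in idx])


def decode_relative_time(
    F: np.ndarray,
    series: StateLabelSeries,
    state: str,
    fs_hz: float,
    seed: int = 0,
    n_bins: int = 100,
    min_duration_s: float = 180.0,
    l1_ratios: tuple = (0.1, 0.5, 0.9),
    alphas: tuple = (1e-4, 1e-3, 1e-2, 1e-1, 1.0),
) -> DecoderResult:
    """Leave-one-period-out elastic-net decoding of relative time.

    Activity is z-scored within the state, each eligible period (>= 3 min)
    is averaged into ``n_bins`` relative-time bins, and an elastic net is
    trained on all periods but one to predict the 0 -> 1 ramp on the
    held-out period.  Hyperparameters are chosen by an inner
    leave-one-training-period-out search.  A scalar gain correction is fit
    on all periods but one and applied to the held-out period (single-fish
    analogue of the cross-fish gain stage).
    """
    if not l1_ratios or not alphas:
        raise ValueError("hyperparameter grid is empty")
    periods = [p for p in series.periods_of(state)
               if p[1] - p[0] >= min_duration_s]
    if len(periods) < 2:
        raise ValueError("need >= 2 eligible periods")
    state_mask = np.zeros(F.shape[1], dtype=bool)
    for a, b in periods:
        state_mask[int(round(a * fs_hz)):int(round(b * fs_hz))] = True
    Z = zscore_rows(F, state_mask)
    X_periods = [_period_bins(Z, a, b, fs_hz, n_bins).T for a, b in periods]
    y = np.linspace(0.0, 1.0, n_bins)

    def _fit(train_idx, l1, alpha):
        Xtr = np.vstack([X_periods[i] for i in train_idx])
        ytr = np.tile(y, len(train_idx))
        net = ElasticNet(alpha=alpha, l1_ratio=l1, max_iter=5000,
                         random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit(Xtr, ytr)
        return net

    # inner hyperparameter search on the first training split
    n_p = len(periods)
    best, best_score = None, -np.inf
    inner = list(range(n_p - 1))
    if len(inner) >= 2:
        for l1 in l1_ratios:
            for alpha in alphas:
                scores = []
                for k in inner:
                    net = _fit([i for i in inner if i != k], l1, alpha)
                    pred = net.predict(X_periods[k])
                    scores.append(1.0 - np.sum((pred - y) ** 2)
                                  / np.sum((y - y.mean()) ** 2))
                sc = float(np.mean(scores))
                if sc > best_score:
                    best, best_score = (l1, alpha), sc
    else:
        best = (l1_ratios[len(l1_ratios) // 2], alphas[len(alphas) // 2])
    l1, alpha = best

    preds, weights = [], []
    for k in range(n_p):
        net = _fit([i for i in range(n_p) if i != k], l1, alpha)
        preds.append(net.predict(X_periods[k]))
        weights.append(net.coef_)
    # gain correction: fit on all periods but one, apply to the held-out one
    corrected = []
    for k in range(n_p):
        others = np.concatenate([preds[i] for i in range(n_p) if i != k])
        target = np.tile(y, n_p - 1)
        g = float(others @ target / (others @ others)) if np.any(others) else 1.0
        corrected.append(g * preds[k])
    all_pred = np.concatenate(corrected)
    all_true = np.tile(y, n_p)
    r2 = float(1.0 - np.sum((all_pred - all_true) ** 2)
               / np.sum((all_true - all_true.mean()) ** 2))
    gain_all = float(np.concatenate(preds) @ all_true
                     / max(np.concatenate(preds) @ np.concatenate(preds), 1e-12))
    return DecoderResult(
        r2=r2, predictions=corrected, truths=[y] * n_p,
        median_weights=np.median(np.array(weights), axis=0), gain=gain_all,
        n_periods=n_p, hyperparams={"l1_ratio": l1, "alpha": alpha},
    )
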