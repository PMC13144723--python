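"""Per-neuron encoding models, ramp classification and anatomical enrichment.

Each neuron's activity is regressed on nine time series — six behavioral
(speed, roll, pitch, left/right eye angle, turn bias) and three QEM-1 state
regressors (binary indicator, its within-period integral, and an onset
impulse convolved with an exponential kernel whose time constant is 1/15 of
the period duration) — with 10-fold blocked cross-validation.  Partial
models time-shuffle a regressor group (eyes, turn bias, or the QEM-1
triple), preserving the parameter count; a group is a significant
contributor when the drop in mean held-out R^2 exceeds twice the standard
error of R^2 across folds.

Positively modulated QEM-1 neurons are classified as ramp-up or ramp-down by
competing exponential fits over relative time within QEM-1 periods, and the
anatomical distribution of encoding neurons is scored by fold-enrichment
against a resampled null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares

from sleepscope.states import StateLabelSeries

REGRESSOR_NAMES = (
    "speed", "roll", "pitch", "left_eye", "right_eye", "turn_bias",
    "qem1_indicator", "qem1_integral", "qem1_onset",
)
GROUPS = {
    "eyes": [3, 4],
    "turn_bias": [5],
    "qem1": [6, 7, 8],
}


def turn_bias(heading_rad: np.ndarray, fs_hz: float,
              sigma_s: float = 480.0) -> np.ndarray:
    """Gaussian-smoothed heading change (sigma = 8 min).

    The result stays stably positive or negative over multiple minutes,
    capturing sustained turn-direction bias.  Heading must be unwrapped.
    """
    dh = np.diff(np.asarray(heading_rad, dtype=float), prepend=heading_rad[0])
    return gaussian_filter1d(dh, sigma_s * fs_hz, mode="nearest")


def build_qem1_regressors(
    series: StateLabelSeries, n_samples: int, fs_hz: float,
    kernel_fraction: float = 1.0 / 15.0,
) -> np.ndarray:
    """QEM-1 indicator, within-period integral, and onset-kernel series.

    The integral (in seconds) resets at each period start and is zero
    outside periods; the onset regressor is exp(-(t - t0)/tau) within each
    period with tau = ``kernel_fraction`` times that period's duration.
    """
    t = np.arange(n_samples) / fs_hz
    ind = np.zeros(n_samples)
    integ = np.zeros(n_samples)
    onset = np.zeros(n_samples)
    for a, b in series.periods_of("QEM1"):
        m = (t >= a) & (t < b)
        ind[m] = 1.0
        integ[m] = t[m] - a
        tau = max((b - a) * kernel_fraction, 1.0 / fs_hz)
        onset[m] = np.exp(-(t[m] - a) / tau)
    return np.vstack([ind, integ, onset])


def build_regressors(
    speed: np.ndarray, roll: np.ndarray, pitch: np.ndarray,
    left_eye: np.ndarray, right_eye: np.ndarray, heading: np.ndarray,
    series: StateLabelSeries, fs_hz: float,
) -> np.ndarray:
    """Assemble the 9 x T regressor matrix on the neural time base."""
    n = speed.size
    tb = turn_bias(heading, fs_hz)
    qem1 = build_qem1_regressors(series, n, fs_hz)
    return np.vstack([speed, roll, pitch, left_eye, right_eye, tb, qem1])


@dataclass
class EncodingResult:
    beta: np.ndarray
    beta0: float
    r2_full: float                 # R^2 of the concatenated CV prediction
    r2_folds: np.ndarray           # per-fold held-out R^2
    partial_r2: dict               # group -> mean held-out R^2 (shuffled)
    significant: dict              # group -> bool
    ridge_fallback: bool = False


def _blocked_folds(n: int, k: int):
    edges = np.linspace(0, n, k + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(k)]


def _cv_r2(y: np.ndarray, X: np.ndarray, folds, ridge: float = 0.0):
    """Per-fold held-out R^2 and the concatenated prediction."""
    n = y.size
    pred = np.empty(n)
    r2s = []
    d = X.shape[0]
    for a, b in folds:
        tr = np.ones(n, dtype=bool)
        tr[a:b] = False
        Xa = np.vstack([X[:, tr], np.ones(tr.sum())])
        if ridge > 0:
            G = Xa @ Xa.T + ridge * np.eye(d + 1)
            coef = np.linalg.solve(G, Xa @ y[tr])
        else:
            coef = np.linalg.lstsq(Xa.T, y[tr], rcond=None)[0]
        yh = np.vstack([X[:, a:b], np.ones(b - a)]).T @ coef
        pred[a:b] = yh
        sst = np.sum((y[a:b] - y[a:b].mean()) ** 2)
        sse = np.sum((y[a:b] - yh) ** 2)
        r2s.append(1.0 - sse / sst if sst > 0 else np.nan)
    sst = np.sum((y - y.mean()) ** 2)
    r2_all = 1.0 - np.sum((y - pred) ** 2) / sst if sst > 0 else np.nan
    return np.array(r2s), r2_all


def fit_encoding(
    y: np.ndarray,
    X: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    min_samples: int = 1000,
) -> EncodingResult:
    """Cross-validated multivariate regression with shuffle-based partials.

    ``X`` is the 9 x T regressor matrix, ``y`` one neuron's (interpolated)
    trace.  Folds are contiguous time blocks.  For each group in
    {eyes, turn bias, qem1}, a partial model with that group's rows randomly
    permuted in time (identical folds) measures the group's contribution;
    the flag fires when the mean R^2 drop exceeds twice the SE of the full
    model's per-fold R^2.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.size < min_samples:
        raise ValueError(f"need >= {min_samples} co-observed samples")
    rng = np.random.default_rng(seed)
    folds = _blocked_folds(y.size, n_folds)
    ridge = 0.0
    ridge_fallback = False
    if np.linalg.matrix_rank(X @ X.T) < X.shape[0]:
        ridge = 1e-6
        ridge_fallback = True
    r2s, r2_all = _cv_r2(y, X, folds, ridge)
    se = float(np.nanstd(r2s, ddof=1) / np.sqrt(len(r2s)))
    partial, flags = {}, {}
    for name, rows in GROUPS.items():
        Xs = X.copy()
        perm = rng.permutation(X.shape[1])
        Xs[rows] = Xs[rows][:, perm]
        r2p, _ = _cv_r2(y, Xs, folds, ridge)
        partial[name] = float(np.nanmean(r2p))
        flags[name] = bool(np.nanmean(r2s) - np.nanmean(r2p) > 2.0 * se)
    Xa = np.vstack([X, np.ones(X.shape[1])])
    G = Xa @ Xa.T + (ridge if ridge else 0.0) * np.eye(X.shape[0] + 1)
    coef = np.linalg.solve(G, Xa @ y) if ridge else np.linalg.lstsq(Xa.T, y, rcond=None)[0]
    return EncodingResult(
        beta=coef[:-1], beta0=float(coef[-1]), r2_full=float(r2_all),
        r2_folds=r2s, partial_r2=partial, significant=flags,
        ridge_fallback=ridge_fallback,
    )


@dataclass
class RampFit:
    model: str                # "decay" or "one_minus_exp"
    a: float
    b: float
    c: float
    r2: float
    delta_r2: float           # R^2(decay) - R^2(ramp-up)
    n_periods: int
    flagged: bool = False


def _resample_periods(
    y: np.ndarray, periods, fs_hz: float, n_points: int = 1000,
    min_duration_s: float = 180.0,
):
    rows = []
    for a, b in periods:
        if b - a < min_duration_s:
            continue
        i0, i1 = int(round(a * fs_hz)), int(round(b * fs_hz))
        seg = y[i0:i1]
        if seg.size < 10:
            continue
        src = np.linspace(0.0, 1.0, seg.size)
        rows.append(np.interp(np.linspace(0.0, 1.0, n_points), src, seg))
    return np.array(rows)


def _exp_model(t, a, b, c, kind, literal):
    if literal:
        # exponent read literally as -1/(b t)
        with np.errstate(divide="ignore", over="ignore"):
            e = np.exp(-1.0 / (b * np.maximum(t, 1e-9)))
    else:
        e = np.exp(-t / b)
    return a * e + c if kind == "decay" else a * (1.0 - e) + c


def fit_ramps(
    y: np.ndarray,
    qem1_periods,
    fs_hz: float,
    literal_exponent: bool = False,
    n_points: int = 1000,
) -> RampFit:
    """Classify a neuron as ramp-down (decay) or ramp-up over relative time.

    Activity in each QEM-1 period (>= 3 min) is resampled to ``n_points``
    along relative time, averaged across periods, min-max normalized to
    [0, 1], and fit with a * exp(-t/b) + c and a * (1 - exp(-t/b)) + c under
    0 < a <= 2, 0 < b <= 2000.  The better R^2 decides the class.

    The amplitude bound must exceed 1: a min-max normalized exponential has
    a = 1 / (1 - exp(-1/b)) > 1 exactly, so a unit bound would forbid the
    true model and bias b downward.
    """
    mat = _resample_periods(np.asarray(y, dtype=float), qem1_periods, fs_hz,
                            n_points)
    if mat.shape[0] < 1:
        return RampFit("undefined", np.nan, np.nan, np.nan, np.nan, np.nan,
                       0, flagged=True)
    m = mat.mean(axis=0)
    span = m.max() - m.min()
    if span <= 0:
        return RampFit("undefined", np.nan, np.nan, np.nan, np.nan, np.nan,
                       mat.shape[0], flagged=True)
    m = (m - m.min()) / span
    t = np.linspace(0.0, 1.0, n_points)
    sst = np.sum((m - m.mean()) ** 2)
    fits = {}
    for kind in ("decay", "one_minus_exp"):
        best = None
        for b0 in (0.1, 0.5, 1.0, 5.0, 50.0):
            try:
                res = least_squares(
                    lambda p: _exp_model(t, *p, kind, literal_exponent) - m,
                    x0=[0.8, b0, 0.1],
                    bounds=([1e-6, 1e-6, -np.inf], [2.0, 2000.0, np.inf]),
                    max_nfev=2000,
                )
            except Exception:
                continue
            sse = float(np.sum(res.fun**2))
            if best is None or sse < best[0]:
                best = (sse, res.x)
        sse, p = best
        fits[kind] = (1.0 - sse / sst if sst > 0 else np.nan, p)
    r2d, r2u = fits["decay"][0], fits["one_minus_exp"][0]
    kind = "decay" if r2d >= r2u else "one_minus_exp"
    a, b, c = fits[kind][1]
    return RampFit(kind, float(a), float(b), float(c),
                   float(max(r2d, r2u)), float(r2d - r2u), mat.shape[0])


@dataclass
class EnrichmentResult:
    region: str
    n_pos: int
    n_tot: int
    p_region: float
    e_fold: float
    n_null_below: int          # null draws with P(X) > P0(X)
    significant: bool
    null_p0: np.ndarray = field(repr=False, default=None)


def enrichment(
    positive: np.ndarray,
    regions: np.ndarray,
    seed: int = 0,
    n_draws: int = 100,
    sig_fraction: float = 0.95,
) -> list[EnrichmentResult]:
    """Per-region fold-enrichment of positive neurons vs a resampled null.

    For region X: P(X) = n_pos/n_tot within the region; each null draw
    samples n_tot(X) neurons without replacement from the whole population
    and computes P0(X) the same way; E(X) = P(X) / mean(P0).  The region is
    significant (per fish) when P(X) > P0(X) in at least ``sig_fraction`` of
    the draws.  Regions with no neurons are skipped.
    """
    positive = np.asarray(positive, dtype=bool)
    regions = np.asarray(regions, dtype=object)
    rng = np.random.default_rng(seed)
    n = positive.size
    out = []
    for region in pd.unique(regions):
        m = regions == region
        n_tot = int(m.sum())
        if n_tot == 0:
            continue
        n_pos = int(positive[m].sum())
        p_region = n_pos / n_tot
        p0 = np.empty(n_draws)
        for d in range(n_draws):
            idx = rng.choice(n, size=n_tot, replace=False)
            p0[d] = positive[idx].sum() / n_tot
        mean_p0 = p0.mean()
        e = p_region / mean_p0 if mean_p0 > 0 else np.inf
        wins = int(np.sum(p_region > p0))
        out.append(EnrichmentResult(
            region=str(region), n_pos=n_pos, n_tot=n_tot,
            p_region=p_region, e_fold=float(e), n_null_below=wins,
            significant=wins >= sig_fraction * n_draws, null_p0=p0,
        ))
    return out


def across_fish_verdict(per_fish_significant: dict, fraction: float = 0.7):
    """Region-level verdict: significant in >= ceil(fraction * n_fish) fish."""
    regions = set()
    for d in per_fish_significant.values():
        regions.update(d)
    n_fish = len(per_fish_significant)
    need = int(np.ceil(fraction * n_fish))
    return {
        r: sum(d.get(r, False) for d in per_fish_significant.values()) >= need
        for r in regions
    }


def enrichment_to_dataframe(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"region": r.region, "n_pos": r.n_pos, "n_tot": r.n_tot,
         "P": r.p_region, "E": r.e_fold, "significant": r.significant}
        for r in results
    ])
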