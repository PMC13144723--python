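"""Sleep-period detection and sleep-substate classification.

Sleep is locomotor quiescence: rolling speed (5 s window) below 0.5 mm/s
for at least one minute.  Each sleep period is divided into 1-min bins
(terminal remainders <= 30 s merge into the preceding bin; longer remainders
stand alone).  Bins without saccades are QNEM; bins with saccades are
classified into QEM-1/2/3 by a 3-component diagonal Gaussian mixture over
(saccade count, mean decay slope, mean fixation duration), with the number
of components supported by the sample-size adjusted BIC (SABIC).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from sklearn.mixture import GaussianMixture

from sleepscope import presets
from sleepscope.saccades import SaccadeEvent

FEATURE_NAMES = ("saccade_count", "mean_decay_slope_deg_s", "mean_fixation_s")
QEM_STATES = ("QEM1", "QEM2", "QEM3")


@dataclass
class SpeedTrace:
    """Locomotor speed (mm/s) on a uniform grid."""

    speed_mm_s: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.speed_mm_s = np.asarray(self.speed_mm_s, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")

    @property
    def n(self) -> int:
        return self.speed_mm_s.size


@dataclass
class SleepPeriod:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Bin:
    start_s: float
    end_s: float


@dataclass
class BinFeatures:
    """Per-bin saccade features; kinematic means are NaN when count == 0."""

    saccade_count: int
    mean_decay_slope_deg_s: float
    mean_fixation_s: float


def detect_sleep(
    speed: SpeedTrace,
    threshold_mm_s: float = presets.SLEEP_SPEED_MM_S,
    min_duration_s: float = presets.SLEEP_MIN_S,
    window_s: float = presets.SPEED_WINDOW_S,
) -> list[SleepPeriod]:
    """Maximal runs of rolling-averaged speed below threshold, >= 1 min."""
    fs = speed.fs_hz
    w = max(1, int(round(window_s * fs)))
    rolled = uniform_filter1d(speed.speed_mm_s, size=w, mode="nearest")
    quiet = rolled < threshold_mm_s
    periods: list[SleepPeriod] = []
    edges = np.flatnonzero(np.diff(quiet.astype(np.int8)))
    starts = [0] if quiet[0] else []
    starts += [int(e) + 1 for e in edges if quiet[e + 1]]
    ends = [int(e) + 1 for e in edges if quiet[e]]
    if quiet[-1]:
        ends.append(quiet.size)
    for s, e in zip(starts, ends):
        dur = (e - s) / fs
        if dur >= min_duration_s:
            periods.append(SleepPeriod(start_s=s / fs, end_s=e / fs))
    return periods


def bin_period(period: SleepPeriod, bin_s: float = 60.0) -> list[Bin]:
    """Consecutive 1-min bins; terminal remainder <= 30 s merges into the
    last bin, remainders in (30, 60) s form their own bin."""
    dur = period.duration_s
    n_full = int(dur // bin_s)
    rem = dur - n_full * bin_s
    edges = [period.start_s + i * bin_s for i in range(n_full + 1)]
    if rem > bin_s / 2:
        edges.append(period.end_s)
    else:
        edges[-1] = period.end_s
    return [Bin(a, b) for a, b in zip(edges[:-1], edges[1:])]


def featurize(bin_: Bin, events: list[SaccadeEvent]) -> BinFeatures:
    """Saccade count and kinematic means for one bin (assignment by onset).

    Censored fixations enter the mean at their censored duration.
    """
    inside = [e for e in events if bin_.start_s <= e.onset_s < bin_.end_s
              and e.rejected_reason is None]
    if not inside:
        return BinFeatures(0, np.nan, np.nan)
    slopes = np.array([e.decay_slope_deg_s for e in inside], dtype=float)
    fixes = np.array([e.fixation_s for e in inside], dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mslope = float(np.nanmean(slopes))
        mfix = float(np.nanmean(fixes))
    return BinFeatures(len(inside), mslope, mfix)


def features_matrix(features: list[BinFeatures]) -> np.ndarray:
    return np.array(
        [[f.saccade_count, f.mean_decay_slope_deg_s, f.mean_fixation_s]
         for f in features], dtype=float,
    )


def sabic(gm: GaussianMixture, X: np.ndarray) -> float:
    """Sample-size adjusted BIC: BIC with n replaced by (n + 2) / 24."""
    n, d = X.shape
    k = gm.n_components
    p = k * d + k * d + (k - 1)  # means + diagonal variances + weights
    log_l = gm.score(X) * n
    return float(-2.0 * log_l + p * np.log((n + 2.0) / 24.0))


LOG_EPS = np.array([0.0, 1e-2, 0.0])  # slope can be measured as exactly 0


def _log_features(X: np.ndarray) -> np.ndarray:
    """Log-transform (count, slope, fixation); all three are positive and
    right-skewed, and the substates separate far better on log scales."""
    return np.log(np.maximum(X, 1e-6) + LOG_EPS)


@dataclass
class SubstateGMM:
    """Fitted 3-component diagonal mixture over log-standardized features.

    ``log_features`` records the transform so a frozen reference fit can be
    re-applied to other datasets unambiguously.
    """

    feat_mean: np.ndarray
    feat_sd: np.ndarray
    weights: np.ndarray
    means: np.ndarray       # (3, 3) standardized space
    variances: np.ndarray   # (3, 3) diagonal
    mapping: dict           # component index -> substate name
    sabic_table: dict = field(default_factory=dict)
    log_features: bool = True

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.log_features:
            X = _log_features(X)
        return (X - self.feat_mean) / self.feat_sd

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Posterior over (QEM1, QEM2, QEM3) for raw feature rows."""
        Z = self._standardize(np.atleast_2d(np.asarray(X, dtype=float)))
        log_p = np.empty((Z.shape[0], 3))
        for k in range(3):
            diff = Z - self.means[k]
            log_p[:, k] = (
                np.log(self.weights[k])
                - 0.5 * np.sum(np.log(2 * np.pi * self.variances[k]))
                - 0.5 * np.sum(diff**2 / self.variances[k], axis=1)
            )
        log_p -= log_p.max(axis=1, keepdims=True)
        post = np.exp(log_p)
        post /= post.sum(axis=1, keepdims=True)
        # reorder columns to (QEM1, QEM2, QEM3)
        order = [next(c for c, s in self.mapping.items() if s == name)
                 for name in QEM_STATES]
        return post[:, order]

    def predict(self, X: np.ndarray) -> list[str]:
        post = self.posterior(X)
        return [QEM_STATES[i] for i in np.argmax(post, axis=1)]

    def to_json(self) -> str:
        return json.dumps({
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "mapping": {str(k): v for k, v in self.mapping.items()},
            "sabic_table": {str(k): v for k, v in self.sabic_table.items()},
            "log_features": self.log_features,
        })

    @classmethod
    def from_json(cls, s: str) -> "SubstateGMM":
        d = json.loads(s)
        return cls(
            feat_mean=np.array(d["feat_mean"]),
            feat_sd=np.array(d["feat_sd"]),
            weights=np.array(d["weights"]),
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
            mapping={int(k): v for k, v in d["mapping"].items()},
            sabic_table={int(k): v for k, v in d.get("sabic_table", {}).items()},
            log_features=bool(d.get("log_features", True)),
        )


def sabic_select(
    X: np.ndarray,
    ks=range(1, 7),
    seed: int = 0,
    n_init: int = 10,
    reg_covar: float = presets.GMM_REG_COVAR,
) -> tuple[int, dict]:
    """Fit diagonal mixtures for each k and return (argmin-SABIC k, table)."""
    Xz = (X - X.mean(axis=0)) / X.std(axis=0)
    table = {}
    for k in ks:
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", reg_covar=reg_covar,
            n_init=n_init, random_state=seed, max_iter=300,
        ).fit(Xz)
        table[int(k)] = sabic(gm, Xz)
    best = min(table, key=table.get)
    return best, table


def fit_substate_gmm(
    features: np.ndarray | list[BinFeatures],
    seed: int = 0,
    reg_covar: float = presets.GMM_REG_COVAR,
    select_k: bool = True,
    log_features: bool = True,
) -> SubstateGMM:
    """Fit the 3-component substate mixture on saccade-containing bins.

    Features are z-standardized; component k is initialized at +1 SD on
    feature k and 0 elsewhere (the diagonally dominant initialization, which
    is only meaningful on commensurate scales).  Components are mapped to
    substates by their dominant feature: highest count mean -> QEM-1,
    steepest slope mean -> QEM-2, longest fixation mean -> QEM-3.
    """
    if not isinstance(features, np.ndarray):
        features = features_matrix(features)
    X = np.asarray(features, dtype=float)
    X = X[np.all(np.isfinite(X), axis=1) & (X[:, 0] >= 1)]
    if X.shape[0] < 30:
        raise ValueError("need >= 30 saccade-containing bins to fit the GMM")
    Xt = _log_features(X) if log_features else X
    mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xt - mu) / sd
    # diagonally dominant initialization: +1 SD on the component's own
    # feature, 0 elsewhere (meaningful only on commensurate scales)
    gm = GaussianMixture(
        n_components=3, covariance_type="diag", reg_covar=reg_covar,
        means_init=np.eye(3), random_state=seed, max_iter=500,
    ).fit(Z)
    # dominance is judged on the components' implied raw-scale means; for
    # log features that is exp(mu + sigma^2/2), so a heavy-tailed component
    # (long fixations) dominates even when its median is modest
    if log_features:
        mu_log = gm.means_ * sd + mu
        var_log = gm.covariances_ * sd**2
        dominance = mu_log + 0.5 * var_log
    else:
        dominance = gm.means_
    mapping = {}
    claimed = set()
    for feat_idx, state in enumerate(QEM_STATES):
        comp = int(np.argmax(dominance[:, feat_idx]))
        if comp in claimed:
            raise ValueError(
                "component labeling is not a bijection: one component is "
                "dominant on two features"
            )
        claimed.add(comp)
        mapping[comp] = state
    table = {}
    if select_k:
        _, table = sabic_select(X, seed=seed)
    return SubstateGMM(
        feat_mean=mu, feat_sd=sd, weights=gm.weights_.copy(),
        means=gm.means_.copy(), variances=gm.covariances_.copy(),
        mapping=mapping, sabic_table=table, log_features=log_features,
    )


@dataclass
class LabeledBin:
    start_s: float
    end_s: float
    label: str
    posterior: np.ndarray | None = None  # over (QEM1, QEM2, QEM3)


@dataclass
class StateLabelSeries:
    """Contiguous labeled intervals covering a recording."""

    bins: list[LabeledBin]

    @property
    def total_s(self) -> float:
        return self.bins[-1].end_s if self.bins else 0.0

    def label_at(self, t_s: float) -> str:
        for b in self.bins:
            if b.start_s <= t_s < b.end_s:
                return b.label
        return "Unlabeled"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start_s": b.start_s, "end_s": b.end_s, "label": b.label}
             for b in self.bins]
        )

    def periods_of(self, state: str) -> list[tuple[float, float]]:
        """Maximal contiguous runs of one state as (start, end) intervals."""
        out: list[tuple[float, float]] = []
        for b in self.bins:
            if b.label != state:
                continue
            if out and abs(out[-1][1] - b.start_s) < 1e-9:
                out[-1] = (out[-1][0], b.end_s)
            else:
                out.append((b.start_s, b.end_s))
        return out


def classify(
    sleep_bins: list[Bin],
    bin_features: list[BinFeatures],
    gmm: SubstateGMM,
    total_duration_s: float,
    unlabeled: list[tuple[float, float]] | None = None,
) -> StateLabelSeries:
    """Label a recording: QNEM (no saccades), QEM-1/2/3 (GMM posterior
    argmax), Wake (non-sleep time) and Unlabeled (tracking gaps)."""
    if gmm is None:
        raise ValueError("gmm must be fitted or loaded")
    labeled: list[LabeledBin] = []
    for b, f in zip(sleep_bins, bin_features):
        if f.saccade_count == 0:
            labeled.append(LabeledBin(b.start_s, b.end_s, "QNEM"))
        else:
            row = np.array([[f.saccade_count, f.mean_decay_slope_deg_s,
                             f.mean_fixation_s]])
            row[~np.isfinite(row)] = 0.0
            post = gmm.posterior(row)[0]
            labeled.append(
                LabeledBin(b.start_s, b.end_s, QEM_STATES[int(np.argmax(post))],
                           posterior=post)
            )
    for a, b in unlabeled or []:
        labeled.append(LabeledBin(a, b, "Unlabeled"))
    labeled.sort(key=lambda x: x.start_s)
    # fill gaps with Wake
    out: list[LabeledBin] = []
    cursor = 0.0
    for lb in labeled:
        if lb.start_s > cursor + 1e-9:
            out.append(LabeledBin(cursor, lb.start_s, "Wake"))
        out.append(lb)
        cursor = max(cursor, lb.end_s)
    if cursor < total_duration_s - 1e-9:
        out.append(LabeledBin(cursor, total_duration_s, "Wake"))
    return StateLabelSeries(out)


def compute_occupancy(
    series: StateLabelSeries,
    windows: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-window state fractions of total time and of sleep time.

    Sleep-relative fractions exclude Wake and Unlabeled time.  Windows with
    no time (or no sleep) get NaN fractions.
    """
    if windows is None:
        windows = [(0.0, series.total_s)]
    rows = []
    for w0, w1 in windows:
        durs = {s: 0.0 for s in presets.STATES + ("Unlabeled",)}
        for b in series.bins:
            ov = max(0.0, min(b.end_s, w1) - max(b.start_s, w0))
            durs[b.label] += ov
        total = w1 - w0
        sleep = sum(durs[s] for s in presets.SLEEP_STATES)
        for state in presets.STATES:
            rows.append({
                "window_start_s": w0, "window_end_s": w1, "state": state,
                "frac_total": durs[state] / total if total > 0 else np.nan,
                "frac_sleep": (
                    durs[state] / sleep
                    if sleep > 0 and state in presets.SLEEP_STATES
                    else (np.nan if state in presets.SLEEP_STATES else np.nan)
                ),
            })
    return pd.DataFrame(rows)


STARTLE_RULES = {
    "tail_angle_gt_180deg": lambda x: np.any(np.abs(x) > 180.0),
    "speed_gt_150mm_s": lambda x: np.any(x > 150.0),
}


def startle_response_probability(
    stimulus_times_s: np.ndarray,
    response: np.ndarray,
    fs_hz: float,
    rule: str,
    series: StateLabelSeries,
    window_s: float = 1.0,
) -> pd.DataFrame:
    """Per-pre-stimulus-state response probability.

    ``response`` is the tail-angle (deg) or speed (mm/s) series at ``fs_hz``;
    a trial is responsive if the rule fires within ``window_s`` after the
    stimulus.  Stimuli during Unlabeled time (or outside the recording) are
    excluded.
    """
    try:
        fn = STARTLE_RULES[rule]
    except KeyError:
        raise ValueError(f"unknown rule {rule!r}") from None
    n = response.size
    counts = {s: [0, 0] for s in presets.STATES}
    for t in np.atleast_1d(stimulus_times_s):
        i0 = int(round(t * fs_hz))
        i1 = i0 + int(round(window_s * fs_hz))
        if i0 < 0 or i1 > n:
            warnings.warn(f"stimulus at {t} s outside recording; trial dropped")
            continue
        state = series.label_at(t)
        if state == "Unlabeled":
            continue
        counts[state][0] += 1
        counts[state][1] += int(bool(fn(response[i0:i1])))
    return pd.DataFrame(
        [{"state": s, "n_trials": c[0],
          "p_response": c[1] / c[0] if c[0] else np.nan}
         for s, c in counts.items()]
    )
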