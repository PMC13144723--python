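"""Latent-variable network model of circadian/luminosity state gating.

The probability of each behavioral state (Wake, QEM-1/2/3, QNEM) at each
1-min step is modeled from three inputs — luminosity (0/1), introduction to
the chamber (1 on the loading day), and circadian time encoded as a
(cos, sin) pair with a 24 h period — through a bottleneck architecture:
4 inputs -> 24 hidden units -> 1-D latent -> 24 hidden units -> 5-way
softmax.  Hidden and latent units use sigmoid activations by default (ReLU
available).  The 1-D latent forces the model to order states along a single
axis, which is the interpretable object of interest.

Training minimizes cross-entropy with full-batch Adam.  Fitting uses k-fold
cross-validation over fish with repetitions; ablations time-shuffle one
input (the cos/sin pair jointly for circadian) before refitting, and the
drop in held-out correlation measures that input's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import wilcoxon

from sleepscope import presets
from sleepscope.states import StateLabelSeries

STATE_ORDER = ("Wake", "QEM1", "QEM2", "QEM3", "QNEM")
INPUT_NAMES = ("luminosity", "introduction", "cos", "sin")
ABLATABLE = {
    "luminosity": [0],
    "introduction": [1],
    "circadian": [2, 3],
}


def build_inputs(
    labels_per_min: np.ndarray | StateLabelSeries,
    lights_per_min: np.ndarray,
    start_clock_h: float,
    day1_per_min: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute input matrix (n, 4) and one-hot targets (n, 5).

    Unlabeled steps are dropped.  The circadian phase offset comes from the
    experiment's start clock time, so a start at midnight gives cos = 1.
    """
    if isinstance(labels_per_min, StateLabelSeries):
        mins = int(labels_per_min.total_s // 60)
        labels_per_min = np.array(
            [labels_per_min.label_at(60.0 * m + 30.0) for m in range(mins)],
            dtype=object,
        )
    labels_per_min = np.asarray(labels_per_min, dtype=object)
    lights_per_min = np.asarray(lights_per_min, dtype=float)
    if lights_per_min.size != labels_per_min.size:
        raise ValueError("lights schedule must match label length")
    n = labels_per_min.size
    t_h = np.arange(n) / 60.0 + start_clock_h
    phase = 2.0 * np.pi * t_h / 24.0
    if day1_per_min is None:
        day1_per_min = (np.arange(n) / 60.0 + start_clock_h) < 24.0
    X = np.column_stack([
        lights_per_min,
        np.asarray(day1_per_min, dtype=float),
        np.cos(phase),
        np.sin(phase),
    ])
    keep = labels_per_min != "Unlabeled"
    Y = np.zeros((n, 5))
    for k, s in enumerate(STATE_ORDER):
        Y[labels_per_min == s, k] = 1.0
    return X[keep], Y[keep]


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
    return np.maximum(x, 0.0)


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return a * (1.0 - a)
    return (a > 0).astype(float)


@dataclass
class StateProbModel:
    """Bottleneck softmax network 4 -> 24 -> 1 -> 24 -> 5."""

    weights: list
    biases: list
    activation: str = "sigmoid"
    meta: dict = field(default_factory=dict)

    @classmethod
    def init(cls, seed: int, hidden: int = 24, activation: str = "sigmoid"):
        rng = np.random.default_rng(seed)
        dims = [4, hidden, 1, hidden, 5]
        W = [rng.normal(0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
             for i in range(4)]
        b = [np.zeros(dims[i + 1]) for i in range(4)]
        return cls(weights=W, biases=b, activation=activation,
                   meta={"seed": seed})

    def _forward(self, X: np.ndarray):
        acts = [X]
        a = X
        for i in range(3):
            a = _act(a @ self.weights[i] + self.biases[i], self.activation)
            acts.append(a)
        logits = a @ self.weights[3] + self.biases[3]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        acts.append(p)
        return acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(X))[-1]

    def latent(self, X: np.ndarray) -> np.ndarray:
        """Scalar latent trajectory z(t)."""
        return self._forward(np.atleast_2d(X))[2].ravel()

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        lr: float = 3e-3,
        max_epochs: int = 800,
        patience: int = 60,
        tol: float = 1e-4,
        seed: int = 0,
    ) -> dict:
        """Full-batch Adam on cross-entropy; early stop on loss plateau."""
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(Y, dtype=np.float32)
        self.weights = [w.astype(np.float32) for w in self.weights]
        self.biases = [x.astype(np.float32) for x in self.biases]
        W, b = self.weights, self.biases
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = X.shape[0]
        best = np.inf
        since_best = 0
        converged = False
        loss = np.inf
        for epoch in range(1, max_epochs + 1):
            acts = self._forward(X)
            p = acts[-1]
            loss = float(-(Y * np.log(p + 1e-12)).sum() / n)
            if loss < best - tol:
                best = loss
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    converged = True
                    break
            delta = (p - Y) / n
            grads_W, grads_b = [None] * 4, [None] * 4
            for i in range(3, -1, -1):
                grads_W[i] = acts[i].T @ delta
                grads_b[i] = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ W[i].T) * _act_grad(acts[i], self.activation)
            for i in range(4):
                mW[i] = b1 * mW[i] + (1 - b1) * grads_W[i]
                vW[i] = b2 * vW[i] + (1 - b2) * grads_W[i] ** 2
                mb[i] = b1 * mb[i] + (1 - b1) * grads_b[i]
                vb[i] = b2 * vb[i] + (1 - b2) * grads_b[i] ** 2
                c1 = 1 - b1**epoch
                c2 = 1 - b2**epoch
                W[i] -= lr * (mW[i] / c1) / (np.sqrt(vW[i] / c2) + eps)
                b[i] -= lr * (mb[i] / c1) / (np.sqrt(vb[i] / c2) + eps)
        self.meta.update({"final_loss": loss, "converged": converged or loss < best + tol})
        return {"loss": loss, "epochs": epoch, "converged": self.meta["converged"]}


def observed_probabilities(
    targets_by_fish: dict, smooth_min: int = 30
) -> np.ndarray:
    """Observed per-state probability: fraction of fish in each state per
    minute, smoothed with a moving average."""
    mats = list(targets_by_fish.values())
    n = min(m.shape[0] for m in mats)
    obs = np.mean([m[:n] for m in mats], axis=0)
    if smooth_min > 1:
        obs = uniform_filter1d(obs, size=smooth_min, axis=0, mode="nearest")
    return obs


def evaluate(
    model: StateProbModel,
    inputs_by_fish: dict,
    targets_by_fish: dict,
    smooth_min: int = 30,
) -> np.ndarray:
    """Per-state Pearson r between model and observed state probabilities.

    Observed probability per time bin is the fraction of held-out fish in
    that state; undefined (zero-variance) states yield NaN.
    """
    obs = observed_probabilities(targets_by_fish, smooth_min)
    n = obs.shape[0]
    Xs = list(inputs_by_fish.values())
    pred = np.mean([model.predict_proba(x[:n]) for x in Xs], axis=0)
    pred = uniform_filter1d(pred, size=smooth_min, axis=0, mode="nearest")
    out = np.full(5, np.nan)
    for k in range(5):
        a, b = pred[:, k], obs[:, k]
        if a.std() > 0 and b.std() > 0:
            out[k] = float(np.corrcoef(a, b)[0, 1])
    return out


@dataclass
class EnsembleResult:
    models: list
    fold_fish: list          # held-out fish ids per model
    r: np.ndarray            # (n_models, 5) held-out correlations
    latents: list            # z(t) per model on its held-out fish


def _folds(fish_ids: list, n_folds: int, rng: np.random.Generator):
    ids = np.array(fish_ids, dtype=object)
    perm = rng.permutation(len(ids))
    return [ids[perm[k::n_folds]].tolist() for k in range(n_folds)]


def fit(
    inputs_by_fish: dict,
    targets_by_fish: dict,
    seed: int = 0,
    n_folds: int = 5,
    n_reps: int = 20,
    activation: str = "sigmoid",
    max_epochs: int = 800,
    smooth_min: int = 30,
) -> EnsembleResult:
    """Cross-validated ensemble over fish (``n_folds`` x ``n_reps`` models).

    Each model trains on all steps pooled over ~80% of fish and is evaluated
    on the held-out fish; non-converged models are excluded with a warning.
    """
    import warnings

    fish = sorted(inputs_by_fish)
    if len(fish) < n_folds:
        raise ValueError(f"need >= {n_folds} fish")
    rng = np.random.default_rng(seed)
    models, fold_fish, rs, latents = [], [], [], []
    for rep in range(n_reps):
        for fold in _folds(fish, n_folds, rng):
            train = [f for f in fish if f not in fold]
            X = np.vstack([inputs_by_fish[f] for f in train])
            Y = np.vstack([targets_by_fish[f] for f in train])
            m = StateProbModel.init(seed=int(rng.integers(2**31)),
                                    activation=activation)
            info = m.fit(X, Y, seed=seed, max_epochs=max_epochs)
            if not info["converged"] and info["loss"] > 1.6:
                warnings.warn("non-converged model excluded from ensemble")
                continue
            held_X = {f: inputs_by_fish[f] for f in fold}
            held_Y = {f: targets_by_fish[f] for f in fold}
            r = evaluate(m, held_X, held_Y, smooth_min)
            models.append(m)
            fold_fish.append(fold)
            rs.append(r)
            latents.append(m.latent(np.vstack(list(held_X.values()))))
    return EnsembleResult(models, fold_fish, np.array(rs), latents)


def shuffle_inputs(
    inputs_by_fish: dict, which: str, seed: int
) -> dict:
    """Time-shuffle one input (cos/sin jointly for 'circadian') per fish."""
    if which not in ABLATABLE:
        raise ValueError(f"unknown input {which!r}; choose from {set(ABLATABLE)}")
    cols = ABLATABLE[which]
    rng = np.random.default_rng(seed)
    out = {}
    for f, X in inputs_by_fish.items():
        X = X.copy()
        perm = rng.permutation(X.shape[0])
        X[:, cols] = X[perm][:, cols]
        out[f] = X
    return out


@dataclass
class AblationResult:
    which: str
    r_full: np.ndarray       # (n_models, 5)
    r_ablated: np.ndarray
    delta_r: np.ndarray      # mean over models, per state
    p_values: np.ndarray     # paired signed-rank across ensemble, per state

    def to_dataframe(self) -> pd.DataFrame:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            return pd.DataFrame({
                "state": STATE_ORDER,
                "r_full": np.nanmean(self.r_full, axis=0),
                "r_ablated": np.nanmean(self.r_ablated, axis=0),
                "delta_r": self.delta_r,
                "p": self.p_values,
            })


def ablate(
    inputs_by_fish: dict,
    targets_by_fish: dict,
    which: str,
    seed: int = 0,
    full: EnsembleResult | None = None,
    **fit_kwargs,
) -> AblationResult:
    """Refit the ensemble with one input time-shuffled; report delta r.

    The full and ablated ensembles use the same fold structure and seed so
    the per-model differences are paired.
    """
    if full is None:
        full = fit(inputs_by_fish, targets_by_fish, seed=seed, **fit_kwargs)
    shuffled = shuffle_inputs(inputs_by_fish, which, seed)
    abl = fit(shuffled, targets_by_fish, seed=seed, **fit_kwargs)
    n = min(len(full.models), len(abl.models))
    r_f, r_a = full.r[:n], abl.r[:n]
    with np.errstate(all="ignore"):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            delta = np.nanmean(r_f - r_a, axis=0)
    ps = np.full(5, np.nan)
    for k in range(5):
        d = (r_f[:, k] - r_a[:, k])
        d = d[np.isfinite(d)]
        if d.size >= 5 and np.any(d != 0):
            ps[k] = float(wilcoxon(d).pvalue)
    return AblationResult(which, r_f, r_a, delta, ps)
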