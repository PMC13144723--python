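"""Exact 1-D total-variation denoising (the fused-lasso signal filter).

Solves, for a 1-D signal ``y`` and penalty ``lam``::

    minimize_x  1/2 * sum_i (y_i - x_i)^2  +  lam * sum_i |x_{i+1} - x_i|

The minimizer is piecewise constant.  The implementation is a direct
taut-string sweep: it runs the signal once, maintaining the candidate value
the current segment would take if it terminated with a downward (``vmin``)
or upward (``vmax``) jump together with the corresponding dual tensions
(``umin``/``umax``), and emits a finished segment whenever the next sample
cannot be absorbed without a tension bound being violated.  It returns the
exact global minimizer of the strictly convex objective, typically in O(n).

``lam`` is defined per sample at the trace's native rate; callers that need
rate invariance must rescale it themselves.
"""

from __future__ import annotations

import numpy as np

try:  # optional JIT; identical pure-Python fallback
    from numba import njit as _njit
except Exception:  # pragma: no cover
    def _njit(**kwargs):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _tv1d(y, lam, x):
    n = y.shape[0]
    k = 0
    k0 = 0          # start of the current segment
    kminus = 0      # last position where the lower tension was saturated
    kplus = 0       # last position where the upper tension was saturated
    vmin = y[0] - lam   # segment value if it ends with an upward jump
    vmax = y[0] + lam   # segment value if it ends with a downward jump
    umin = lam
    umax = -lam
    while True:
        while k == n - 1:
            if umin < 0.0:
                # lower tension exhausted at the end: close a vmin segment
                for i in range(k0, kminus + 1):
                    x[i] = vmin
                k0 = kminus + 1
                k = k0
                kminus = k0
                vmin = y[k0]
                umin = lam
                umax = vmin + lam - vmax
            elif umax > 0.0:
                for i in range(k0, kplus + 1):
                    x[i] = vmax
                k0 = kplus + 1
                k = k0
                kplus = k0
                vmax = y[k0]
                umax = -lam
                umin = vmax - lam - vmin
            else:
                v = vmin + umin / (k - k0 + 1)
                for i in range(k0, n):
                    x[i] = v
                return
        umin += y[k + 1] - vmin
        umax += y[k + 1] - vmax
        if umin < -lam:
            # forced upward jump after kminus
            for i in range(k0, kminus + 1):
                x[i] = vmin
            k0 = kminus + 1
            k = k0
            kminus = k0
            kplus = k0
            vmin = y[k0]
            vmax = vmin + 2.0 * lam
            umin = lam
            umax = -lam
        elif umax > lam:
            # forced downward jump after kplus
            for i in range(k0, kplus + 1):
                x[i] = vmax
            k0 = kplus + 1
            k = k0
            kminus = k0
            kplus = k0
            vmax = y[k0]
            vmin = vmax - 2.0 * lam
            umin = lam
            umax = -lam
        else:
            # absorb the next sample into the running segment
            k += 1
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                kminus = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kplus = k


def tv_denoise(y: np.ndarray, lam: float) -> np.ndarray:
    """Return the exact 1-D total-variation (fused-lasso) denoising of ``y``.

    Parameters
    ----------
    y : 1-D array of finite floats.
    lam : non-negative penalty on successive differences.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("tv_denoise expects a 1-D array")
    if y.size and not np.all(np.isfinite(y)):
        raise ValueError("tv_denoise input must be finite")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n = y.size
    if n <= 1 or lam == 0:
        return y.copy()
    x = np.empty_like(y)
    _tv1d(y, float(lam), x)
    return x
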