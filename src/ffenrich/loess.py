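"""Local polynomial (loess) smoother with tricube weights.

A small local-quadratic regression used for the GC-correction fit and the
size-based fetal-fraction curves: span 0.75 and degree 2 by default, i.e.
the defaults of the classical loess smoother.  Problem sizes here are a few
hundred points, so the straightforward O(n * k) implementation is plenty.
"""

from __future__ import annotations

import numpy as np


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray | None = None,
    span: float = 0.75,
    degree: int = 2,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate a loess fit of ``y`` on ``x`` at ``x_eval`` (default: x).

    At each evaluation point the nearest ``ceil(span * n)`` observations get
    tricube weights by scaled distance (times any prior ``weights``) and a
    weighted polynomial of the given degree is fit by least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("x and y must be equal-length, non-empty")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x range (all x equal)")
    if x_eval is None:
        x_eval = x
    x_eval = np.asarray(x_eval, dtype=float)
    n = len(x)
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    prior = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            h = max(d.max(), np.finfo(float).tiny)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3 * prior
        pos = w > 0
        # guard against fewer support points than parameters
        deg = min(degree, max(0, int(pos.sum()) - 1))
        xc = x[pos] - x0  # center for conditioning
        coef = np.polyfit(xc, y[pos], deg, w=np.sqrt(w[pos]))
        out[i] = coef[-1]  # value at xc = 0
    return out
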