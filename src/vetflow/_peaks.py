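"""Quadratic peak interpolation shared by energy transients and IR signals."""

from __future__ import annotations

import numpy as np


def quadratic_peak(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Peak (time, value) of a sampled transient.

    The discrete maximum is refined by a parabola through the maximum and its
    two neighbours. A maximum on either boundary of the grid is returned as-is
    (a monotone decay therefore reports the first grid time). Ties break
    toward the earlier time.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.size == 0 or y.shape != t.shape:
        raise ValueError("t and y must be equal-length non-empty 1-D arrays")
    k = int(np.argmax(y))  # first occurrence -> earlier-time tie break
    if k == 0 or k == y.size - 1:
        return float(t[k]), float(y[k])
    t0, t1, t2 = t[k - 1], t[k], t[k + 1]
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0:  # flat or degenerate neighbourhood
        return float(t1), float(y1)
    # uniform-grid vertex formula
    h = 0.5 * (t2 - t0)
    dt = 0.5 * (y0 - y2) / denom * h
    tp = float(t1 + dt)
    yp = float(y1 - 0.25 * (y0 - y2) * dt / h)
    return tp, yp
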