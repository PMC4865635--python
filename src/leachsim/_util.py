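"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np


def piecewise_linear(x, knots, left="flat", right="flat"):
    """Evaluate a piecewise-linear table of (x, y) pairs.

    ``left``/``right`` control extrapolation: "flat" holds the end value,
    "zero" interpolates linearly from/to (0, 0).
    """
    pts = np.asarray(knots, dtype=float)
    xs, ys = pts[:, 0], pts[:, 1]
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if left == "zero":
        xs = np.concatenate(([0.0], xs))
        ys = np.concatenate(([0.0], ys))
    y = np.interp(x, xs, ys)
    if left == "flat":
        y = np.where(x < xs[0], ys[0], y)
    if right == "flat":
        y = np.where(x > xs[-1], ys[-1], y)
    return float(y[0]) if scalar else y
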