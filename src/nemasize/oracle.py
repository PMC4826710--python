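"""Brute-force verification by dense polygonal sampling.

:func:`revolve_oracle` computes the four size measures of a sampled
boundary with composite trapezoid / exact-frustum sums written directly
on the sample arrays.  It shares no code with the estimator modules, so
it serves as an independent check: both are exact for piecewise-linear
boundaries, and for smooth boundaries the oracle converges with the
usual O(n^-2) trapezoid error.
"""

from __future__ import annotations

import numpy as np

from .estimates import SizeEstimates

__all__ = ["revolve_oracle"]


def revolve_oracle(x, y, length: float = 1.0) -> SizeEstimates:
    """Size measures of a sampled boundary ``(x_i, y_i)`` with ``y >= 0``.

    Perimeter: twice the polyline arc length plus the terminal caps
    ``2 (y_0 + y_n)``.  Projected area: doubled trapezoid rule.  Surface:
    exact frustum lateral sums plus terminal discs.  Volume: exact
    frustum sums.  Signed ``dx`` are used throughout, so the traversal
    direction is irrelevant; absolute values are taken at the end.

    ``x`` and ``y`` are interpreted as fractions of ``length``, and the
    results are scaled by ``length`` and its powers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with at least 2 samples")
    if (y < 0).any():
        raise ValueError("boundary ordinates must be non-negative")
    dx = np.diff(x)
    seg = np.hypot(dx, np.diff(y))
    ysum = y[:-1] + y[1:]
    p = 2.0 * (y[0] + y[-1]) + 2.0 * seg.sum()
    a = abs((ysum * dx).sum())  # = |2 * trapezoid(y, x)|
    s = np.pi * (y[0] ** 2 + y[-1] ** 2) + np.pi * (ysum * seg).sum()
    v = abs((np.pi / 3.0) * ((y[:-1] ** 2 + y[:-1] * y[1:] + y[1:] ** 2) * dx).sum())
    L = length
    return SizeEstimates(
        perimeter=p * L,
        projected_area=a * L**2,
        surface_area=s * L**2,
        volume=v * L**3,
        method="geometric",
    )
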