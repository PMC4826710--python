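"""Piecewise conical-frustum size estimators.

A nematode is treated as a solid of revolution about its midline: the
radius ``r(l)`` varies along the axial coordinate ``l``.  Joining the
measured coordinates by straight lines decomposes the body into conical
frusta (with cylinders and cones as the equal-radius and zero-radius
special cases), for which perimeter, projected area, lateral surface and
volume all have closed forms.  Summing the frustum contributions — plus
end caps where the terminal radii are non-zero — gives the piecewise
estimator; letting the number of segments grow gives the continuous
(quadrature) forms.

Both the outline perimeter and the lateral-surface sums count the two
mirror-symmetric flanks of the silhouette, i.e. carry a factor 2 on the
slant-length terms.
"""

from __future__ import annotations

from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import quad

from .estimates import SizeEstimates
from .morphometry import MorphometricProfile

__all__ = ["FrustumMeasures", "frustum_measures", "piecewise_estimates", "continuous_estimates"]


class FrustumMeasures(NamedTuple):
    """Closed-form measures of a single conical frustum (no end caps)."""

    volume: float
    surface_area: float
    perimeter: float
    area: float


def frustum_measures(r1: float, r2: float, h: float) -> FrustumMeasures:
    """Volume, total surface, silhouette perimeter and area of a frustum.

    Parameters
    ----------
    r1, r2 : float
        Base and top radii, ``r1 >= r2 >= 0``.  The order is enforced
        rather than silently swapped: the caller controls orientation.
    h : float
        Height (axial extent), ``h > 0``.

    Returns
    -------
    FrustumMeasures
        ``volume = (pi h / 3)(r1^2 + r1 r2 + r2^2)``;
        ``surface_area`` includes both end discs;
        ``perimeter`` and ``area`` describe the trapezoidal silhouette.
    """
    if not (r1 >= r2 >= 0):
        raise ValueError(f"frustum requires r1 >= r2 >= 0, got r1={r1}, r2={r2}")
    if h <= 0:
        raise ValueError(f"frustum height must be positive, got h={h}")
    slant = np.hypot(r1 - r2, h)
    return FrustumMeasures(
        volume=np.pi * h / 3.0 * (r1**2 + r1 * r2 + r2**2),
        surface_area=np.pi * (r1 + r2) * slant + np.pi * (r1**2 + r2**2),
        perimeter=2.0 * (r1 + r2) + 2.0 * slant,
        area=(r1 + r2) * h,
    )


def piecewise_estimates(profile: MorphometricProfile) -> SizeEstimates:
    """Size estimates from the piecewise-linear (conical-frustum) model.

    In relative units, with coordinates ``(l_i, r_i)``, ``i = 0..n``::

        p   = 2 (r_0 + r_n) + 2 sum_i sqrt(dr_i^2 + dl_i^2)
        a   = sum_i (r_i + r_{i+1}) dl_i
        a_s = pi (r_0^2 + r_n^2) + pi sum_i (r_i + r_{i+1}) sqrt(dr_i^2 + dl_i^2)
        v   = (pi / 3) sum_i (r_i^2 + r_i r_{i+1} + r_{i+1}^2) dl_i

    The end-cap terms ``2 (r_0 + r_n)`` and ``pi (r_0^2 + r_n^2)`` vanish
    for supplemented profiles and reproduce the cylinder formulas for a
    two-coordinate constant-radius profile.  Interface discs between
    adjacent frusta cancel and are never formed.  Results are scaled by
    ``L``, ``L^2``, ``L^2`` and ``L^3``.
    """
    r = profile.radii
    dl = np.diff(profile.positions)
    dr = np.diff(r)
    slant = np.hypot(dr, dl)
    pair = r[:-1] + r[1:]
    L = profile.length
    return SizeEstimates(
        perimeter=(2.0 * (r[0] + r[-1]) + 2.0 * slant.sum()) * L,
        projected_area=float((pair * dl).sum()) * L**2,
        surface_area=(np.pi * (r[0] ** 2 + r[-1] ** 2) + np.pi * (pair * slant).sum()) * L**2,
        volume=(np.pi / 3.0 * ((r[:-1] ** 2 + r[:-1] * r[1:] + r[1:] ** 2) * dl).sum()) * L**3,
        method="geometric",
    )


def continuous_estimates(
    radius_fn: Callable[[float], float],
    length: float = 1.0,
    quadrature_tol: float = 1e-12,
    breakpoints: Sequence[float] | None = None,
    derivative: Callable[[float], float] | None = None,
) -> SizeEstimates:
    """Size estimates for an arbitrary radius function ``r(l)``, ``l in [0, 1]``.

    The continuous limits of the piecewise sums are, with ``ds`` the line
    element along the flank::

        P = 2 (r(0) + r(1)) + 2 * integral ds
        A = 2 * integral r dl
        S = pi (r(0)^2 + r(1)^2) + 2 pi * integral r ds
        V = pi * integral r^2 dl

    each evaluated by adaptive quadrature to absolute tolerance
    ``quadrature_tol`` in relative units, then scaled by powers of
    ``length``.

    Parameters
    ----------
    radius_fn : callable
        Non-negative, piecewise-smooth radius as a fraction of length.
    breakpoints : sequence of float, optional
        Interior points where ``radius_fn`` has kinks; passed to the
        quadrature routine so piecewise-linear profiles integrate exactly.
    derivative : callable, optional
        ``dr/dl``; a central finite difference (one-sided at the ends)
        is used when omitted.
    """
    r0, r1 = float(radius_fn(0.0)), float(radius_fn(1.0))
    for name, val in (("r(0)", r0), ("r(1)", r1)):
        if not np.isfinite(val) or val < 0:
            raise ValueError(f"radius function must be finite and non-negative; {name}={val}")

    if derivative is None:
        h = 1e-7

        def derivative(l: float) -> float:  # noqa: A001 - shadows arg deliberately
            lo, hi = max(0.0, l - h), min(1.0, l + h)
            return (radius_fn(hi) - radius_fn(lo)) / (hi - lo)

    def ds(l: float) -> float:
        return np.hypot(1.0, derivative(l))

    pts = list(breakpoints) if breakpoints is not None else None
    opts = dict(epsabs=quadrature_tol, epsrel=quadrature_tol, limit=200, points=pts)

    def integrate(f):
        val, _ = quad(f, 0.0, 1.0, **opts)
        if not np.isfinite(val):
            raise ValueError("quadrature did not converge to a finite value")
        return val

    arc = integrate(ds)
    area = integrate(lambda l: radius_fn(l))
    surf = integrate(lambda l: radius_fn(l) * ds(l))
    vol = integrate(lambda l: radius_fn(l) ** 2)
    L = length
    return SizeEstimates(
        perimeter=(2.0 * (r0 + r1) + 2.0 * arc) * L,
        projected_area=2.0 * area * L**2,
        surface_area=(np.pi * (r0**2 + r1**2) + 2.0 * np.pi * surf) * L**2,
        volume=np.pi * vol * L**3,
        method="geometric",
    )
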