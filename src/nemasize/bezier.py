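"""Least-squares Bézier representation of the nematode outline.

A Bézier curve of degree ``n`` is the Bernstein-weighted sum of ``n + 1``
control points, ``C(t) = sum_i P_i B_{i,n}(t)`` with
``B_{i,n}(t) = C(n,i) t^i (1-t)^(n-i)``, ``t in [0, 1]``.  Given
morphometric coordinates ``C`` observed at parameter values (nodes), the
control points follow by (weighted) least squares,
``P = (B'WB)^{-1} B'WC``; when the number of nodes equals ``n + 1`` the
curve interpolates the data exactly.

Three outline constructions are supported for a supplemented profile of
``m`` coordinates (``m = 7`` for Cobb data):

``simple7``
    One curve of degree ``m - 1`` through the upper coordinates,
    mirrored about the body axis.  High-degree interpolation through the
    closely spaced anterior coordinates produces Runge loops; these are
    detected and reported as a warning.
``extended13``
    One closed curve of degree ``2m - 2`` fitted clockwise through the
    coordinates of both flanks (upper side anterior to posterior, then
    lower side posterior to anterior, closing back at the anterior tip):
    ``m + (m - 2) + 1 = 2m - 1`` coordinates at uniform nodes.
``edited``
    The extended curve with only the well-behaved lower arc retained —
    from the posterior tip node to the node of the first (anteriormost)
    lower coordinate — mirrored to form the upper boundary and closed
    anteriorly by straight segments to the tip.  This is the
    representation used for size estimation.

Size measures follow from the parametric integrals over the retained
arc (``y`` is the boundary ordinate, primes are ``d/dt``)::

    P = 2 * integral sqrt(x'^2 + y'^2) dt         (+ cap segments)
    A = 2 * integral y x' dt                      (+ cap triangle)
    S = 2 pi * integral |y| sqrt(x'^2 + y'^2) dt  (+ cap cone surface)
    V = pi * integral y^2 x' dt                   (+ cap cone volume)

Signs depend on the traversal direction; absolute values are taken after
checking that the orientation is consistent.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from shapely.geometry import LineString

from .estimates import SizeEstimates
from .morphometry import MorphometricProfile

__all__ = [
    "bernstein",
    "basis_matrix",
    "fit_control_points",
    "BezierCurve",
    "OutlineModel",
    "build_outline",
    "arc_measures",
    "bezier_estimates",
]

CONSTRUCTIONS = ("simple7", "extended13", "edited")

_log = logging.getLogger(__name__)


def _bernstein_raw(i: int, n: int, t):
    """Bernstein weight, defined as 0 for ``i`` outside ``0..n``."""
    if i < 0 or i > n:
        return np.zeros_like(np.asarray(t, dtype=float))
    t = np.asarray(t, dtype=float)
    return math.comb(n, i) * t**i * (1.0 - t) ** (n - i)


def bernstein(i: int, n: int, t):
    """Bernstein polynomial ``B_{i,n}(t) = C(n,i) t^i (1-t)^(n-i)``.

    ``i`` must lie in ``0..n``; ``t`` may be a scalar or array in [0, 1].
    """
    if not 0 <= i <= n:
        raise ValueError(f"Bernstein index i={i} outside 0..{n}")
    out = _bernstein_raw(i, n, t)
    return float(out) if np.isscalar(t) else out


def basis_matrix(nodes, degree: int) -> np.ndarray:
    """Bernstein basis matrix: entry ``(j, i) = B_{i,degree}(t_j)``."""
    nodes = np.asarray(nodes, dtype=float)
    return np.column_stack([_bernstein_raw(i, degree, nodes) for i in range(degree + 1)])


def fit_control_points(data, nodes, degree: int, weights=None) -> np.ndarray:
    """Least-squares Bézier control points, ``P = (B'WB)^{-1} B'WC``.

    Parameters
    ----------
    data : (m, k) array
        Observed coordinates ``C`` (one row per node).
    nodes : (m,) array
        Parameter values in [0, 1] at which the data are attached.
    degree : int
        Curve degree ``n``; requires ``m >= n + 1``.
    weights : (m,) array, optional
        Diagonal of ``W``; uniform weights when omitted.  With
        ``m = n + 1`` the solution interpolates regardless of weights.
    """
    C = np.atleast_2d(np.asarray(data, dtype=float))
    nodes = np.asarray(nodes, dtype=float)
    if C.shape[0] != nodes.size:
        raise ValueError("data and nodes must have the same number of rows")
    if C.shape[0] < degree + 1:
        raise ValueError(f"need at least degree + 1 = {degree + 1} data points, got {C.shape[0]}")
    B = basis_matrix(nodes, degree)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (nodes.size,):
            raise ValueError("weights must be a vector with one entry per node")
        BtWB = B.T @ (w[:, None] * B)
        rhs = B.T @ (w[:, None] * C)
    else:
        BtWB = B.T @ B
        rhs = B.T @ C
    try:
        # solve the normal equations; for the interpolation case this is
        # algebraically B^{-1} C
        P = np.linalg.solve(BtWB, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal matrix B'WB is singular; use distinct nodes or lower the degree"
        ) from exc
    return P


@dataclass(frozen=True)
class BezierCurve:
    """A Bézier curve defined by its control points.

    ``C(0)`` is the first control point and ``C(1)`` the last; the curve
    in between generally does not pass through the interior control
    points.
    """

    control_points: np.ndarray

    def __post_init__(self) -> None:
        P = np.atleast_2d(np.asarray(self.control_points, dtype=float)).copy()
        if P.shape[0] < 2:
            raise ValueError("a Bézier curve needs at least two control points")
        P.setflags(write=False)
        object.__setattr__(self, "control_points", P)

    @property
    def degree(self) -> int:
        return self.control_points.shape[0] - 1

    def __call__(self, t) -> np.ndarray:
        """Evaluate ``C(t)``; returns shape ``(len(t), k)`` (or ``(k,)`` for scalars)."""
        scalar = np.isscalar(t)
        out = basis_matrix(np.atleast_1d(t), self.degree) @ self.control_points
        return out[0] if scalar else out

    def derivative(self, t) -> np.ndarray:
        """``dC/dt = n sum_i P_i (B_{i-1,n-1} - B_{i,n-1})``.

        Out-of-range Bernstein terms are zero, so the endpoint identities
        ``C'(0) = n (P_1 - P_0)`` and ``C'(1) = n (P_n - P_{n-1})`` hold.
        """
        scalar = np.isscalar(t)
        tt = np.atleast_1d(t)
        n = self.degree
        out = np.zeros((tt.size, self.control_points.shape[1]))
        for i in range(n + 1):
            w = _bernstein_raw(i - 1, n - 1, tt) - _bernstein_raw(i, n - 1, tt)
            out += np.outer(w, self.control_points[i])
        out *= n
        return out[0] if scalar else out


@dataclass(frozen=True)
class OutlineModel:
    """A mirrored nematode outline built from a Bézier arc.

    Attributes
    ----------
    curve : BezierCurve
        The fitted curve in relative units.
    t_span : tuple of float
        Parameter interval of the retained arc.
    cap : tuple of float or None
        ``(x1, y1)`` of the anterior closure point: the outline is closed
        by straight segments from the tip ``(0, 0)`` to ``(x1, +/-y1)``.
        ``None`` when the arc itself reaches the tip.
    construction : str
        One of ``simple7``, ``extended13``, ``edited``.
    length : float
        Body length ``L`` in metres (for conversion to absolute units).
    label : str
        Specimen name carried over from the profile.
    """

    curve: BezierCurve
    t_span: tuple
    cap: tuple | None
    construction: str
    length: float
    label: str = ""

    def sample(self, n: int = 512) -> dict:
        """Sampled boundary in relative units.

        Returns a dict with ``upper`` and ``lower`` ``(k, 2)`` arrays
        ordered anterior to posterior, including any cap point and with
        the upper boundary carrying ``y >= 0``.
        """
        t0, t1 = self.t_span
        pts = self.curve(np.linspace(t0, t1, n))
        x, y = pts[:, 0], pts[:, 1]
        upper = np.column_stack([x, np.abs(y)])
        # order anterior -> posterior
        if upper[0, 0] > upper[-1, 0]:
            upper = upper[::-1]
        if self.cap is not None:
            x1, y1 = self.cap
            upper = np.vstack([[0.0, 0.0], [x1, y1], upper])
        lower = upper * np.array([1.0, -1.0])
        return {"upper": upper, "lower": lower}

    def closed_boundary(self, n: int = 512) -> np.ndarray:
        """The full outline as a closed polygon (upper then reversed lower)."""
        s = self.sample(n)
        return np.vstack([s["upper"], s["lower"][::-1], s["upper"][:1]])

    def self_intersects(self, n: int = 512) -> bool:
        """Segment-pair test (via shapely) on the sampled mirrored outline.

        The raw fitted curve and its mirror image are joined into the
        closed boundary ring; a curve that strays across the body axis
        (the anterior Runge loops of the simple construction) makes the
        two flanks cross and the ring non-simple.
        """
        t0, t1 = self.t_span
        pts = self.curve(np.linspace(t0, t1, n))
        # the flanks legitimately meet on the axis at the tips: snap the
        # representation noise there so the mirror join is not a crossing
        pts[np.abs(pts[:, 1]) < 1e-9, 1] = 0.0
        if self.construction == "extended13":
            ring = pts
        else:
            mirror = pts[::-1] * np.array([1.0, -1.0])
            tip = np.array([[0.0, 0.0]]) if self.cap is not None else np.empty((0, 2))
            ring = np.vstack([pts, tip, mirror])
        keep = np.r_[True, np.any(np.diff(ring, axis=0) != 0.0, axis=1)]
        ring = ring[keep]
        return not LineString(np.vstack([ring, ring[:1]])).is_simple


def _clockwise_coordinates(profile: MorphometricProfile) -> np.ndarray:
    """Both-flank coordinates ordered clockwise, closed at the anterior tip."""
    upper = profile.coords()
    lower = profile.coords()[::-1][1:-1] * np.array([1.0, -1.0])
    return np.vstack([upper, lower, upper[:1]])


def build_outline(profile: MorphometricProfile, construction: str = "edited") -> OutlineModel:
    """Build one of the three Bézier outline constructions for a profile.

    The profile must be supplemented (terminal coordinates ``(0, 0)`` and
    ``(1, 0)``).  For ``m`` coordinates the extended/edited constructions
    fit a degree ``2m - 2`` curve through the ``2m - 1`` clockwise-ordered
    boundary coordinates at uniform nodes ``t = i / (2m - 2)``; the edited
    construction retains the arc between the posterior-tip node and the
    node of the anteriormost lower coordinate, and closes the anterior
    with straight segments.
    """
    if construction not in CONSTRUCTIONS:
        raise ValueError(f"unknown construction {construction!r}; expected one of {CONSTRUCTIONS}")
    if not profile.is_supplemented:
        raise ValueError("outline constructions require a supplemented profile (zero end radii)")
    m = profile.n_coords
    if m < 4:
        raise ValueError("outline constructions need at least two interior coordinates")

    if construction == "simple7":
        nodes = np.linspace(0.0, 1.0, m)
        P = fit_control_points(profile.coords(), nodes, degree=m - 1)
        outline = OutlineModel(
            curve=BezierCurve(P),
            t_span=(0.0, 1.0),
            cap=None,
            construction=construction,
            length=profile.length,
            label=profile.label,
        )
        if outline.self_intersects():
            warnings.warn(
                "simple Bézier outline self-intersects (anterior Runge loops); "
                "consider the 'edited' construction",
                RuntimeWarning,
                stacklevel=2,
            )
        return outline

    coords = _clockwise_coordinates(profile)  # 2m - 1 rows
    degree = 2 * m - 2
    nodes = np.arange(2 * m - 1) / degree
    P = fit_control_points(coords, nodes, degree=degree)
    curve = BezierCurve(P)

    if construction == "extended13":
        return OutlineModel(
            curve=curve,
            t_span=(0.0, 1.0),
            cap=None,
            construction=construction,
            length=profile.length,
            label=profile.label,
        )

    # edited: keep the lower arc from the posterior tip (node m - 1) to the
    # anteriormost lower coordinate (node 2m - 3); the residual piece back
    # to the tip is replaced by the straight anterior cap
    t_post = nodes[m - 1]
    t_ant = nodes[2 * m - 3]
    cap_point = (float(profile.positions[1]), float(profile.radii[1]))
    return OutlineModel(
        curve=curve,
        t_span=(float(t_post), float(t_ant)),
        cap=cap_point,
        construction="edited",
        length=profile.length,
        label=profile.label,
    )


def arc_measures(
    curve: BezierCurve, t0: float, t1: float, quadrature_tol: float = 1e-10
) -> tuple:
    """Relative-unit parametric integrals over one boundary arc.

    Returns ``(p, a, s, v)``: both-flank perimeter ``2 * int ds``, mirrored
    projected area ``|2 * int y x' dt|``, revolution surface
    ``|2 pi * int y ds|`` and revolution volume ``|pi * int y^2 x' dt|``.

    Fixed-order Gauss–Legendre quadrature (64 nodes) is doubled until
    successive estimates agree to ``quadrature_tol`` relative; the
    integrands are polynomials of modest degree (and one square root), so
    this converges immediately in practice.
    """
    if not (0.0 <= t0 < t1 <= 1.0):
        raise ValueError(f"invalid arc span ({t0}, {t1})")

    def evaluate(order: int):
        xg, wg = leggauss(order)
        t = 0.5 * (t1 - t0) * xg + 0.5 * (t0 + t1)
        jac = 0.5 * (t1 - t0)
        pts = curve(t)
        der = curve.derivative(t)
        y, xp = pts[:, 1], der[:, 0]
        ds = np.hypot(der[:, 0], der[:, 1])
        return np.array(
            [
                2.0 * np.sum(wg * ds) * jac,
                2.0 * np.sum(wg * y * xp) * jac,
                2.0 * np.pi * np.sum(wg * y * ds) * jac,
                np.pi * np.sum(wg * y**2 * xp) * jac,
            ]
        )

    order = 64
    prev = evaluate(order)
    while True:
        order *= 2
        cur = evaluate(order)
        scale = np.maximum(np.abs(cur), 1e-300)
        if np.max(np.abs(cur - prev) / scale) < quadrature_tol:
            break
        if order > 4096:
            raise RuntimeError(
                f"arc quadrature did not converge: order={order}, last change "
                f"{np.max(np.abs(cur - prev) / scale):.3e}"
            )
        prev = cur
    p, a, s, v = cur
    # orientation: the signed integrals flip together when the arc is
    # traversed the other way; a boundary that crosses the body axis has no
    # consistent orientation and the absolute values below are approximate
    y_check = curve(np.linspace(t0, t1, 257))[:, 1]
    y_amp = np.abs(y_check).max()
    if y_amp > 0 and y_check.max() > 1e-9 * y_amp and y_check.min() < -1e-9 * y_amp:
        warnings.warn(
            "boundary arc crosses the body axis; signed size integrals may partially cancel",
            RuntimeWarning,
            stacklevel=2,
        )
    _log.debug(
        "arc [%g, %g]: orientation %s, quadrature order %d",
        t0,
        t1,
        "reversed" if v < 0 else "forward",
        order,
    )
    return float(p), float(abs(a)), float(abs(s)), float(abs(v))


def bezier_estimates(outline: OutlineModel, quadrature_tol: float = 1e-10) -> SizeEstimates:
    """Size estimates from a Bézier outline (retained arc plus caps).

    The parametric integrals are evaluated over the retained arc; for the
    edited construction the anterior closure contributes its straight-
    segment perimeter, triangle area, cone lateral surface and cone
    volume.  Results are scaled by ``L``, ``L^2``, ``L^2``, ``L^3``.
    """
    t0, t1 = outline.t_span
    if outline.construction == "extended13":
        # the closed curve is mirror-symmetric under t -> 1 - t; measure its
        # lower half (posterior tip at t = 1/2 back to the anterior tip at
        # t = 1) with the standard mirrored-arc integrals.  Integrating the
        # full closed path instead would cancel the signed volume integral.
        t0, t1 = 0.5, 1.0
    p, a, s, v = arc_measures(outline.curve, t0, t1, quadrature_tol)
    if outline.cap is not None:
        x1, y1 = outline.cap
        slant = math.hypot(x1, y1)
        p += 2.0 * slant
        a += x1 * y1
        s += math.pi * y1 * slant
        v += math.pi / 3.0 * y1**2 * x1
    L = outline.length
    return SizeEstimates(
        perimeter=p * L,
        projected_area=a * L**2,
        surface_area=s * L**2,
        volume=v * L**3,
        method="bezier",
    )
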