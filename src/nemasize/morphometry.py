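"""Morphometric data model and conversions.

Nematode morphometry is conventionally reported in one of two schemes:

* **Cobb's ratios** — the axial positions ``l1..l5`` of five anatomical
  landmarks (base of the pharynx/buccal cavity, nerve ring, end of the
  oesophagus, vulva or mid-body, anus) and the body diameters ``d1..d5``
  at those landmarks, each expressed as a percentage of the total body
  length ``L``.
* **de Man indices** — the dimensionless ratios ``a`` (length / greatest
  diameter), ``b`` (length / oesophagus length), ``c`` (length / tail
  length) and ``c'`` (tail length / body radius at the anus).

The canonical in-memory form used by every estimator in this package is
the :class:`MorphometricProfile`: an ordered list of ``(position, radius)``
coordinates expressed as fractions of ``L``, together with ``L`` itself in
metres.  Cobb's percentages are positions and *diameters*; the conversion
to radii (division by 200, not 100) is an easy trap and is handled here
once, explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MorphometricProfile",
    "CobbRatios",
    "DeManIndices",
    "ClassicalShapeParams",
    "cobb_to_profile",
    "profile_to_cobb",
    "deman_to_partial_cobb",
    "profile_to_absolute",
]


def _as_readonly(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).copy()
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class MorphometricProfile:
    """Ordered ``(axial position, radius)`` coordinates in units of ``L``.

    Parameters
    ----------
    length : float
        Total body length ``L`` in metres; must be positive.
    positions : array-like
        Axial positions ``l_i`` as fractions of ``L``; strictly increasing,
        starting at 0 and ending at 1.
    radii : array-like
        Radii ``r_i`` as fractions of ``L``; non-negative, and strictly
        positive at interior coordinates.
    label : str
        Free-text specimen name.
    """

    length: float
    positions: np.ndarray
    radii: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", _as_readonly(self.positions))
        object.__setattr__(self, "radii", _as_readonly(self.radii))
        pos, rad = self.positions, self.radii
        if self.length <= 0 or not math.isfinite(self.length):
            raise ValueError(f"length must be a positive finite number, got {self.length}")
        if pos.ndim != 1 or rad.ndim != 1 or pos.size != rad.size:
            raise ValueError("positions and radii must be 1-d arrays of equal size")
        if pos.size < 2:
            raise ValueError("a profile needs at least two coordinates")
        if not (np.isfinite(pos).all() and np.isfinite(rad).all()):
            raise ValueError("positions and radii must be finite")
        diffs = np.diff(pos)
        bad = np.flatnonzero(diffs <= 0)
        if bad.size:
            i = int(bad[0])
            if diffs[i] == 0:
                raise ValueError(f"duplicate axial position at index {i + 1} (l={pos[i + 1]})")
            raise ValueError(f"axial positions not increasing at index {i + 1} (l={pos[i + 1]})")
        if pos[0] != 0.0 or pos[-1] != 1.0:
            raise ValueError("axial positions must start at 0 and end at 1")
        if (rad < 0).any():
            i = int(np.flatnonzero(rad < 0)[0])
            raise ValueError(f"negative radius at index {i}")
        interior = rad[1:-1]
        if (interior <= 0).any():
            i = int(np.flatnonzero(interior <= 0)[0]) + 1
            raise ValueError(f"interior radius must be positive at index {i}")

    # -- derived quantities -------------------------------------------------

    @property
    def n_coords(self) -> int:
        return int(self.positions.size)

    @property
    def max_radius(self) -> float:
        """Greatest relative radius, i.e. ``D / (2 L)``."""
        return float(self.radii.max())

    @property
    def is_supplemented(self) -> bool:
        """Whether the profile is closed by ``(0, 0)`` and ``(1, 0)``."""
        return self.radii[0] == 0.0 and self.radii[-1] == 0.0

    def coords(self) -> np.ndarray:
        """The ``(n, 2)`` coordinate matrix ``[l_i, r_i]`` in relative units."""
        return np.column_stack([self.positions, self.radii])

    def interpolator(self):
        """Piecewise-linear radius function ``r(l)`` on ``[0, 1]``."""
        pos, rad = self.positions, self.radii
        return lambda l: np.interp(l, pos, rad)

    def classical_params(self) -> "ClassicalShapeParams":
        """Derive ``(L, D, d, lambda)`` for the classical estimators.

        ``D`` is twice the greatest radius, ``d`` twice the radius at the
        first interior coordinate (the labial region), and ``lambda`` the
        fractional position of the greatest radius (the mean position when
        the maximum is attained more than once, as for a cylinder, and
        clipped to [0.01, 0.99] so degenerate shapes stay in the valid
        parameter domain).
        """
        attained = self.positions[self.radii == self.radii.max()]
        lam = float(np.clip(attained.mean(), 0.01, 0.99))
        d_rel = self.radii[1] if self.n_coords > 2 else self.radii[0]
        return ClassicalShapeParams(
            length=self.length,
            max_diameter=2.0 * self.max_radius * self.length,
            labial_diameter=2.0 * float(d_rel) * self.length,
            lambda_pos=lam,
        )

    def with_label(self, label: str) -> "MorphometricProfile":
        return replace(self, label=label)


@dataclass(frozen=True)
class CobbRatios:
    """Cobb's percentage ratios: landmark positions and diameters.

    ``l`` and ``d`` hold the five landmark positions and diameters as
    percentages of ``L``.  Entries may be NaN when unknown (e.g. when
    derived from de Man indices); :func:`cobb_to_profile` requires a
    complete set.
    """

    length: float
    l: np.ndarray
    d: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "l", _as_readonly(self.l))
        object.__setattr__(self, "d", _as_readonly(self.d))
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.l.shape != (5,) or self.d.shape != (5,):
            raise ValueError("Cobb's formula defines exactly five landmarks")
        present_l = self.l[np.isfinite(self.l)]
        present_d = self.d[np.isfinite(self.d)]
        if ((present_l <= 0) | (present_l >= 100)).any():
            raise ValueError("landmark positions must lie strictly between 0 and 100 percent")
        if (present_d <= 0).any():
            raise ValueError("landmark diameters must be positive")
        lv = self.l
        for i in range(4):
            if np.isfinite(lv[i]) and np.isfinite(lv[i + 1]) and lv[i] >= lv[i + 1]:
                raise ValueError(
                    f"landmark positions must increase: l{i + 1}={lv[i]} >= l{i + 2}={lv[i + 1]}"
                )

    @property
    def is_complete(self) -> bool:
        return bool(np.isfinite(self.l).all() and np.isfinite(self.d).all())


@dataclass(frozen=True)
class DeManIndices:
    """The de Man shape indices ``a``, ``b``, ``c`` and ``c'``."""

    length: float
    a: float
    b: float
    c: float
    c_prime: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 1:
                raise ValueError(f"de Man index {name} must exceed 1")
        if self.c_prime <= 0:
            raise ValueError("de Man index c' must be positive")


@dataclass(frozen=True)
class ClassicalShapeParams:
    """The ``(L, D, d, lambda)`` parameters of the classical estimators.

    ``L`` is the body length, ``D`` the maximum diameter and ``d`` the
    labial-region (anterior) diameter, all in metres.  ``lambda_pos`` is
    the fractional axial position of the maximum diameter, used by the
    weighted variant of Tsalolikhin's estimator.
    """

    length: float
    max_diameter: float
    labial_diameter: float
    lambda_pos: float = 0.5

    def __post_init__(self) -> None:
        L, D, d = self.length, self.max_diameter, self.labial_diameter
        if L <= 0:
            raise ValueError(f"length must be positive, got {L}")
        # degenerate d = 0 (pointed anterior) and even D = 0 (a line) are
        # permitted; individual estimators reject what they cannot handle
        if not 0 <= d <= D:
            raise ValueError(f"require 0 <= d <= D, got d={d}, D={D}")
        if not 0 < self.lambda_pos < 1:
            raise ValueError(f"lambda_pos must lie in (0, 1), got {self.lambda_pos}")


# -- conversions ------------------------------------------------------------


def cobb_to_profile(ratios: CobbRatios) -> MorphometricProfile:
    """Convert Cobb's percentage ratios to a supplemented coordinate profile.

    The five landmarks give positions ``l_i / 100`` and radii ``d_i / 200``
    (Cobb reports *diameters*); the profile is closed by prepending
    ``(0, 0)`` and appending ``(1, 0)``, yielding seven coordinates.
    """
    if not ratios.is_complete:
        missing = [f"l{i + 1}" for i in range(5) if not np.isfinite(ratios.l[i])]
        missing += [f"d{i + 1}" for i in range(5) if not np.isfinite(ratios.d[i])]
        raise ValueError(f"incomplete Cobb ratios; missing {', '.join(missing)}")
    positions = np.concatenate([[0.0], ratios.l / 100.0, [1.0]])
    radii = np.concatenate([[0.0], ratios.d / 200.0, [0.0]])
    return MorphometricProfile(ratios.length, positions, radii, label=ratios.label)


def profile_to_cobb(profile: MorphometricProfile) -> CobbRatios:
    """Recover Cobb's percentages from a supplemented 7-coordinate profile."""
    if profile.n_coords != 7 or not profile.is_supplemented:
        raise ValueError("expected a supplemented 7-coordinate profile")
    return CobbRatios(
        length=profile.length,
        l=profile.positions[1:-1] * 100.0,
        d=profile.radii[1:-1] * 200.0,
        label=profile.label,
    )


def deman_to_partial_cobb(idx: DeManIndices) -> CobbRatios:
    """Express the Cobb ratios recoverable from the de Man indices.

    Only four entries are determined::

        l3 = 100 / b          (end of the oesophagus)
        d4 = 200 / a          (maximum diameter, approximately at mid-body)
        l5 = 100 (1 - 1/c)    (anus)
        d5 = 200 / (c c')     (diameter at the anus)

    The remaining six entries are returned as NaN.
    """
    l = np.full(5, np.nan)
    d = np.full(5, np.nan)
    l[2] = 100.0 / idx.b
    d[3] = 200.0 / idx.a
    l[4] = 100.0 * (1.0 - 1.0 / idx.c)
    d[4] = 200.0 / (idx.c * idx.c_prime)
    return CobbRatios(length=idx.length, l=l, d=d, label=idx.label)


def profile_to_absolute(profile: MorphometricProfile) -> np.ndarray:
    """Scale a relative profile into metres: ``(n, 2)`` array of ``(l, r) * L``."""
    return profile.coords() * profile.length
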