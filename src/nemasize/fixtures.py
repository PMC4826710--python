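"""Synthetic morphometric profiles with known properties.

Every estimator in the package can be exercised without any external
data: cylinders, cones and frusta have closed-form measures, the
fusiform shape places its greatest diameter at a configurable fractional
position (for midlength-error studies), and ``random_monotone`` draws
reproducible random slender-body profiles.

Radii are kept within (0, 0.05] of the body length — the slender-body
regime typical of nematodes.
"""

from __future__ import annotations

import numpy as np

from .morphometry import MorphometricProfile

__all__ = ["make_fixture", "SHAPES"]

SHAPES = ("cylinder", "cone", "frustum", "fusiform", "random_monotone")

_MAX_REL_RADIUS = 0.05


def make_fixture(shape: str, seed: int | None = None, length: float = 1e-3, **params) -> MorphometricProfile:
    """Build a deterministic synthetic profile.

    Parameters
    ----------
    shape : str
        One of :data:`SHAPES`.
    seed : int, optional
        Seeds the generator for ``random_monotone``; ignored (but
        accepted) elsewhere.
    length : float
        Body length in metres (default 1 mm).

    Shape parameters (all radii as fractions of length)
    ---------------------------------------------------
    cylinder : ``radius`` (default 0.01)
    cone : ``radius`` (default 0.01), base at the anterior
    frustum : ``r_base`` (default 0.012), ``r_top`` (default 0.008)
    fusiform : ``lambda_pos`` (default 0.5), ``r_anterior`` (default 0.004),
        ``r_max`` (default 0.012), ``n_interior`` (default 21); a smooth
        taper from a blunt anterior to a pointed posterior with the
        greatest radius at ``lambda_pos``.
    random_monotone : ``n_interior`` (default 5), ``max_radius``
        (default 0.05); strictly increasing random positions with
        positive random radii, closed by ``(0, 0)`` and ``(1, 0)``.
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown fixture shape {shape!r}; expected one of {SHAPES}")

    if shape == "cylinder":
        r = params.get("radius", 0.01)
        return MorphometricProfile(length, [0.0, 1.0], [r, r], label="cylinder fixture")

    if shape == "cone":
        r = params.get("radius", 0.01)
        return MorphometricProfile(length, [0.0, 1.0], [r, 0.0], label="cone fixture")

    if shape == "frustum":
        r1 = params.get("r_base", 0.012)
        r2 = params.get("r_top", 0.008)
        return MorphometricProfile(length, [0.0, 1.0], [r1, r2], label="frustum fixture")

    if shape == "fusiform":
        lam = params.get("lambda_pos", 0.5)
        r_ant = params.get("r_anterior", 0.004)
        r_max = params.get("r_max", 0.012)
        n = int(params.get("n_interior", 21))
        if not 0 < lam < 1:
            raise ValueError("lambda_pos must lie in (0, 1)")
        if not 0 < r_ant <= r_max <= _MAX_REL_RADIUS:
            raise ValueError(f"require 0 < r_anterior <= r_max <= {_MAX_REL_RADIUS}")
        pos = np.unique(np.concatenate([np.linspace(0.0, 1.0, n + 2), [lam]]))

        def radius(l):
            l = np.asarray(l, dtype=float)
            ant = r_ant + (r_max - r_ant) * np.sin(np.pi * l / (2 * lam))
            post = r_max * np.cos(np.pi * (l - lam) / (2 * (1 - lam)))
            return np.where(l <= lam, ant, post)

        rad = radius(pos)
        rad[-1] = 0.0
        return MorphometricProfile(length, pos, rad, label=f"fusiform fixture (lambda={lam})")

    # random_monotone
    rng = np.random.default_rng(seed)
    n = int(params.get("n_interior", 5))
    rmax = params.get("max_radius", _MAX_REL_RADIUS)
    if not 0 < rmax <= _MAX_REL_RADIUS:
        raise ValueError(f"max_radius must lie in (0, {_MAX_REL_RADIUS}]")
    pos = np.sort(rng.uniform(0.01, 0.99, size=n))
    while np.any(np.diff(pos) < 1e-4):  # keep positions distinct
        pos = np.sort(rng.uniform(0.01, 0.99, size=n))
    rad = rng.uniform(0.1 * rmax, rmax, size=n)
    return MorphometricProfile(
        length,
        np.concatenate([[0.0], pos, [1.0]]),
        np.concatenate([[0.0], rad, [0.0]]),
        label=f"random fixture (seed={seed})",
    )
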