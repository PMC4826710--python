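"""The classical single- and three-parameter size estimators.

Three approximations are in long use in nematology:

* the **cylinder** of length ``L`` and diameter ``D``;
* **Andrássy's** estimator, the cylinder volume with a 4/5 correction
  factor;
* **Tsalolikhin's** estimator, the mean of the volumes of a cone
  (diameter ``D``, length ``L``) and a conical frustum (diameters ``D``
  and ``d``, length ``L``), which is exactly the volume of the composite
  shape made of an anterior frustum (``d`` to ``D`` over ``L/2``) and a
  posterior cone (``D`` to a point over ``L/2``).

The midlength assumption built into Tsalolikhin's estimator — that the
widest point sits at ``L/2`` — can be relaxed by weighting the two
halves by the actual fractional position ``lambda`` of the widest point;
the relative volume error ``epsilon_T`` of the midlength assumption then
has a closed form.
"""

from __future__ import annotations

import numpy as np

from .estimates import SizeEstimates
from .geometric import piecewise_estimates
from .morphometry import ClassicalShapeParams, MorphometricProfile

__all__ = [
    "cylinder_estimates",
    "andrassy_volume",
    "tsalolikhin_volume",
    "tsalolikhin_shape_estimates",
    "tsalolikhin_lambda_volume",
    "epsilon_T",
]


def cylinder_estimates(params: ClassicalShapeParams) -> SizeEstimates:
    """All four measures of the cylinder of length ``L`` and diameter ``D``.

    The perimeter and surface area include the two end caps:
    ``p = 2L + 2D`` and ``a_s = pi D L + pi D^2 / 2``.
    """
    L, D = params.length, params.max_diameter
    return SizeEstimates(
        perimeter=2.0 * L + 2.0 * D,
        projected_area=L * D,
        surface_area=np.pi * D * L + np.pi * D**2 / 2.0,
        volume=np.pi * L * (D / 2.0) ** 2,
        method="cylinder",
    )


def andrassy_volume(params: ClassicalShapeParams) -> float:
    """Andrássy's corrected cylinder volume, ``(4/5) pi L (D/2)^2``."""
    return 0.8 * cylinder_estimates(params).volume


def tsalolikhin_volume(params: ClassicalShapeParams) -> float:
    """Tsalolikhin's volume: mean of a cone and a frustum on ``(L, D, d)``.

    ``V_T = (pi L / 24) [(d^2 + d D + D^2) + D^2]``.
    """
    L, D, d = params.length, params.max_diameter, params.labial_diameter
    return np.pi * L / 24.0 * ((d**2 + d * D + D**2) + D**2)


def _tsalolikhin_profile(params: ClassicalShapeParams) -> MorphometricProfile:
    L, D, d = params.length, params.max_diameter, params.labial_diameter
    return MorphometricProfile(
        length=L,
        positions=[0.0, 0.5, 1.0],
        radii=[d / (2 * L), D / (2 * L), 0.0],
        label="tsalolikhin composite",
    )


def tsalolikhin_shape_estimates(params: ClassicalShapeParams) -> SizeEstimates:
    """All four measures of the explicit Tsalolikhin composite shape.

    The shape is the three-coordinate profile ``(0, d/2L)``, ``(1/2, D/2L)``,
    ``(1, 0)`` evaluated with the piecewise frustum model (anterior end cap
    included); its volume equals :func:`tsalolikhin_volume` exactly.
    """
    est = piecewise_estimates(_tsalolikhin_profile(params))
    return SizeEstimates(
        perimeter=est.perimeter,
        projected_area=est.projected_area,
        surface_area=est.surface_area,
        volume=est.volume,
        method="tsalolikhin",
    )


def tsalolikhin_lambda_volume(params: ClassicalShapeParams) -> float:
    """Position-weighted variant of Tsalolikhin's volume.

    With the widest point at fractional position ``lambda`` (taken from
    ``params.lambda_pos``)::

        V_Tlambda = (pi L / 3) [lambda (d^2 + d D) / 4 + D^2 / 4]

    which reduces to ``V_T`` at ``lambda = 1/2``.
    """
    L, D, d = params.length, params.max_diameter, params.labial_diameter
    lam = params.lambda_pos
    return np.pi * L / 3.0 * (lam * (d**2 + d * D) / 4.0 + D**2 / 4.0)


def epsilon_T(params: ClassicalShapeParams) -> float:
    """Relative volume error of the midlength assumption.

    ``epsilon_T = (V_T - V_Tlambda) / V_Tlambda
                = (1/2)(1 - 2 lambda) / (lambda + D^2 / (d^2 + d D))``

    dimensionless; negative whenever the widest point is posterior of the
    midpoint (``lambda > 1/2``).  The ratio only depends on ``d / D``.
    """
    D, d = params.max_diameter, params.labial_diameter
    lam = params.lambda_pos
    if d == 0 and D == 0:
        raise ValueError("epsilon_T undefined for d = D = 0")
    if d == 0:
        return 0.0  # degenerate frustum: the weighting drops out
    return 0.5 * (1.0 - 2.0 * lam) / (lam + D**2 / (d**2 + d * D))
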