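"""Container for the four size measures of an axisymmetric body."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Estimation methods understood throughout the package.
METHODS = ("cylinder", "andrassy", "tsalolikhin", "geometric", "bezier")


@dataclass(frozen=True)
class SizeEstimates:
    """Perimeter, projected area, surface area and volume of a nematode.

    All values are in SI units (m, m^2, m^2, m^3) unless the producing
    routine states otherwise (routines working in relative units return
    values scaled by L, L^2, L^2 and L^3 respectively).

    Attributes
    ----------
    perimeter : float
        Perimeter ``p`` of the two-dimensional silhouette (m).
    projected_area : float
        Area ``a`` of the silhouette as seen under the microscope (m^2).
    surface_area : float
        Surface area ``a_s`` of the solid of revolution (m^2).
    volume : float
        Volume ``v`` of the solid of revolution (m^3).
    method : str
        Which estimator produced these values (one of :data:`METHODS`).
    """

    perimeter: float
    projected_area: float
    surface_area: float
    volume: float
    method: str = field(default="geometric")

    def __post_init__(self) -> None:
        for name in ("perimeter", "projected_area", "surface_area", "volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "perimeter_m": self.perimeter,
            "projected_area_m2": self.projected_area,
            "surface_area_m2": self.surface_area,
            "volume_m3": self.volume,
        }

    def scaled(self, k: float) -> "SizeEstimates":
        """Return the estimates for the same shape with length scaled by ``k``."""
        return SizeEstimates(
            perimeter=self.perimeter * k,
            projected_area=self.projected_area * k**2,
            surface_area=self.surface_area * k**2,
            volume=self.volume * k**3,
            method=self.method,
        )
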