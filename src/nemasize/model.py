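"""Model/Results interface tying the estimators together.

:class:`NematodeSizeModel` wraps a morphometric profile; ``fit()``
evaluates the requested estimators (the Bézier one involves an actual
least-squares fit) and returns a :class:`NematodeSizeResults` carrying
the per-method size estimates, the comparison table with percent
differences against a reference method, and export/plotting helpers.

>>> model = NematodeSizeModel.from_cobb(ratios)
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classical, io as _io
from .bezier import OutlineModel, bezier_estimates, build_outline
from .estimates import METHODS, SizeEstimates
from .geometric import piecewise_estimates
from .morphometry import CobbRatios, MorphometricProfile, cobb_to_profile

__all__ = ["NematodeSizeModel", "NematodeSizeResults"]

_MEASURES = ("perimeter_m", "projected_area_m2", "surface_area_m2", "volume_m3")


class NematodeSizeModel:
    """Size-estimation model for a single nematode profile.

    Parameters
    ----------
    profile : MorphometricProfile
        The specimen's coordinate profile in relative units.
    """

    def __init__(self, profile: MorphometricProfile):
        self.profile = profile

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_cobb(cls, ratios: CobbRatios) -> "NematodeSizeModel":
        return cls(cobb_to_profile(ratios))

    @classmethod
    def from_file(cls, path) -> "NematodeSizeModel":
        """Build from a profile CSV or JSON file (documented dialect)."""
        return cls(_io.read_profile(path))

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        methods=METHODS,
        bezier_construction: str = "edited",
        quadrature_tol: float = 1e-10,
    ) -> "NematodeSizeResults":
        """Evaluate the requested estimators.

        ``cylinder``, ``andrassy`` and ``tsalolikhin`` derive their
        ``(L, D, d, lambda)`` parameters from the profile; ``geometric``
        uses the piecewise frustum model on all coordinates; ``bezier``
        fits the requested outline construction and integrates it.
        """
        unknown = set(methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; expected a subset of {METHODS}")
        params = self.profile.classical_params()
        estimates: dict[str, SizeEstimates] = {}
        outline: OutlineModel | None = None
        for method in methods:
            if method == "cylinder":
                estimates[method] = classical.cylinder_estimates(params)
            elif method == "andrassy":
                estimates[method] = SizeEstimates(
                    perimeter=0.0,
                    projected_area=0.0,
                    surface_area=0.0,
                    volume=classical.andrassy_volume(params),
                    method="andrassy",
                )
            elif method == "tsalolikhin":
                estimates[method] = classical.tsalolikhin_shape_estimates(params)
            elif method == "geometric":
                estimates[method] = piecewise_estimates(self.profile)
            elif method == "bezier":
                outline = build_outline(self.profile, bezier_construction)
                estimates[method] = bezier_estimates(outline, quadrature_tol)
        return NematodeSizeResults(model=self, estimates=estimates, outline=outline)


@dataclass
class NematodeSizeResults:
    """Fitted size estimates for one specimen.

    Attributes
    ----------
    model : NematodeSizeModel
    estimates : dict
        Method name -> :class:`SizeEstimates` (SI units).  Andrássy's
        approach defines only the volume; its other measures are
        reported as NaN in tables.
    outline : OutlineModel or None
        The fitted Bézier outline, when the ``bezier`` method was run.
    """

    model: NematodeSizeModel
    estimates: dict
    outline: OutlineModel | None = field(default=None)

    def table(self, reference: str | None = "geometric") -> pd.DataFrame:
        """Per-method measures, plus percent differences vs ``reference``.

        Percent differences are ``100 (x - x_ref) / x_ref``; Andrássy's
        undefined perimeter/area/surface entries are NaN.
        """
        rows = {}
        for method, est in self.estimates.items():
            row = est.to_dict()
            row.pop("method")
            if method == "andrassy":
                for key in _MEASURES[:3]:
                    row[key] = np.nan
            rows[method] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "method"
        if reference is not None:
            if reference not in df.index:
                raise ValueError(f"reference method {reference!r} was not fitted")
            for key in _MEASURES:
                ref = df.loc[reference, key]
                df[f"pct_diff_{key.rsplit('_', 1)[0]}"] = 100.0 * (df[key] - ref) / ref
        return df

    def percent_difference(
        self, method: str, measure: str = "volume_m3", reference: str = "geometric"
    ) -> float:
        """Percent difference of one method's measure against a reference."""
        a = self.estimates[method].to_dict()[measure]
        b = self.estimates[reference].to_dict()[measure]
        return 100.0 * (a - b) / b

    def summary(self, reference: str | None = "geometric") -> str:
        """Human-readable comparison table (4 significant figures)."""
        profile = self.model.profile
        df = self.table(reference)
        with pd.option_context("display.float_format", lambda v: f"{v:.4g}"):
            body = df.to_string()
        head = [
            "Nematode size estimates",
            "=" * 60,
            f"specimen: {profile.label or '(unnamed)'}",
            f"length L: {profile.length:.4g} m, coordinates: {profile.n_coords}",
        ]
        if reference is not None:
            head.append(f"percent differences relative to: {reference}")
        return "\n".join(head) + "\n" + body

    # -- export -------------------------------------------------------------

    def to_csv(self, path, reference: str | None = "geometric", full_precision: bool = True) -> None:
        fmt = "%.17g" if full_precision else "%.4g"
        self.table(reference).to_csv(path, float_format=fmt)

    def to_json(self, path, reference: str | None = "geometric") -> None:
        df = self.table(reference)
        Path(path).write_text(json.dumps(json.loads(df.to_json(orient="index")), indent=1) + "\n")

    def outline_to_svg(self, path, y_exaggeration: float = 1.0) -> None:
        if self.outline is None:
            raise ValueError("no Bézier outline was fitted; include 'bezier' in methods")
        _io.outline_to_svg(self.outline, path, y_exaggeration=y_exaggeration)
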