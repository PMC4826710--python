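"""File input/output: profile CSV/JSON dialects and SVG outline export.

The profile formats are deliberately explicit about conventions: the
metadata must state whether values are radii or diameters and whether
positions/values are percentages of the length, fractions of it, or
absolute metres.  Guessing is refused — the diameter/radius confusion is
the classic error in this literature.

CSV dialect::

    # units=percent            {percent|fraction|absolute}
    # value_kind=diameter      {radius|diameter}
    # length_m=0.0006
    # label=Aplectus antarcticus
    position,value
    0,0
    0.1,0.8
    ...

JSON carries the same keys: ``units``, ``value_kind``, ``length_m``,
``label`` and ``coordinates`` (a list of ``[position, value]`` pairs).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import MorphometricProfile

__all__ = [
    "read_profile",
    "read_profile_csv",
    "read_profile_json",
    "write_profile_csv",
    "write_profile_json",
    "outline_to_svg",
    "outline_to_csv",
]

UNITS = ("percent", "fraction", "absolute")
VALUE_KINDS = ("radius", "diameter")


def _normalize(positions, values, units: str, value_kind: str, length: float):
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if units not in UNITS:
        raise ValueError(f"units must be one of {UNITS}, got {units!r}")
    if value_kind not in VALUE_KINDS:
        raise ValueError(f"value_kind must be one of {VALUE_KINDS}, got {value_kind!r}")
    if units == "percent":
        positions = positions / 100.0
        values = values / 100.0
    elif units == "absolute":
        positions = positions / length
        values = values / length
    if value_kind == "diameter":
        values = values / 2.0
    return positions, values


def read_profile_csv(path) -> MorphometricProfile:
    """Read a profile from the documented CSV dialect."""
    text = Path(path).read_text()
    meta = {}
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    table = pd.read_csv(_io.StringIO(text), comment="#", float_precision="round_trip")
    return _build(meta, table, path)


def read_profile_json(path) -> MorphometricProfile:
    """Read a profile from the JSON mirror of the CSV dialect."""
    data = json.loads(Path(path).read_text())
    coords = data.get("coordinates")
    if not coords:
        raise ValueError(f"{path}: missing 'coordinates'")
    table = pd.DataFrame(coords, columns=["position", "value"])
    return _build(data, table, path)


def _build(meta: dict, table: pd.DataFrame, path) -> MorphometricProfile:
    for key in ("units", "value_kind", "length_m"):
        if key not in meta or meta[key] in (None, ""):
            raise ValueError(
                f"{path}: metadata key {key!r} is required "
                "(the radius/diameter and unit conventions are never guessed)"
            )
    if not {"position", "value"} <= set(table.columns):
        raise ValueError(f"{path}: expected columns 'position' and 'value'")
    length = float(meta["length_m"])
    positions, radii = _normalize(
        table["position"].to_numpy(),
        table["value"].to_numpy(),
        str(meta["units"]),
        str(meta["value_kind"]),
        length,
    )
    return MorphometricProfile(length, positions, radii, label=str(meta.get("label", "")))


def read_profile(path) -> MorphometricProfile:
    """Read a profile, dispatching on the file extension (.csv or .json)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return read_profile_json(path)
    if suffix == ".csv":
        return read_profile_csv(path)
    raise ValueError(f"unsupported profile format {suffix!r}; expected .csv or .json")


def write_profile_csv(profile: MorphometricProfile, path) -> None:
    """Write a profile in the CSV dialect (fraction/radius conventions)."""
    lines = [
        "# units=fraction",
        "# value_kind=radius",
        f"# length_m={profile.length!r}",
        f"# label={profile.label}",
        "position,value",
    ]
    lines += [f"{float(p)!r},{float(r)!r}" for p, r in zip(profile.positions, profile.radii)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile_json(profile: MorphometricProfile, path) -> None:
    data = {
        "units": "fraction",
        "value_kind": "radius",
        "length_m": profile.length,
        "label": profile.label,
        "coordinates": [[float(p), float(r)] for p, r in zip(profile.positions, profile.radii)],
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


# -- SVG / CSV outline export ----------------------------------------------


def _path_d(points: np.ndarray) -> str:
    return "M " + " L ".join(f"{x:.6g},{y:.6g}" for x, y in points)


def outline_to_svg(outline, path, y_exaggeration: float = 1.0, samples: int = 512) -> None:
    """Export a mirrored outline as an SVG 1.1 document.

    The drawing is in relative units with the y axis exaggerated by
    ``y_exaggeration`` (the conventional 10x makes slender bodies
    legible).
    """
    s = outline.sample(samples)
    ey = float(y_exaggeration)
    upper = s["upper"] * np.array([1.0, -ey])  # SVG y grows downwards
    lower = s["lower"] * np.array([1.0, -ey])
    ymax = max(abs(upper[:, 1]).max(), abs(lower[:, 1]).max(), 1e-6)
    pad = 0.05
    closed = np.vstack([upper, lower[::-1], upper[:1]])
    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'viewBox="{-pad} {-(ymax + pad)} {1 + 2 * pad} {2 * (ymax + pad)}">\n'
        f'  <title>{outline.label or "nematode outline"} ({outline.construction}, '
        f"y x{ey:g})</title>\n"
        f'  <path d="{_path_d(closed)} Z" fill="none" stroke="black" '
        f'stroke-width="{(ymax + pad) / 200:.6g}"/>\n'
        "</svg>\n"
    )
    Path(path).write_text(svg)


def outline_to_csv(outline, path, samples: int = 512) -> None:
    """Write the sampled outline as CSV columns x,y_upper,y_lower."""
    s = outline.sample(samples)
    df = pd.DataFrame(
        {"x": s["upper"][:, 0], "y_upper": s["upper"][:, 1], "y_lower": s["lower"][:, 1]}
    )
    df.to_csv(path, index=False, float_format="%.17g")
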