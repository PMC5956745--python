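"""Vesicle morphometry on annotated presynaptic terminal geometry.

Works on 2-D section annotations (nm): a terminal outline polygon,
organelle polygons, active-zone (AZ) polylines and vesicle centres with
diameters.  Three families of statistics are computed: grid-based vesicle
density (0.1 μm² squares; squares touching the terminal border or an
organelle are excluded), AZ proximity counts (centres < 100 nm from an AZ,
normalised per 50 nm of AZ length) and membrane-adjacent counts (centre
within one diameter of the AZ, i.e. the vesicle edge within one radius).
Analysis is strictly 2-D, as appropriate for thin sections; no
stereological correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box


class GeometryError(ValueError):
    """Raised on degenerate annotation geometry."""


@dataclass
class TerminalAnnotation:
    """EM annotation of one presynaptic terminal (coordinates in nm).

    ``vesicles`` is a DataFrame with columns ``x_nm, y_nm, diameter_nm``.
    ``scale_nm_per_px`` records the acquisition scale; files store raw
    pixel coordinates which are converted to nm on load.
    """

    terminal: list[tuple[float, float]]
    organelles: list[list[tuple[float, float]]] = field(default_factory=list)
    active_zones: list[list[tuple[float, float]]] = field(default_factory=list)
    vesicles: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["x_nm", "y_nm", "diameter_nm"]))
    scale_nm_per_px: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        poly = self.terminal_polygon
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError("terminal polygon is degenerate")
        for org in self.organelle_polygons:
            if not org.is_valid or org.area <= 0:
                raise GeometryError("organelle polygon is degenerate")
        if len(self.vesicles):
            d = self.vesicles["diameter_nm"].to_numpy(float)
            if np.any(d <= 0):
                raise GeometryError("vesicle diameters must be positive")

    @property
    def terminal_polygon(self) -> Polygon:
        return Polygon(self.terminal)

    @property
    def organelle_polygons(self) -> list[Polygon]:
        return [Polygon(p) for p in self.organelles]

    @property
    def az_linestrings(self) -> list[LineString]:
        return [LineString(a) for a in self.active_zones]

    @property
    def n_vesicles(self) -> int:
        return len(self.vesicles)


@dataclass
class VesicleStats:
    """Derived per-terminal vesicle statistics."""

    density: float                 # vesicles per um^2 (grid-based)
    n_valid_squares: int
    proximal_per_az: float         # mean count of vesicles < 100 nm per AZ
    proximal_per_50nm: float       # mean per-AZ count per 50 nm of AZ length
    adjacent_per_az: float
    adjacent_per_50nm: float
    mean_diameter: float           # nm
    sd_diameter: float             # nm (nan for a single vesicle)
    n_vesicles: int
    label: str = ""

    def to_row(self) -> dict:
        return {
            "terminal": self.label,
            "density_per_um2": self.density,
            "n_valid_squares": self.n_valid_squares,
            "proximal_per_az": self.proximal_per_az,
            "proximal_per_50nm": self.proximal_per_50nm,
            "adjacent_per_az": self.adjacent_per_az,
            "adjacent_per_50nm": self.adjacent_per_50nm,
            "mean_diameter_nm": self.mean_diameter,
            "sd_diameter_nm": self.sd_diameter,
            "n_vesicles": self.n_vesicles,
        }


# ---------------------------------------------------------------------------
# Annotation file format (JSON, raw pixel coordinates plus scale)
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> TerminalAnnotation:
    """Read a terminal-annotation JSON file; pixel coords scaled to nm."""
    with open(path) as fh:
        raw = json.load(fh)
    s = float(raw.get("scale_nm_per_px", 1.0))
    scale_pts = lambda pts: [(x * s, y * s) for x, y in pts]
    ves = raw.get("vesicles", [])
    df = pd.DataFrame({
        "x_nm": [v["x"] * s for v in ves],
        "y_nm": [v["y"] * s for v in ves],
        "diameter_nm": [v["diameter"] * s for v in ves],
    })
    return TerminalAnnotation(
        terminal=scale_pts(raw["terminal"]),
        organelles=[scale_pts(p) for p in raw.get("organelles", [])],
        active_zones=[scale_pts(p) for p in raw.get("active_zones", [])],
        vesicles=df,
        scale_nm_per_px=s,
        label=str(raw.get("label", Path(path).stem)),
    )


def write_annotation(ann: TerminalAnnotation, path: str | Path) -> None:
    """Write an annotation JSON (coordinates stored as raw pixels)."""
    s = ann.scale_nm_per_px
    unscale = lambda pts: [[x / s, y / s] for x, y in pts]
    data = {
        "scale_nm_per_px": s,
        "label": ann.label,
        "terminal": unscale(ann.terminal),
        "organelles": [unscale(p) for p in ann.organelles],
        "active_zones": [unscale(p) for p in ann.active_zones],
        "vesicles": [
            {"x": r.x_nm / s, "y": r.y_nm / s, "diameter": r.diameter_nm / s}
            for r in ann.vesicles.itertuples()
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def grid_density(
    ann: TerminalAnnotation,
    square_area_um2: float = 0.1,
    grid_origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, int]:
    """Grid-based vesicle density (per μm²) and the number of valid squares.

    An axis-aligned grid of squares of side sqrt(area) is anchored at
    ``grid_origin``; a square is valid iff it lies fully inside the
    terminal and intersects no organelle.  Density is the number of vesicle
    centres falling in valid squares divided by the total valid area.
    """
    term = ann.terminal_polygon
    side = np.sqrt(square_area_um2) * 1000.0  # nm
    if term.area < 4 * side * side:
        raise GeometryError("terminal smaller than 4 grid squares")
    orgs = ann.organelle_polygons
    minx, miny, maxx, maxy = term.bounds
    ox, oy = grid_origin
    ix0 = int(np.floor((minx - ox) / side))
    ix1 = int(np.ceil((maxx - ox) / side))
    iy0 = int(np.floor((miny - oy) / side))
    iy1 = int(np.ceil((maxy - oy) / side))
    valid: set[tuple[int, int]] = set()
    for ix in range(ix0, ix1 + 1):
        for iy in range(iy0, iy1 + 1):
            sq = box(ox + ix * side, oy + iy * side,
                     ox + (ix + 1) * side, oy + (iy + 1) * side)
            if not sq.within(term):
                continue
            if any(sq.intersects(org) for org in orgs):
                continue
            valid.add((ix, iy))
    if not valid:
        raise GeometryError("no valid grid squares inside the terminal")
    if len(ann.vesicles):
        x = ann.vesicles["x_nm"].to_numpy(float)
        y = ann.vesicles["y_nm"].to_numpy(float)
        ix = np.floor((x - ox) / side).astype(int)
        iy = np.floor((y - oy) / side).astype(int)
        count = sum((a, b) in valid for a, b in zip(ix, iy))
    else:
        count = 0
    density = count / (len(valid) * square_area_um2)
    return float(density), len(valid)


def grid_density_profile(
    ann: TerminalAnnotation,
    square_area_um2: float = 0.1,
    n_offsets: int = 4,
) -> pd.DataFrame:
    """Density across ``n_offsets`` grid origin offsets (robustness check)."""
    side = np.sqrt(square_area_um2) * 1000.0
    rows = []
    for j in range(n_offsets):
        off = j * side / n_offsets
        d, n = grid_density(ann, square_area_um2, grid_origin=(off, off))
        rows.append({"offset_nm": off, "density_per_um2": d,
                     "n_valid_squares": n})
    return pd.DataFrame(rows)


def _nearest_az_distances(ann: TerminalAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """Per-vesicle (nearest-AZ index, centre distance in nm)."""
    azs = ann.az_linestrings
    if not azs:
        raise GeometryError("annotation has no active zones")
    for az in azs:
        if az.length <= 0:
            raise GeometryError("zero-length active-zone polyline")
    pts = [Point(x, y) for x, y in
           zip(ann.vesicles["x_nm"], ann.vesicles["y_nm"])]
    dists = np.array([[az.distance(p) for az in azs] for p in pts]
                     ) if pts else np.empty((0, len(azs)))
    if dists.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    return dists.argmin(axis=1), dists.min(axis=1)


def az_proximity_counts(
    ann: TerminalAnnotation,
    proximity_nm: float = 100.0,
    unit_nm: float = 50.0,
) -> tuple[float, float]:
    """Mean proximal vesicle count per AZ and per ``unit_nm`` of AZ length.

    A vesicle is proximal when its centre lies < ``proximity_nm`` from its
    nearest AZ polyline; each vesicle counts toward that AZ only.
    """
    azs = ann.az_linestrings
    nearest, dist = _nearest_az_distances(ann)
    counts = np.zeros(len(azs))
    for a, d in zip(nearest, dist):
        if d < proximity_nm:
            counts[a] += 1
    lengths = np.array([az.length for az in azs])
    per_unit = counts / (lengths / unit_nm)
    return float(counts.mean()), float(per_unit.mean())


def membrane_adjacent_counts(
    ann: TerminalAnnotation,
    unit_nm: float = 50.0,
) -> tuple[float, float]:
    """Membrane-adjacent counts per AZ and per ``unit_nm`` of AZ length.

    A vesicle is membrane-adjacent when its edge lies within one of its own
    radii of the AZ, i.e. centre distance <= its diameter.
    """
    azs = ann.az_linestrings
    nearest, dist = _nearest_az_distances(ann)
    diam = ann.vesicles["diameter_nm"].to_numpy(float)
    counts = np.zeros(len(azs))
    for a, d, dm in zip(nearest, dist, diam):
        if d <= dm:
            counts[a] += 1
    lengths = np.array([az.length for az in azs])
    per_unit = counts / (lengths / unit_nm)
    return float(counts.mean()), float(per_unit.mean())


def diameter_stats(ann: TerminalAnnotation) -> tuple[float, float, int]:
    """Per-terminal mean and SD (nm) of annotated vesicle diameters."""
    d = ann.vesicles["diameter_nm"].to_numpy(float)
    if d.size < 1:
        raise ValueError("annotation has no vesicles")
    sd = float(d.std(ddof=1)) if d.size > 1 else float("nan")
    return float(d.mean()), sd, int(d.size)


def percent_change(before: float, after: float) -> float:
    """Percent reduction 100*(before - after)/before."""
    if before == 0:
        raise ValueError("undefined percent change from zero")
    return 100.0 * (before - after) / before


def vesicle_stats(
    ann: TerminalAnnotation,
    square_area_um2: float = 0.1,
    proximity_nm: float = 100.0,
    unit_nm: float = 50.0,
    grid_origin: tuple[float, float] = (0.0, 0.0),
) -> VesicleStats:
    """All per-terminal statistics in one VesicleStats record."""
    density, n_sq = grid_density(ann, square_area_um2, grid_origin)
    if ann.active_zones:
        prox_az, prox_unit = az_proximity_counts(ann, proximity_nm, unit_nm)
        adj_az, adj_unit = membrane_adjacent_counts(ann, unit_nm)
    else:
        prox_az = prox_unit = adj_az = adj_unit = float("nan")
    mean_d, sd_d, n = diameter_stats(ann)
    return VesicleStats(
        density=density, n_valid_squares=n_sq,
        proximal_per_az=prox_az, proximal_per_50nm=prox_unit,
        adjacent_per_az=adj_az, adjacent_per_50nm=adj_unit,
        mean_diameter=mean_d, sd_diameter=sd_d, n_vesicles=n,
        label=ann.label)
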