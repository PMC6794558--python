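"""Voronoi-cell areas of interest around fixation-density centroids.

Each centroid generates the cell of screen locations closer to it than to
any other centroid; cell boundaries are the perpendicular bisectors between
neighbouring sites.  Cells are clipped to the screen rectangle by
half-plane intersection, so together they tile the full stimulus frame.
Semantic labels ("Face", "Target", ...) are attached by an explicit,
auditable mapping; unlabeled cells default to "Background".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .clustering import CentroidSet
from .events import FixationSet
from .geometry import ScreenGeometry

__all__ = [
    "VoronoiCell",
    "AOIMap",
    "build_voronoi",
    "label_cells",
    "assign_fixations",
    "assign_by_containment",
    "OFF_SCREEN_LABEL",
    "BACKGROUND_LABEL",
]

OFF_SCREEN_LABEL = "off_screen"
BACKGROUND_LABEL = "Background"


@dataclass(frozen=True)
class VoronoiCell:
    """One convex AOI cell: its generating centroid, clipped polygon, label."""

    centroid: tuple
    polygon: Polygon
    label: str = "unlabeled"

    @property
    def area(self) -> float:
        return float(self.polygon.area)


@dataclass
class AOIMap:
    """Screen-tiling set of labeled Voronoi cells for one stimulus."""

    stimulus_id: str
    cells: list
    geometry: ScreenGeometry

    @property
    def sites(self) -> np.ndarray:
        return np.array([c.centroid for c in self.cells], dtype=float)

    @property
    def labels(self) -> list:
        return [c.label for c in self.cells]

    def total_area(self) -> float:
        return float(sum(c.area for c in self.cells))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.cells):
            verts = ";".join(f"{x:.6f},{y:.6f}" for x, y in c.polygon.exterior.coords)
            rows.append(
                {
                    "stimulus": self.stimulus_id,
                    "cell": i,
                    "label": c.label,
                    "site_x": c.centroid[0],
                    "site_y": c.centroid[1],
                    "area_px2": c.area,
                    "vertices": verts,
                }
            )
        return pd.DataFrame(rows)


def _halfplane(si: np.ndarray, sj: np.ndarray, extent: float) -> Polygon:
    """Polygon covering the half-plane of points closer to si than sj."""
    mid = 0.5 * (si + sj)
    d = sj - si
    nrm = d / np.linalg.norm(d)
    u = np.array([-nrm[1], nrm[0]])  # along the bisector
    a = mid + u * extent
    b = mid - u * extent
    return Polygon([a, b, b - nrm * extent, a - nrm * extent])


def build_voronoi(cs: CentroidSet | np.ndarray, geometry: ScreenGeometry,
                  stimulus_id: str | None = None) -> AOIMap:
    """Tessellate the screen rectangle into one clipped cell per centroid.

    A single centroid yields one cell equal to the whole screen.  Unbounded
    outer regions are clipped by intersecting each site's bisector
    half-planes with the screen rectangle, so the cells tile the frame
    exactly.  Deterministic; duplicate sites raise ``ValueError``.
    """
    if isinstance(cs, CentroidSet):
        sites = np.asarray(cs.centroids, dtype=float)
        stim = stimulus_id if stimulus_id is not None else cs.stimulus_id
    else:
        sites = np.atleast_2d(np.asarray(cs, dtype=float))
        stim = stimulus_id or ""
    if sites.size == 0:
        raise ValueError("build_voronoi requires at least one centroid")
    for sx, sy in sites:
        if not geometry.contains(sx, sy):
            raise ValueError(f"centroid ({sx:.1f}, {sy:.1f}) outside the screen rectangle")
    if len(sites) > 1:
        from scipy.spatial.distance import pdist

        if pdist(sites).min() == 0.0:
            raise ValueError("degenerate sites: duplicate centroids")
    screen = box(0.0, 0.0, float(geometry.raster_width), float(geometry.raster_height))
    extent = 4.0 * (geometry.raster_width + geometry.raster_height)
    cells = []
    for i, si in enumerate(sites):
        poly = screen
        for j, sj in enumerate(sites):
            if i == j:
                continue
            poly = poly.intersection(_halfplane(si, sj, extent))
        if poly.is_empty or poly.area <= 0:
            raise ValueError(f"degenerate sites: empty cell for centroid {i}")
        cells.append(VoronoiCell(centroid=(float(si[0]), float(si[1])), polygon=poly))
    return AOIMap(stimulus_id=stim, cells=cells, geometry=geometry)


def label_cells(aoi: AOIMap, labels: dict) -> AOIMap:
    """Attach semantic labels to cells by centroid index.

    Cells absent from ``labels`` default to "Background" (screen regions
    outside the semantically named AOIs).  Several cells may share a label;
    metrics pool them.  Geometry is untouched.
    """
    n = len(aoi.cells)
    for idx in labels:
        if not (isinstance(idx, (int, np.integer)) and 0 <= idx < n):
            raise KeyError(f"unknown cell index {idx!r} (map has {n} cells)")
    cells = [
        replace(cell, label=str(labels.get(i, BACKGROUND_LABEL)))
        for i, cell in enumerate(aoi.cells)
    ]
    return AOIMap(stimulus_id=aoi.stimulus_id, cells=cells, geometry=aoi.geometry)


def _nearest_site(aoi: AOIMap, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    sites = aoi.sites
    d2 = (x[:, None] - sites[None, :, 0]) ** 2 + (y[:, None] - sites[None, :, 1]) ** 2
    # argmin returns the first (lowest-index) minimiser: the boundary tie-break
    return np.argmin(d2, axis=1)


def assign_fixations(fs: FixationSet, aoi: AOIMap) -> pd.DataFrame:
    """Map each fixation to the AOI cell containing its centroid.

    On-screen fixations are assigned to the nearest centroid (equivalently,
    the containing polygon; ties on a cell boundary break to the lowest
    centroid index).  Off-screen fixations get cell -1 and the
    "off_screen" label.
    """
    df = fs.to_frame()
    if df.empty:
        df["cell"] = pd.Series(dtype=int)
        df["aoi_label"] = pd.Series(dtype=object)
        return df
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    on = (
        (x >= 0)
        & (x < aoi.geometry.raster_width)
        & (y >= 0)
        & (y < aoi.geometry.raster_height)
    )
    cell = np.full(len(df), -1, dtype=int)
    if on.any():
        cell[on] = _nearest_site(aoi, x[on], y[on])
    labels = np.array(aoi.labels + [OFF_SCREEN_LABEL], dtype=object)
    df["cell"] = cell
    df["aoi_label"] = labels[cell]
    return df


def assign_by_containment(aoi: AOIMap, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cell index per point by polygon containment (dual of nearest-site).

    Points on shared boundaries are resolved to the lowest containing cell
    index; off-screen points get -1.
    """
    out = np.full(len(x), -1, dtype=int)
    for k in range(len(x)):
        p = Point(float(x[k]), float(y[k]))
        for i, cell in enumerate(aoi.cells):
            if cell.polygon.covers(p):
                out[k] = i
                break
    return out
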