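"""Tile-based segmentation plumbing and alpha-shape cell boundaries.

The section is subdivided into overlapping tiles (default 350 μm with 50 μm
overlap), a pluggable per-tile segmenter produces a label volume, transcripts
are assigned to the label of their containing voxel, and per-tile assignments
are stitched with a share-fraction merge rule: if more than half of a smaller
cell's transcripts are shared with a larger cell the two are merged, otherwise
each contested transcript goes to the cell from the later-processed tile.
Cell boundaries are per-z-plane alpha shapes of the assigned transcript
positions, stacked into a pseudo-3D representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, MultiPolygon, Polygon
from shapely.ops import unary_union

from .core import ConfigurationError
from .density import VolumeImage

__all__ = [
    "Tile",
    "LabelVolume",
    "PolygonPlane",
    "CellPolygonStack",
    "make_tiles",
    "segment_tile",
    "assign_transcripts",
    "stitch_and_merge",
    "build_cell_polygons",
    "compute_geometry",
]


@dataclass(frozen=True)
class Tile:
    index: int
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y):
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)


@dataclass
class LabelVolume:
    """Integer label grid (0 = background) sharing VolumeImage geometry."""

    labels: np.ndarray
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def voxel_of(self, x, y, z):
        return VolumeImage(self.labels, self.origin, self.voxel_size).voxel_of(x, y, z)


@dataclass
class PolygonPlane:
    z: float
    polygon: Optional[Polygon]
    alpha_used: Optional[float] = None


@dataclass
class CellPolygonStack:
    """Closed simple polygons on consecutive z-planes for one cell."""

    planes: List[PolygonPlane] = field(default_factory=list)
    alpha_scale: float = 0.75

    @property
    def has_boundary(self) -> bool:
        return any(p.polygon is not None for p in self.planes)


def make_tiles(extent, tile_size: float = 350.0, overlap: float = 50.0) -> List[Tile]:
    """Row-major overlapping tiling of a rectangular extent ``(x0,y0,x1,y1)``.

    Tiles stride by ``tile_size - overlap`` from the minimum corner; an extent
    smaller than one tile yields a single tile covering the extent.
    """
    if not tile_size > overlap >= 0:
        raise ConfigurationError("require tile_size > overlap >= 0")
    x0, y0, x1, y1 = map(float, extent)
    stride = tile_size - overlap

    def starts(lo, hi):
        span = hi - lo
        if span <= tile_size:
            return [lo]
        n = int(math.ceil((span - tile_size) / stride)) + 1
        return [lo + i * stride for i in range(n)]

    tiles = []
    idx = 0
    for ty in starts(y0, y1):
        for tx in starts(x0, x1):
            tiles.append(Tile(idx, tx, ty, min(tx + tile_size, x1), min(ty + tile_size, y1)))
            idx += 1
    return tiles


def segment_tile(
    dapi: VolumeImage,
    density: VolumeImage,
    backend: str = "builtin",
    threshold: Optional[float] = None,
    min_peak_distance: int = 3,
) -> LabelVolume:
    """Run the per-tile segmenter and return a label volume on the same grid.

    ``builtin`` thresholds the density stain and runs a distance-transform
    watershed seeded on density maxima; ``cellpose`` delegates to the external
    volumetric Cellpose model when installed.
    """
    if dapi.shape != density.shape:
        raise ConfigurationError("dapi and density images must share geometry")
    if backend == "cellpose":
        try:
            from cellpose import models  # noqa: F401
        except ImportError as exc:  # pragma: no cover - external backend
            raise ConfigurationError("cellpose backend requested but cellpose is not installed") from exc
        raise ConfigurationError("cellpose backend is external; run it out-of-process and feed labels in")
    if backend != "builtin":
        raise ConfigurationError(f"unknown segmentation backend {backend!r}")

    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from skimage.segmentation import watershed

    vals = density.values.astype(float)
    if not np.any(vals > 0):
        return LabelVolume(np.zeros(vals.shape, dtype=np.int32), density.origin, density.voxel_size)
    if threshold is None:
        pos = vals[vals > 0]
        threshold = threshold_otsu(pos) if pos.size > 1 and np.ptp(pos) > 0 else 0.0
    mask = vals > threshold
    if not mask.any():
        return LabelVolume(np.zeros(vals.shape, dtype=np.int32), density.origin, density.voxel_size)
    peaks = peak_local_max(vals, min_distance=min_peak_distance, labels=mask, exclude_border=False)
    markers = np.zeros(vals.shape, dtype=np.int32)
    for i, p in enumerate(peaks, start=1):
        markers[tuple(p)] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(mask)
    labels = watershed(-vals, markers=markers, mask=mask)
    return LabelVolume(labels.astype(np.int32), density.origin, density.voxel_size)


def assign_transcripts(spots: pd.DataFrame, labels: LabelVolume, tile_index: int = 0) -> pd.DataFrame:
    """Assign each transcript the label of its containing voxel.

    Background (label 0) and out-of-volume transcripts stay unassigned; the
    output has exactly one row per input transcript with columns
    ``transcript_id, cell_id, tile_index``. Cell ids are strings
    ``"t{tile}-c{label}"`` so they stay unique across tiles before stitching.
    """
    n = len(spots)
    cell_id = np.full(n, None, dtype=object)
    if n:
        iz, iy, ix = labels.voxel_of(spots["x"].to_numpy(), spots["y"].to_numpy(), spots["z"].to_numpy())
        nz, ny, nx = labels.labels.shape
        ok = (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        lab = np.zeros(n, dtype=np.int64)
        lab[ok] = labels.labels[iz[ok], iy[ok], ix[ok]]
        hit = lab > 0
        cell_id[hit] = [f"t{tile_index}-c{v}" for v in lab[hit]]
    return pd.DataFrame(
        {"transcript_id": spots["transcript_id"].to_numpy(), "cell_id": cell_id, "tile_index": tile_index}
    )


def stitch_and_merge(per_tile: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Stitch per-tile assignment tables into one table with ≤1 cell per transcript.

    Tiles are processed in increasing ``tile_index`` (the row-major tiling
    order); a tile processed later is the "newer" one. For each pair of cells
    sharing transcripts in an overlap region, with ``s`` the shared fraction of
    the smaller cell's transcripts (size = transcript count, ties broken by
    lexicographic id): if ``s > 0.5`` (strict) the smaller cell is merged into
    the larger one, otherwise every contested transcript is reassigned to the
    newer tile's cell.
    """
    assigned: dict = {}  # transcript_id -> cell id
    members: dict = {}  # cell id -> set of transcript_ids
    tiles = sorted(per_tile, key=lambda t: int(t["tile_index"].iloc[0]) if len(t) else 0)
    order: list = []  # transcript ids in first-seen order
    seen = set()

    for table in tiles:
        tile_idx = int(table["tile_index"].iloc[0]) if len(table) else 0
        for tid in table["transcript_id"]:
            if tid not in seen:
                seen.add(tid)
                order.append(tid)
        rows = table.dropna(subset=["cell_id"])
        for new_cell, group in rows.groupby("cell_id", sort=True):
            new_tids = set(group["transcript_id"])
            current = str(new_cell)
            members.setdefault(current, set())
            # transcripts already claimed by earlier cells, keyed by that cell
            overlaps: dict = {}
            for tid in new_tids:
                old = assigned.get(tid)
                if old is not None and old != current:
                    overlaps.setdefault(old, set()).add(tid)
            pending = set(new_tids)
            for old, shared in sorted(overlaps.items()):
                old = assigned.get(next(iter(shared)))  # follow merges applied this round
                if old == current:
                    continue
                size_new = len(members[current] | pending)
                size_old = len(members[old])
                if (size_new, current) < (size_old, old):
                    smaller, larger = current, old
                    smaller_size = size_new
                else:
                    smaller, larger = old, current
                    smaller_size = size_old
                s = len(shared) / smaller_size if smaller_size else 0.0
                if s > 0.5:
                    # merge smaller into larger
                    for tid in members[smaller]:
                        assigned[tid] = larger
                    members[larger] |= members[smaller]
                    members.pop(smaller)
                    if smaller == current:
                        current = larger
                        members.setdefault(current, set())
                else:
                    # contested transcripts go to the newer (current) cell
                    for tid in shared:
                        assigned[tid] = current
                        members[old].discard(tid)
                        members[current].add(tid)
            for tid in pending:
                if assigned.get(tid) is None or assigned.get(tid) == current or tid not in assigned:
                    assigned[tid] = current
                    members[current].add(tid)
        # unassigned rows: remember the transcript exists
        for tid in table.loc[table["cell_id"].isna(), "transcript_id"]:
            assigned.setdefault(tid, None)

    out = pd.DataFrame({"transcript_id": order})
    out["cell_id"] = [assigned.get(t) for t in order]
    out["tile_index"] = 0
    # recover the tile index of the winning cell where parseable
    tile_of = {}
    for table in tiles:
        ti = int(table["tile_index"].iloc[0]) if len(table) else 0
        for c in table["cell_id"].dropna().unique():
            tile_of.setdefault(c, ti)
    out["tile_index"] = [tile_of.get(c, -1) if c is not None else -1 for c in out["cell_id"]]
    return out


def _triangle_circumradius(pts: np.ndarray) -> float:
    a = np.linalg.norm(pts[1] - pts[0])
    b = np.linalg.norm(pts[2] - pts[1])
    c = np.linalg.norm(pts[0] - pts[2])
    area2 = abs(
        (pts[1][0] - pts[0][0]) * (pts[2][1] - pts[0][1])
        - (pts[2][0] - pts[0][0]) * (pts[1][1] - pts[0][1])
    )
    if area2 == 0:
        return np.inf
    return a * b * c / (2 * area2)


def _delaunay_triangles(points: np.ndarray):
    """Delaunay triangle polygons and their circumradii, or None if degenerate."""
    try:
        tri = Delaunay(points)
    except QhullError:
        return None
    polys, radii = [], []
    for simplex in tri.simplices:
        pts = points[simplex]
        polys.append(Polygon(pts))
        radii.append(_triangle_circumradius(pts))
    return polys, np.asarray(radii)


def _alpha_shape(points: np.ndarray, radius: float):
    """Union of Delaunay triangles whose circumradius is at most ``radius``."""
    tri = _delaunay_triangles(points)
    if tri is None:
        return None
    polys, radii = tri
    kept = [p for p, r in zip(polys, radii) if r <= radius]
    if not kept:
        return Polygon()
    return unary_union(kept)


def _is_single_closed_polygon(geom) -> bool:
    return isinstance(geom, Polygon) and not geom.is_empty and geom.is_valid


def build_cell_polygons(
    cell_spots: pd.DataFrame,
    alpha_scale: float = 0.75,
) -> CellPolygonStack:
    """Per-z-plane alpha-shape boundaries for one cell's transcripts.

    On each plane the alpha parameter (inverse circumradius threshold) is
    chosen as the maximum alpha whose alpha shape is a single closed polygon,
    then multiplied by ``alpha_scale``. The search is a binary search over the
    sorted triangle circumradii — the predicate can only change at those
    values, so this is the exact limit a bisection converges to, with ties
    toward smaller alpha. If the scaled alpha still yields multiple components
    the largest-area one is kept. Planes with fewer than three non-collinear
    points get a null boundary.
    """
    stack = CellPolygonStack(alpha_scale=alpha_scale)
    for z, group in cell_spots.groupby("z", sort=True):
        pts = np.unique(group[["x", "y"]].to_numpy(dtype=float), axis=0)
        plane = PolygonPlane(z=float(z), polygon=None)
        stack.planes.append(plane)
        if len(pts) < 3:
            continue
        tri = _delaunay_triangles(pts)
        if tri is None:  # collinear
            continue
        polys, radii = tri

        def shape_at(radius):
            kept = [p for p, r in zip(polys, radii) if r <= radius]
            return unary_union(kept) if kept else Polygon()

        finite = np.unique(radii[np.isfinite(radii)])
        if finite.size == 0:
            continue
        if not _is_single_closed_polygon(shape_at(finite[-1])):
            hull = MultiPoint([tuple(p) for p in pts]).convex_hull
            if isinstance(hull, Polygon):
                plane.polygon = hull
                plane.alpha_used = 1.0 / float(finite[-1])
            continue
        # minimal circumradius threshold whose shape is one closed polygon
        lo, hi = 0, finite.size - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if _is_single_closed_polygon(shape_at(finite[mid])):
                hi = mid
            else:
                lo = mid + 1
        r_crit = float(finite[lo])
        r_used = r_crit / alpha_scale if alpha_scale > 0 else r_crit
        geom = shape_at(r_used)
        if geom is None or geom.is_empty:
            geom = shape_at(r_crit)
        if isinstance(geom, MultiPolygon):
            geom = max(geom.geoms, key=lambda g: g.area)
        if isinstance(geom, Polygon) and not geom.is_empty:
            plane.polygon = geom
            plane.alpha_used = 1.0 / r_used
    return stack


def compute_geometry(stack: CellPolygonStack, z_spacing: float = 1.0):
    """Pseudo-3D geometry of a polygon stack.

    Volume is the sum of plane areas times the z spacing; the reported 2D area
    is the maximum single-plane area; the centroid is the area-weighted mean
    of per-plane polygon centroids (z from the plane positions). A null
    boundary gives zero volume and area and a NaN centroid.
    """
    areas, cxs, cys, zs = [], [], [], []
    for plane in stack.planes:
        if plane.polygon is None or plane.polygon.is_empty:
            continue
        areas.append(plane.polygon.area)
        c = plane.polygon.centroid
        cxs.append(c.x), cys.append(c.y), zs.append(plane.z)
    if not areas:
        return 0.0, 0.0, (np.nan, np.nan, np.nan)
    areas = np.asarray(areas)
    w = areas / areas.sum()
    centroid = (float(np.dot(w, cxs)), float(np.dot(w, cys)), float(np.dot(w, zs)))
    return float(areas.sum() * z_spacing), float(areas.max()), centroid
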