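"""Atlas registration of cell centroids from section-alignment files.

Manual alignment tools export, per tissue section, a linear anchoring (a 3×3
affine mapping normalized section coordinates to 3D atlas coordinates, stored
as anchoring vectors o, u, v) and a set of landmark pairs for a non-linear
correction. This module applies those files to cell centroids: a piecewise
barycentric warp over the Delaunay triangulation of the source landmarks, the
section-to-atlas affine, an optional atlas scaling matrix, and region lookup
in a labeled annotation volume (25 μm voxels).

Fixture schema (mirrors the real files):
  anchoring JSON: {"slices": [{"filename", "nr", "width", "height",
                               "anchoring": [ox,oy,oz, ux,uy,uz, vx,vy,vz]}]}
  landmark JSON:  {"slices": [{"filename", "markers":
                               [[src_x, src_y, tgt_x, tgt_y], ...]}]}
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .core import ConsistencyError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "SectionAnchor",
    "LandmarkSet",
    "AnnotationVolume",
    "parse_alignment",
    "warp_points",
    "to_ccf",
    "annotate_regions",
    "rasterize_centroids",
]


@dataclass
class SectionAnchor:
    """Linear anchoring of one section: atlas = o + x_norm*u + y_norm*v."""

    name: str
    width: float
    height: float
    o: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        """3×3 matrix M with rows (u, v, o): [x_norm, y_norm, 1] @ M = atlas xyz."""
        return np.vstack([self.u, self.v, self.o])


@dataclass
class LandmarkSet:
    """Paired source/target marker positions in section-image coordinates."""

    name: str
    source: np.ndarray  # (n, 2)
    target: np.ndarray  # (n, 2)
    width: float = 0.0
    height: float = 0.0


@dataclass
class AnnotationVolume:
    """Labeled 3D atlas volume; axis order (x, y, z) unless permuted."""

    labels: np.ndarray
    voxel_size_um: float = 25.0
    label_names: Dict[int, str] = field(default_factory=dict)
    atlas_matrix: Optional[np.ndarray] = None  # 4x4 homogeneous, optional
    axis_order: Tuple[int, int, int] = (0, 1, 2)


def parse_alignment(anchoring_path, landmark_path=None) -> Tuple[List[SectionAnchor], List[LandmarkSet]]:
    """Parse anchoring and landmark JSON files into per-section records.

    Landmark sets are matched to anchors by section filename; a landmark
    section with no anchor is a consistency error; a section with no markers
    array yields an empty landmark set (identity warp) with a warning.
    """
    try:
        with open(anchoring_path) as fh:
            qdata = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON in {anchoring_path}: {exc}") from exc
    anchors = []
    for sl in qdata.get("slices", []):
        a = np.asarray(sl["anchoring"], dtype=float)
        if a.shape != (9,):
            raise FormatError(f"anchoring must have 9 values in {anchoring_path}")
        anchors.append(
            SectionAnchor(
                name=str(sl.get("filename", sl.get("nr", ""))),
                width=float(sl["width"]),
                height=float(sl["height"]),
                o=a[0:3], u=a[3:6], v=a[6:9],
            )
        )
    landmarks: List[LandmarkSet] = []
    if landmark_path is not None:
        try:
            with open(landmark_path) as fh:
                vdata = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed JSON in {landmark_path}: {exc}") from exc
        names = {a.name for a in anchors}
        by_name = {a.name: a for a in anchors}
        for sl in vdata.get("slices", []):
            name = str(sl.get("filename", sl.get("nr", "")))
            if name not in names:
                raise ConsistencyError(f"landmark section {name!r} has no anchor")
            markers = np.asarray(sl.get("markers", []), dtype=float)
            if markers.size == 0:
                logger.warning("section %s has no markers; no warp will be applied", name)
                markers = np.zeros((0, 4))
            anc = by_name[name]
            landmarks.append(
                LandmarkSet(
                    name=name,
                    source=markers[:, 0:2].copy(),
                    target=markers[:, 2:4].copy(),
                    width=float(sl.get("width", anc.width)),
                    height=float(sl.get("height", anc.height)),
                )
            )
    return anchors, landmarks


def _barycentric(tri: Delaunay, simplex_ids: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Barycentric weights of each point w.r.t. its (given) simplex."""
    T = tri.transform[simplex_ids]  # (n, 3, 2)
    b2 = np.einsum("nij,nj->ni", T[:, :2, :], points - T[:, 2, :])
    return np.column_stack([b2, 1.0 - b2.sum(axis=1)])


def warp_points(points, lm: LandmarkSet) -> np.ndarray:
    """Non-linear landmark warp via barycentric interpolation.

    Each point is located in its containing triangle of the Delaunay
    triangulation of the source markers; its barycentric weights are applied
    to the paired target markers. Points outside the triangulation use the
    affine extension of the nearest triangle (by centroid distance). Fewer
    than 3 or collinear markers give the identity warp with a warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(lm.source) < 3:
        logger.warning("fewer than 3 markers for %s; identity warp", lm.name)
        return points.copy()
    try:
        tri = Delaunay(lm.source)
    except QhullError:
        logger.warning("degenerate (collinear) markers for %s; identity warp", lm.name)
        return points.copy()
    simplex = tri.find_simplex(points)
    outside = simplex < 0
    if outside.any():
        centroids = lm.source[tri.simplices].mean(axis=1)
        d = ((points[outside][:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        simplex = simplex.copy()
        simplex[outside] = np.argmin(d, axis=1)
    bary = _barycentric(tri, simplex, points)
    verts = tri.simplices[simplex]  # (n, 3)
    return np.einsum("ni,nij->nj", bary, lm.target[verts])


def to_ccf(coords2d, anchor: SectionAnchor, atlas_matrix: Optional[np.ndarray] = None) -> np.ndarray:
    """Section-image coordinates to 3D atlas coordinates.

    Coordinates are normalized by image width/height, pushed through the
    anchoring (o + x_norm*u + y_norm*v) and optionally through a 4×4
    homogeneous atlas matrix that scales to voxel units and shifts to the
    atlas origin.
    """
    pts = np.atleast_2d(np.asarray(coords2d, dtype=float))
    xn = pts[:, 0] / anchor.width
    yn = pts[:, 1] / anchor.height
    homog = np.column_stack([xn, yn, np.ones(len(pts))])
    out = homog @ anchor.matrix
    if atlas_matrix is not None:
        m = np.asarray(atlas_matrix, dtype=float)
        out = np.column_stack([out, np.ones(len(out))]) @ m.T
        out = out[:, :3]
    return out


def annotate_regions(coords3d, vol: AnnotationVolume) -> np.ndarray:
    """Region label per cell by floor-voxel lookup; out-of-volume gives 0."""
    pts = np.atleast_2d(np.asarray(coords3d, dtype=float))
    idx = np.floor(pts / vol.voxel_size_um).astype(int)
    idx = idx[:, list(vol.axis_order)]
    labels = np.zeros(len(pts), dtype=vol.labels.dtype)
    shape = vol.labels.shape
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    labels[ok] = vol.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return labels


def rasterize_centroids(points, values, width: int, height: int) -> np.ndarray:
    """Rasterize labeled centroids into an integer image (for manual-alignment
    landmark images); pixel = last value drawn at that location, 0 = empty."""
    img = np.zeros((int(height), int(width)), dtype=int)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vals = np.asarray(values)
    ix = np.floor(pts[:, 0]).astype(int)
    iy = np.floor(pts[:, 1]).astype(int)
    ok = (ix >= 0) & (ix < width) & (iy >= 0) & (iy < height)
    img[iy[ok], ix[ok]] = vals[ok]
    return img
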