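"""Tumor-bulk delineation: an alpha hull around segmented tumor-epithelium
pixels.

Alpha semantics: a Delaunay triangle of the point set is kept iff its
circumradius is at most ``1/alpha``; the union of kept triangles, dissolved
into polygons, is the hull.  ``alpha = 0`` keeps every triangle and yields
the convex hull.  Coordinates are pixels at the segmentation spacing
(1.0 um/px by default) and alpha defaults to 0.038 in those units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage.morphology import erosion, remove_small_holes, remove_small_objects

from .imgio import LabelMask, binary_mask, rasterize_polygons

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.038

__all__ = ["BulkPolygon", "alpha_shape", "bulk_from_mask", "circumradius", "DEFAULT_ALPHA"]


@dataclass
class BulkPolygon:
    """One or more simple polygons delimiting the tumor bulk."""

    polygons: list[Polygon] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA
    spacing_um: float = 1.0
    source: str = ""

    @property
    def geometry(self) -> MultiPolygon:
        return MultiPolygon(self.polygons)

    @property
    def area(self) -> float:
        return sum(p.area for p in self.polygons)

    @property
    def is_empty(self) -> bool:
        return not self.polygons


def circumradius(tri: np.ndarray) -> float:
    """Circumradius of a triangle given as a (3, 2) vertex array."""
    a = np.linalg.norm(tri[1] - tri[0])
    b = np.linalg.norm(tri[2] - tri[1])
    c = np.linalg.norm(tri[0] - tri[2])
    u, v = tri[1] - tri[0], tri[2] - tri[0]
    area2 = abs(u[0] * v[1] - u[1] * v[0])  # 2 * area
    if area2 == 0:
        return np.inf
    return a * b * c / (2.0 * area2)


def alpha_shape(
    points: np.ndarray, alpha: float, spacing_um: float = 1.0, source: str = ""
) -> BulkPolygon:
    """Alpha hull of a 2-D point set (columns x, y).

    Keeps Delaunay triangles with circumradius <= 1/alpha and dissolves
    their union into simple polygons.  Fewer than 3 points, or an
    all-collinear set, yields an empty hull with a warning.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    pts = np.unique(pts, axis=0)
    if len(pts) < 3:
        warnings.warn("alpha_shape: fewer than 3 distinct points; empty hull")
        return BulkPolygon([], alpha, spacing_um, source)
    try:
        tri = Delaunay(pts)
    except QhullError:
        warnings.warn("alpha_shape: degenerate (collinear) point set; empty hull")
        return BulkPolygon([], alpha, spacing_um, source)

    r_max = np.inf if alpha == 0 else 1.0 / alpha
    kept = [
        Polygon(pts[s])
        for s in tri.simplices
        if circumradius(pts[s]) <= r_max
    ]
    if not kept:
        return BulkPolygon([], alpha, spacing_um, source)
    merged = unary_union(kept)
    if isinstance(merged, Polygon):
        polys = [merged]
    elif isinstance(merged, MultiPolygon):
        polys = list(merged.geoms)
    else:  # GeometryCollection with line/point debris from slivers
        polys = [g for g in getattr(merged, "geoms", []) if isinstance(g, Polygon)]
    return BulkPolygon([p for p in polys if p.area > 0], alpha, spacing_um, source)


def mask_points(mask: np.ndarray, stride: int) -> np.ndarray:
    """Foreground pixel centers as (x, y): a stride-subsampled grid plus
    the full object boundary, so thin structures and extents survive."""
    fg = np.asarray(mask, dtype=bool)
    grid = np.zeros_like(fg)
    grid[::stride, ::stride] = True
    boundary = fg & ~erosion(fg)
    rr, cc = np.nonzero((fg & grid) | boundary)
    return np.stack([cc, rr], axis=1).astype(float)


def bulk_from_mask(
    tumor_epi: LabelMask | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    stride: int = 8,
    fill_hole_frac: float = 0.05,
    min_object_px: int = 64,
    spacing_um: float | None = None,
) -> tuple[BulkPolygon, LabelMask]:
    """Alpha-hull bulk from a binary tumor-epithelium mask.

    Speckle components below ``min_object_px`` are dropped first — isolated
    false positives far from the bulk would otherwise stretch the hull.
    Returns the hull polygons and their rasterization (pixel-center rule)
    with interior holes below ``fill_hole_frac`` of the hull area filled.
    """
    if isinstance(tumor_epi, LabelMask):
        data = tumor_epi.data.astype(bool)
        spacing_um = spacing_um or tumor_epi.spacing_um
    else:
        data = np.asarray(tumor_epi, dtype=bool)
        spacing_um = spacing_um or 1.0
    if min_object_px > 1:
        data = remove_small_objects(data, max_size=min_object_px - 1)
    if not data.any():
        log.info("bulk_from_mask: empty tumor-epithelium mask")
        return (
            BulkPolygon([], alpha, spacing_um),
            binary_mask(np.zeros(data.shape, np.uint8), spacing_um),
        )
    pts = mask_points(data, stride)
    hull = alpha_shape(pts, alpha, spacing_um)
    if hull.is_empty:
        return hull, binary_mask(np.zeros(data.shape, np.uint8), spacing_um)
    # tiny outward buffer keeps pixel centers on hull edges robustly inside
    mask = rasterize_polygons([p.buffer(1e-9) for p in hull.polygons], data.shape)
    if fill_hole_frac > 0:
        thresh = max(int(fill_hole_frac * mask.sum()), 1)
        mask = remove_small_holes(mask, max_size=thresh)
    return hull, binary_mask(mask, spacing_um)
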