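"""Shared polygon/mask geometry under one rasterization convention.

Every mask/IoU computation in the package uses the same rule: image
coordinates are x = column, y = row, origin at the top-left, 0-based;
rectangles are half-open; and a pixel (r, c) belongs to a polygon iff its
center (c + 0.5, r + 0.5) lies strictly inside the polygon interior.
With integer-edged rectangles and half-integer centers this convention is
exact: a box [x0, x1) x [y0, y1) rasterizes to exactly the pixels whose
indices fall in those ranges.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import shapely
from shapely.geometry import Polygon, MultiPolygon
from shapely.geometry.base import BaseGeometry

__all__ = [
    "rasterize_polygon",
    "rasterize_union",
    "mask_iou",
    "clean_polygon",
    "polygon_from_mask",
]


def rasterize_polygon(geom: BaseGeometry, height: int, width: int) -> np.ndarray:
    """Rasterize a shapely geometry to a boolean (height, width) mask.

    Pixel-center convention: pixel (r, c) is set iff the point
    (c + 0.5, r + 0.5) is contained in the geometry interior.
    """
    mask = np.zeros((height, width), dtype=bool)
    if geom is None or geom.is_empty:
        return mask
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)), width)
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)), height)
    if c1 <= c0 or r1 <= r0:
        return mask
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    cc, rr = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(geom, cc.ravel() + 0.5, rr.ravel() + 0.5)
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return mask


def rasterize_union(geoms: Iterable[BaseGeometry], height: int, width: int) -> np.ndarray:
    """Union of per-geometry rasterizations (not the rasterization of the
    geometric union; the two can differ on shared boundaries)."""
    mask = np.zeros((height, width), dtype=bool)
    for g in geoms:
        mask |= rasterize_polygon(g, height, width)
    return mask


def mask_iou(a: np.ndarray, b: np.ndarray, *, empty_is_one: bool = False) -> float:
    """Intersection-over-union of two boolean masks of equal shape.

    Both masks empty is undefined and raises, unless ``empty_is_one``.
    """
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        if empty_is_one:
            return 1.0
        raise ValueError("IoU of two empty masks is undefined")
    inter = int(np.count_nonzero(a & b))
    return inter / union


def clean_polygon(geom: BaseGeometry) -> BaseGeometry:
    """Repair a possibly self-intersecting polygon and drop degenerate parts."""
    if geom.is_empty:
        return geom
    if not geom.is_valid:
        geom = geom.buffer(0)
    if isinstance(geom, MultiPolygon):
        parts = [p for p in geom.geoms if p.area > 0]
        if not parts:
            return Polygon()
        geom = MultiPolygon(parts) if len(parts) > 1 else parts[0]
    return geom


def polygon_from_mask(mask: np.ndarray, *, simplify_tol: float = 1.0) -> Polygon | None:
    """Extract the largest outer contour of a boolean mask as a polygon.

    Contours are traced with marching squares at the 0.5 level on a padded
    copy (so blobs touching the border close properly), converted from
    (row, col) to (x, y) pixel-center coordinates, and Douglas-Peucker
    simplified. Returns None for an empty mask.
    """
    from skimage import measure

    if not mask.any():
        return None
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    best: Polygon | None = None
    for contour in contours:
        # (row, col) on padded grid -> (x, y) center coords on original
        xy = np.column_stack([contour[:, 1] - 1 + 0.5, contour[:, 0] - 1 + 0.5])
        if len(xy) < 3:
            continue
        poly = clean_polygon(Polygon(xy))
        if poly.is_empty or poly.area == 0:
            continue
        if isinstance(poly, MultiPolygon):
            poly = max(poly.geoms, key=lambda p: p.area)
        if best is None or poly.area > best.area:
            best = poly
    if best is None:
        return None
    if simplify_tol > 0:
        # Douglas-Peucker can bite noticeably into small shapes at a fixed
        # tolerance; halve it until the area is preserved to 0.5 %.
        tol = simplify_tol
        while tol > 1e-3:
            simplified = best.simplify(tol, preserve_topology=True)
            if (
                not simplified.is_empty
                and simplified.area > 0
                and abs(simplified.area - best.area) <= 0.005 * best.area
            ):
                return simplified
            tol /= 2
    return best
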