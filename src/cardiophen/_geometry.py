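"""Polygon rasterization shared by the synthetic generator and volumetry.

Convention: pixel (row r, col c) occupies the unit square [c, c+1) x [r, r+1)
with its center at (x, y) = (c + 0.5, r + 0.5); polygon vertices are given in
the same 0-based pixel coordinate frame, origin at the top-left corner.
A pixel belongs to an ROI iff its center falls inside the polygon.
"""

from __future__ import annotations

import numpy as np
import shapely

__all__ = ["polygon_mask", "polygon_pixel_count"]


def _as_polygon(vertices) -> shapely.Polygon:
    poly = shapely.Polygon(np.asarray(vertices, dtype=float))
    if poly.is_empty or poly.area == 0:
        raise ValueError("polygon is empty or degenerate")
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def polygon_mask(shape: tuple[int, int], vertices) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon."""
    poly = _as_polygon(vertices)
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols.ravel() + 0.5
    y = rows.ravel() + 0.5
    inside = shapely.contains_xy(poly, x, y)
    return inside.reshape(h, w)


def polygon_pixel_count(shape: tuple[int, int], vertices) -> int:
    return int(polygon_mask(shape, vertices).sum())
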