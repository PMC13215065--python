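"""Polygon rasterization onto the pixel-center grid."""

from __future__ import annotations

import numpy as np
from skimage import draw


def rasterize_ring(xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels whose centers lie inside one polygon ring.

    ``xy`` is (N, 2) in (x, y) pixel coordinates (pixel centers at integers).
    """
    xy = np.asarray(xy, dtype=float)
    rr, cc = draw.polygon(xy[:, 1], xy[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def rasterize_rings_evenodd(rings: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization of a list of rings (XOR of ring interiors).

    Holes are rings nested inside an outer ring; XOR realises the even-odd
    fill rule without needing ring orientation or nesting order.
    """
    mask = np.zeros(shape, dtype=bool)
    for ring in rings:
        mask ^= rasterize_ring(ring, shape)
    return mask


def shapely_to_mask(geom, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a shapely Polygon/MultiPolygon given in pixel coordinates."""
    from shapely.geometry import MultiPolygon, Polygon

    if geom.is_empty:
        return np.zeros(shape, dtype=bool)
    if isinstance(geom, Polygon):
        polys = [geom]
    elif isinstance(geom, MultiPolygon):
        polys = list(geom.geoms)
    else:  # GeometryCollection from intersections: keep polygonal parts
        polys = [g for g in getattr(geom, "geoms", []) if g.geom_type == "Polygon"]
    mask = np.zeros(shape, dtype=bool)
    for poly in polys:
        m = rasterize_ring(np.asarray(poly.exterior.coords), shape)
        for interior in poly.interiors:
            m &= ~rasterize_ring(np.asarray(interior.coords), shape)
        mask |= m
    return mask
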