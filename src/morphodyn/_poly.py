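"""Small planar-polygon primitives used by the tissue simulator.

Polygons are (k, 2) float arrays of vertices in counter-clockwise order,
without a repeated closing vertex. All lengths are in micrometres.
"""
from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon


def area(verts: np.ndarray) -> float:
    """Signed shoelace area; positive for counter-clockwise vertex order."""
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def centroid(verts: np.ndarray) -> np.ndarray:
    x, y = verts[:, 0], verts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return verts.mean(axis=0)
    cx = np.sum((x + np.roll(x, -1)) * cross) / (6.0 * a)
    cy = np.sum((y + np.roll(y, -1)) * cross) / (6.0 * a)
    return np.array([cx, cy])


def second_moments(verts: np.ndarray) -> np.ndarray:
    """Central second area moments [[Ixx, Ixy], [Ixy, Iyy]] of the region.

    Uses the standard shoelace extension; the polygon must be simple.
    """
    c = centroid(verts)
    v = verts - c
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    ixx = np.sum(cross * (x * x + x * x1 + x1 * x1)) / 12.0
    iyy = np.sum(cross * (y * y + y * y1 + y1 * y1)) / 12.0
    ixy = np.sum(cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)) / 24.0
    return np.array([[ixx, ixy], [ixy, iyy]])


def long_axis(verts: np.ndarray) -> np.ndarray:
    """Unit vector along the polygon's principal (longest) area axis."""
    # second_moments returns [[∫x²dA, ∫xy dA], [∫xy dA, ∫y²dA]] about the
    # centroid, i.e. the (unnormalised) covariance of the region.
    cov = second_moments(verts)
    w, vec = np.linalg.eigh(cov)
    return vec[:, np.argmax(w)]


def split_by_line(verts: np.ndarray, point: np.ndarray, direction: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Split a convex polygon by the line through ``point`` along
    ``direction``.

    Returns the two daughter vertex arrays; their areas sum to the mother's
    area exactly up to floating point. Implemented as intersections with the
    two half-planes bounded by the line (robust for convex cells).
    """
    c = np.asarray(point, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    n = np.array([-d[1], d[0]])  # normal of the cutting line
    span = 10.0 * (np.ptp(verts, axis=0).max() + 1.0)
    # Large rectangles covering each half-plane.
    p0, p1 = c - span * d, c + span * d
    rect_a = Polygon([p0, p1, p1 + span * n, p0 + span * n])
    rect_b = Polygon([p0, p1, p1 - span * n, p0 - span * n])
    mother = Polygon(verts)
    out = []
    for rect in (rect_a, rect_b):
        piece = mother.intersection(rect)
        if piece.is_empty or piece.area <= 0:
            raise ValueError("degenerate division: cutting line misses the cell")
        if piece.geom_type != "Polygon":  # pick the largest piece defensively
            piece = max(piece.geoms, key=lambda g: g.area)
        xy = np.asarray(piece.exterior.coords)[:-1]
        if area(xy) < 0:
            xy = xy[::-1]
        out.append(xy)
    return out[0], out[1]
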