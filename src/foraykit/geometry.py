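"""Planar geometric primitives shared by every pipeline stage.

All geometry lives in a single planar metric CRS (UTM is the expected
projection for field data); coordinates are metres throughout.  Inputs in
geographic coordinates must be projected before they reach this package.

The module is a thin, typed layer over :mod:`shapely`: convex hulls,
point-in-polygon tests, unsigned distance to a polygon's exterior ring, and
linear referencing (chainage) along a river centerline.  The one
non-standard primitive is :func:`mcp`, the percentage minimum convex
polygon used as the home-range estimator: it peels points by distance from
the arithmetic centroid before taking the hull.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "DegenerateGeometryError",
    "convex_hull",
    "mcp",
    "point_in_polygon",
    "distance_to_boundary",
    "project_onto_polyline",
    "step_distance",
    "as_points_array",
]

#: Distance tolerance (m) below which a point counts as lying on a boundary.
BOUNDARY_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a hull or MCP cannot be formed (<3 distinct points, or
    all points collinear)."""


def as_points_array(points: Iterable) -> np.ndarray:
    """Coerce an iterable of (x, y) pairs / Points into an (n, 2) float array."""
    pts = []
    for p in points:
        if isinstance(p, Point):
            pts.append((p.x, p.y))
        else:
            pts.append((float(p[0]), float(p[1])))
    arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (x, y) pairs")
    if not np.isfinite(arr).all():
        raise ValueError("coordinates must be finite")
    return arr


def convex_hull(points: Iterable) -> Polygon:
    """Minimal convex polygon containing all input points.

    Raises
    ------
    DegenerateGeometryError
        If fewer than 3 distinct points remain, or all points are collinear.
    """
    arr = as_points_array(points)
    if len(np.unique(arr, axis=0)) < 3:
        raise DegenerateGeometryError("convex hull needs >=3 distinct points")
    from shapely import MultiPoint

    hull = MultiPoint(arr).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:
        raise DegenerateGeometryError("points are collinear; hull is degenerate")
    return hull


def mcp(points: Iterable, fraction: float = 0.95) -> Polygon:
    """Percentage minimum convex polygon (MCP) home-range estimator.

    Retains the ``floor(fraction * n)`` points nearest the arithmetic
    centroid of *all* points (ties broken by input order) and returns their
    convex hull.  ``fraction=1`` is exactly :func:`convex_hull`.

    Parameters
    ----------
    points
        (x, y) locations in metres.
    fraction
        Proportion of points to retain, in (0, 1].

    Raises
    ------
    DegenerateGeometryError
        If the retained subset cannot form a polygon.
    """
    arr = as_points_array(points)
    idx = mcp_retained_indices(arr, fraction)
    return convex_hull(arr[idx])


def mcp_retained_indices(points, fraction: float = 0.95) -> np.ndarray:
    """Indices (input order) of the points the MCP peel retains.

    The peel keeps the ``floor(fraction * n)`` points nearest the arithmetic
    centroid; ties are broken by earlier input index (stable sort).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    arr = as_points_array(points)
    n = len(arr)
    keep = int(np.floor(fraction * n))
    if keep < 3:
        raise DegenerateGeometryError("fewer than 3 points retained by MCP peeling")
    centroid = arr.mean(axis=0)
    d = np.hypot(arr[:, 0] - centroid[0], arr[:, 1] - centroid[1])
    order = np.argsort(d, kind="stable")[:keep]
    return np.sort(order)


def point_in_polygon(p, poly: Polygon) -> bool:
    """Containment test; points on the boundary count as inside."""
    pt = p if isinstance(p, Point) else Point(p[0], p[1])
    if poly.covers(pt):
        return True
    # covers() already treats the boundary as inside; the distance guard
    # absorbs floating-point slack at shared vertices.
    return poly.exterior.distance(pt) <= BOUNDARY_TOL


def distance_to_boundary(p, poly: Polygon) -> float:
    """Unsigned minimal Euclidean distance (m) from ``p`` to the polygon's
    exterior ring, whether ``p`` is inside or outside."""
    pt = p if isinstance(p, Point) else Point(p[0], p[1])
    return float(poly.exterior.distance(pt))


def project_onto_polyline(p, line: LineString) -> tuple[float, float]:
    """Linear referencing of a point against a polyline.

    Returns
    -------
    (chainage, offset)
        ``chainage`` is the along-line distance (m) from the line's start to
        the nearest point on the line, in ``[0, line.length]``; ``offset``
        is the perpendicular (shortest) distance from ``p`` to the line.
    """
    pt = p if isinstance(p, Point) else Point(p[0], p[1])
    chainage = float(line.project(pt))
    offset = float(line.distance(pt))
    return chainage, offset


def step_distance(a, b) -> float:
    """Euclidean distance (m) between two fixes."""
    ax, ay = (a.x, a.y) if isinstance(a, Point) else (a[0], a[1])
    bx, by = (b.x, b.y) if isinstance(b, Point) else (b[0], b[1])
    return float(np.hypot(bx - ax, by - ay))


def polyline_from_vertices(vertices: Sequence) -> LineString:
    """Build a centerline polyline, dropping zero-length segments."""
    arr = as_points_array(vertices)
    keep = [arr[0]]
    for v in arr[1:]:
        if np.hypot(*(v - keep[-1])) > 0:
            keep.append(v)
    if len(keep) < 2:
        raise ValueError("polyline needs >=2 distinct vertices")
    return LineString(keep)
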