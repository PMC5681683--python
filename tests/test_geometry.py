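"""Geometric primitives checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString, Point, Polygon

from foraykit.geometry import (
    DegenerateGeometryError,
    convex_hull,
    distance_to_boundary,
    mcp,
    mcp_retained_indices,
    point_in_polygon,
    project_onto_polyline,
    step_distance,
)


# ---------------------------------------------------------------------------
# independent oracles


def winding_number_inside(p, vertices) -> bool:
    """Classic winding-number containment, written independently of shapely.
    Boundary points are treated as inside."""
    x, y = p
    n = len(vertices)
    wn = 0
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-segment check (boundary counts as inside)
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if y1 <= y:
            if y2 > y and cross > 0:
                wn += 1
        else:
            if y2 <= y and cross < 0:
                wn -= 1
    return wn != 0


def dense_boundary_min_distance(p, vertices, n_samples=20_000) -> float:
    """Min distance from p to a densely sampled polygon ring / polyline."""
    vertices = np.asarray(vertices, dtype=float)
    best = np.inf
    for i in range(len(vertices) - 1):
        a, b = vertices[i], vertices[i + 1]
        t = np.linspace(0, 1, max(2, n_samples // len(vertices)))[:, None]
        pts = a + t * (b - a)
        best = min(best, float(np.hypot(*(pts - np.asarray(p)).T).min()))
    return best


# ---------------------------------------------------------------------------


class TestConvexHull:
    def test_square_is_its_own_hull(self):
        poly = convex_hull([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert poly.area == pytest.approx(1.0)

    def test_interior_point_absorbed(self):
        poly = convex_hull([(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)])
        assert poly.area == pytest.approx(1.0)
        assert len(poly.exterior.coords) == 5  # 4 corners + closing vertex

    def test_matches_qhull_on_random_points(self):
        from scipy.spatial import ConvexHull as QHull

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(50, 2))
        assert convex_hull(pts).area == pytest.approx(QHull(pts).volume, rel=1e-12)

    def test_contains_every_input_point(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5, 5, size=(200, 2))
        hull = convex_hull(pts)
        assert all(point_in_polygon(p, hull) for p in pts)

    @pytest.mark.parametrize(
        "pts", [[(0, 0), (1, 1)], [(0, 0), (1, 1), (2, 2), (3, 3)], [(1, 1)] * 5]
    )
    def test_degenerate_inputs_raise(self, pts):
        with pytest.raises(DegenerateGeometryError):
            convex_hull(pts)


class TestMCP:
    def test_outlier_peeled_at_95(self):
        rng = np.random.default_rng(0)
        cluster = rng.uniform(0, 100, size=(19, 2))
        pts = np.vstack([cluster, [[5000.0, 5000.0]]])
        poly = mcp(pts, 0.95)
        xs, ys = poly.exterior.xy
        diam = max(
            np.hypot(x1 - x2, y1 - y2)
            for x1, y1 in zip(xs, ys)
            for x2, y2 in zip(xs, ys)
        )
        assert diam < 200.0
        assert not point_in_polygon((5000, 5000), poly)

    def test_fraction_one_is_convex_hull(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 2))
        assert mcp(pts, 1.0).equals(convex_hull(pts))

    def test_retained_set_matches_bruteforce_centroid_sort(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 1000, size=(100, 2))
        idx = mcp_retained_indices(pts, 0.95)
        centroid = pts.mean(axis=0)
        d = np.hypot(*(pts - centroid).T)
        expected = sorted(np.argsort(d, kind="stable")[:95])
        assert list(idx) == expected

    def test_area_monotone_in_fraction(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1, 1, size=(100, 2))
        areas = [mcp(pts, f).area for f in (0.5, 0.7, 0.9, 0.95, 1.0)]
        assert all(a <= b + 1e-12 for a, b in zip(areas, areas[1:]))


class TestPointInPolygon:
    def test_centroid_inside_square(self, unit_square):
        assert point_in_polygon((0.5, 0.5), unit_square)

    def test_far_point_outside(self, unit_square):
        assert not point_in_polygon((10, 10), unit_square)

    def test_boundary_counts_as_inside(self, unit_square):
        assert point_in_polygon((1.0, 0.5), unit_square)
        assert point_in_polygon((0.0, 0.0), unit_square)

    def test_agrees_with_winding_number_oracle(self, l_shape):
        rng = np.random.default_rng(11)
        verts = list(l_shape.exterior.coords)[:-1]
        pts = rng.uniform(-0.5, 2.5, size=(1000, 2))
        for p in pts:
            assert point_in_polygon(p, l_shape) == winding_number_inside(p, verts)


class TestDistanceToBoundary:
    def test_axis_aligned_offset(self, unit_square):
        assert distance_to_boundary((2.0, 0.5), unit_square) == pytest.approx(1.0)

    def test_zero_on_boundary(self, unit_square):
        assert distance_to_boundary((1.0, 0.3), unit_square) == pytest.approx(0.0)

    def test_interior_point_positive(self, unit_square):
        # unsigned distance: interior points are distance-to-ring, not zero
        assert distance_to_boundary((0.5, 0.5), unit_square) == pytest.approx(0.5)

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            pts = rng.uniform(0, 100, size=(12, 2))
            poly = convex_hull(pts)
            verts = np.asarray(poly.exterior.coords)
            for _ in range(40):
                p = rng.uniform(-20, 120, size=2)
                got = distance_to_boundary(p, poly)
                ref = dense_boundary_min_distance(p, verts)
                assert got == pytest.approx(ref, abs=1e-2)
                assert got <= ref + 1e-12  # exact distance never exceeds sampled


class TestProjectOntoPolyline:
    def test_straight_line(self):
        line = LineString([(0, 0), (10, 0)])
        chain, off = project_onto_polyline((5, 3), line)
        assert chain == pytest.approx(5.0)
        assert off == pytest.approx(3.0)

    def test_vertex_projection(self):
        line = LineString([(0, 0), (3, 4), (10, 4)])
        chain, off = project_onto_polyline((3, 4), line)
        assert off == pytest.approx(0.0)
        assert chain == pytest.approx(5.0)

    def test_zigzag_matches_dense_sampling(self):
        rng = np.random.default_rng(17)
        verts = np.column_stack([np.arange(6) * 10.0, rng.uniform(-5, 5, 6)])
        line = LineString(verts)
        samples = np.array(
            [line.interpolate(s).coords[0] for s in np.linspace(0, line.length, 50_000)]
        )
        svals = np.linspace(0, line.length, 50_000)
        for _ in range(200):
            p = rng.uniform(-10, 70, size=2)
            chain, off = project_onto_polyline(p, line)
            d = np.hypot(*(samples - p).T)
            i = int(d.argmin())
            assert off == pytest.approx(float(d[i]), abs=1e-3)
            assert chain == pytest.approx(float(svals[i]), abs=line.length / 10_000)

    def test_offset_equals_point_to_line_distance(self):
        rng = np.random.default_rng(19)
        verts = rng.uniform(0, 100, size=(5, 2))
        line = LineString(verts)
        for _ in range(100):
            p = rng.uniform(0, 100, size=2)
            _, off = project_onto_polyline(p, line)
            assert off == pytest.approx(Point(p).distance(line), rel=1e-12)


coords = st.floats(min_value=-1e4, max_value=1e4, allow_nan=False)
point_lists = st.lists(st.tuples(coords, coords), min_size=6, max_size=40)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(point_lists)
def test_hull_contains_points_and_mcp_is_monotone(pts):
    """For any point cloud: the hull covers every input point, and the MCP
    area never decreases with the retained fraction."""
    arr = np.asarray(pts)
    try:
        hull = convex_hull(arr)
        areas = [mcp(arr, f).area for f in (0.6, 0.8, 1.0)]
    except DegenerateGeometryError:
        return  # collinear/duplicate draws are legitimately rejected
    assert all(point_in_polygon(p, hull) for p in arr)
    assert areas[0] <= areas[1] + 1e-9 <= areas[2] + 2e-9
    assert areas[2] == pytest.approx(hull.area)


class TestStepDistance:
    def test_3_4_5(self):
        assert step_distance((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_zero(self):
        assert step_distance((2, 2), (2, 2)) == 0.0

    def test_matches_hypot(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            a, b = rng.normal(size=(2, 2)) * 100
            assert step_distance(a, b) == pytest.approx(float(np.hypot(*(b - a))))
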