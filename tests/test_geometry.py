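import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from herdmotion import (
    ConvergenceError,
    EmptyMaskError,
    InvalidGeometryError,
    Point2D,
    Polygon,
    RasterMask,
    centroid_least_squares,
    centroid_mean,
    centroid_signed_area,
    centroid_spatial_moment,
    rasterize_polygon,
    spatial_moments,
)
from conftest import random_convex_polygon, random_star_polygon


class TestPolygon:
    def test_requires_three_distinct_vertices(self):
        with pytest.raises(InvalidGeometryError):
            Polygon([(0, 0), (1, 1)])
        with pytest.raises(InvalidGeometryError):
            Polygon([(0, 0), (0, 0), (1, 1), (1, 1)])

    def test_collinear_vertices_rejected(self):
        with pytest.raises(InvalidGeometryError):
            Polygon([(0, 0), (1, 1), (2, 2)])

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidGeometryError):
            Polygon([(0, 0), (1, 0), (float("nan"), 1)])

    def test_raw_vertices_preserved_ring_deduplicated(self):
        poly = Polygon([(0, 0), (0, 0), (1, 0), (1, 1), (0, 1)])
        assert len(poly.vertices) == 5
        assert len(poly.ring) == 4


class TestRasterize:
    def test_offset_square_covers_exactly_four_pixels(self):
        # pixel centers (0,0),(1,0),(0,1),(1,1) are strictly inside
        poly = Polygon([(-0.5, -0.5), (1.5, -0.5), (1.5, 1.5), (-0.5, 1.5)])
        mask = rasterize_polygon(poly, 4, 4)
        set_pixels = {(int(x), int(y)) for y, x in zip(*np.nonzero(mask.intensity))}
        assert set_pixels == {(0, 0), (1, 0), (0, 1), (1, 1)}

    def test_full_cover_rectangle_sets_every_pixel(self):
        poly = Polygon([(-2, -2), (7, -2), (7, 6), (-2, 6)])
        mask = rasterize_polygon(poly, 5, 3)
        assert mask.count() == 15

    def test_boundary_pixel_centers_count_as_inside(self):
        # edges pass exactly through integer pixel centers
        poly = Polygon([(0, 0), (2, 0), (2, 2), (0, 2)])
        mask = rasterize_polygon(poly, 4, 4)
        assert mask.count() == 9  # the 3x3 block {0,1,2}^2

    def test_degenerate_polygon_raises(self):
        poly = Polygon([(0, 0), (1, 1), (2, 2)], validate=False)
        with pytest.raises(InvalidGeometryError):
            rasterize_polygon(poly, 4, 4)

    def test_clipped_to_frame(self):
        poly = Polygon([(-10, -10), (1.5, -10), (1.5, 1.5), (-10, 1.5)])
        mask = rasterize_polygon(poly, 3, 3)
        assert mask.count() == 4  # only (0,0),(1,0),(0,1),(1,1) are in frame


class TestSpatialMoments:
    def test_single_pixel(self):
        grid = np.zeros((8, 8), dtype=np.uint8)
        grid[5, 3] = 1  # (x=3, y=5)
        m = spatial_moments(RasterMask(8, 8, grid))
        assert (m.m00, m.m10, m.m01) == (1, 3, 5)

    def test_two_by_two_block(self):
        grid = np.zeros((4, 4), dtype=np.uint8)
        grid[0:2, 0:2] = 1
        m = spatial_moments(RasterMask(4, 4, grid))
        assert (m.m00, m.m10, m.m01) == (4, 2, 2)

    def test_empty_mask_zero_moments(self):
        m = spatial_moments(RasterMask(4, 4, np.zeros((4, 4), dtype=np.uint8)))
        assert (m.m00, m.m10, m.m01) == (0, 0, 0)


class TestSpatialMomentCentroid:
    def test_four_pixel_square(self):
        poly = Polygon([(-0.5, -0.5), (1.5, -0.5), (1.5, 1.5), (-0.5, 1.5)])
        c = centroid_spatial_moment(poly, 4, 4)
        assert (c.x, c.y) == (0.5, 0.5)

    def test_contour_outside_frame_raises(self):
        poly = Polygon([(100, 100), (110, 100), (110, 110), (100, 110)])
        with pytest.raises(EmptyMaskError):
            centroid_spatial_moment(poly, 50, 50)

    def test_integer_translation_equivariance(self):
        rng = np.random.default_rng(4)
        poly = random_star_polygon(rng, scale=40)
        c0 = centroid_spatial_moment(poly, 512, 512)
        c1 = centroid_spatial_moment(poly.translated(17, 23), 512, 512)
        assert c1.x - c0.x == pytest.approx(17, abs=1e-9)
        assert c1.y - c0.y == pytest.approx(23, abs=1e-9)

    def test_disc_centroid_recovers_center(self):
        t = np.linspace(0, 2 * np.pi, 65)[:-1]
        disc = Polygon(np.column_stack([500 + 100 * np.cos(t), 300 + 100 * np.sin(t)]))
        c = centroid_spatial_moment(disc, 1024, 1024)
        assert math.hypot(c.x - 500, c.y - 300) < 0.5

    def test_matches_brute_force_pixel_average(self):
        rng = np.random.default_rng(9)
        poly = random_star_polygon(rng, scale=30)
        mask = rasterize_polygon(poly, 256, 256)
        ys, xs = np.nonzero(mask.intensity)
        c = centroid_spatial_moment(poly, 256, 256)
        assert c.x == pytest.approx(xs.mean(), abs=1e-9)
        assert c.y == pytest.approx(ys.mean(), abs=1e-9)

    @pytest.mark.parametrize("scales", [(1.0, 4.0, 16.0)])
    def test_converges_to_signed_area_centroid_with_resolution(self, scales):
        """Uniform-density mask moments approach the continuum polygon
        centroid as the raster resolution (polygon scale) grows."""
        rng = np.random.default_rng(21)
        poly = random_convex_polygon(rng, scale=30)
        sa = centroid_signed_area(poly)
        gaps = []
        for s in scales:
            scaled = Polygon(poly.vertices * s)
            frame = int(math.ceil(max(scaled.bounds()[2], scaled.bounds()[3])) + 4)
            c = centroid_spatial_moment(scaled, frame, frame)
            gaps.append(math.hypot(c.x - sa.x * s, c.y - sa.y * s) / s)
        assert gaps[0] >= gaps[-1] - 1e-12
        assert gaps[-1] <= 0.5


class TestMeanCentroid:
    @pytest.mark.parametrize(
        "verts, expected",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], (0.5, 0.5)),
            ([(0, 0), (3, 0), (0, 3)], (1, 1)),
            # repeated vertex pulls the mean toward it: (5/7, 5/7)
            (
                [(0, 0), (1, 0), (1, 1), (1, 1), (1, 1), (1, 1), (0, 1)],
                (5 / 7, 5 / 7),
            ),
        ],
    )
    def test_examples(self, verts, expected):
        c = centroid_mean(Polygon(verts))
        assert (c.x, c.y) == pytest.approx(expected)


class TestLeastSquaresCentroid:
    def test_agrees_with_vertex_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            poly = random_star_polygon(rng)
            ls = centroid_least_squares(poly, tol=1e-9)
            m = centroid_mean(poly)
            assert math.hypot(ls.x - m.x, ls.y - m.y) <= 1e-9

    def test_identical_vertices_fixed_point(self):
        poly = Polygon([(2, 3)] * 4, validate=False)
        c = centroid_least_squares(poly)
        assert (c.x, c.y) == (2, 3)

    def test_unit_square_tight_tolerance(self, unit_square):
        c = centroid_least_squares(unit_square, tol=1e-9)
        assert math.hypot(c.x - 0.5, c.y - 0.5) <= 1e-9

    def test_nonconvergence_reports_last_iterate(self):
        poly = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        with pytest.raises(ConvergenceError) as err:
            centroid_least_squares(poly, tol=1e-12, max_iter=2)
        assert err.value.last_iterate is not None


class TestSignedAreaCentroid:
    def test_unit_square(self, unit_square):
        c = centroid_signed_area(unit_square)
        assert (c.x, c.y) == pytest.approx((0.5, 0.5))

    def test_l_shape_rectangle_decomposition(self, l_shape):
        # 2x2 square minus 1x1 corner: (4*(1,1) - 1*(1.5,1.5)) / 3 = (5/6, 5/6)
        c = centroid_signed_area(l_shape)
        assert (c.x, c.y) == pytest.approx((5 / 6, 5 / 6))

    def test_orientation_independent(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            poly = random_star_polygon(rng)
            fwd = centroid_signed_area(poly)
            rev = centroid_signed_area(Polygon(poly.vertices[::-1]))
            assert (fwd.x, fwd.y) == pytest.approx((rev.x, rev.y), abs=1e-9)

    def test_matches_shapely_centroid(self):
        from shapely.geometry import Polygon as ShapelyPolygon

        rng = np.random.default_rng(5)
        for _ in range(10):
            poly = random_star_polygon(rng)
            ours = centroid_signed_area(poly)
            ref = ShapelyPolygon(poly.vertices).centroid
            assert (ours.x, ours.y) == pytest.approx((ref.x, ref.y), abs=1e-9)

    def test_zero_area_raises(self):
        poly = Polygon([(0, 0), (1, 1), (2, 2)], validate=False)
        with pytest.raises(InvalidGeometryError):
            centroid_signed_area(poly)


class TestSharedCenterProperties:
    def test_all_centers_inside_convex_polygon(self):
        from shapely.geometry import Point as ShapelyPoint
        from shapely.geometry import Polygon as ShapelyPolygon

        rng = np.random.default_rng(12)
        for _ in range(10):
            poly = random_convex_polygon(rng, scale=80)
            shp = ShapelyPolygon(poly.vertices).buffer(1e-6)
            for center in (
                centroid_mean(poly),
                centroid_least_squares(poly),
                centroid_signed_area(poly),
                centroid_spatial_moment(poly, 400, 400),
            ):
                assert shp.contains(ShapelyPoint(center.x, center.y))

    @given(
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
        s=st.floats(0.1, 10),
    )
    def test_translation_and_scale_equivariance(self, dx, dy, s):
        poly = Polygon([(0, 0), (4, 1), (5, 6), (1, 4)])
        for fn in (centroid_mean, centroid_signed_area):
            base = fn(poly)
            moved = fn(Polygon(poly.vertices + np.array([dx, dy])))
            assert (moved.x, moved.y) == pytest.approx(
                (base.x + dx, base.y + dy), abs=1e-9
            )
            scaled = fn(Polygon(poly.vertices * s))
            assert (scaled.x, scaled.y) == pytest.approx(
                (base.x * s, base.y * s), rel=1e-9
            )
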