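import math

import numpy as np
import pytest
from shapely.geometry import Point, box

from gridpop.admin import AdminSet, AdminUnit
from gridpop.grids import (DEFAULT_NODATA, Grid, buffer_region, distance_to,
                           focal_proportion, nibble_fill, rasterize_units,
                           slope_from_dem)

from .oracles import (brute_distance_to, brute_focal_proportion, brute_nibble,
                      brute_rasterize, brute_slope)


def unit(uid, geom, pop=10, level=1, parent=None):
    return AdminUnit(uid, level, geom, pop, geom.area / 1e6, parent_id=parent)


class TestGridType:
    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            Grid(np.zeros(5))

    def test_rejects_nonpositive_cell(self):
        with pytest.raises(ValueError):
            Grid(np.zeros((2, 2)), cell_size=0)

    def test_rejects_nan(self):
        v = np.zeros((2, 2))
        v[0, 0] = np.nan
        with pytest.raises(ValueError):
            Grid(v)

    def test_alignment(self):
        a = Grid(np.zeros((3, 4)), cell_size=100, origin=(0, 300))
        b = Grid(np.ones((3, 4)), cell_size=100, origin=(0, 300))
        c = Grid(np.ones((3, 4)), cell_size=100, origin=(50, 300))
        assert a.aligned_with(b)
        assert not a.aligned_with(c)

    def test_bounds(self):
        g = Grid(np.zeros((3, 4)), cell_size=100, origin=(10, 300))
        assert g.bounds == (10, 0, 410, 300)


class TestRasterizeUnits:
    def test_single_square_full_containment(self):
        g = box(0, 0, 1000, 1000)
        units = AdminSet([unit(7, g)])
        ur = rasterize_units(units, 100)
        assert ur.shape == (10, 10)
        assert (ur.values == 7).all()

    def test_half_plane_partition(self):
        a = box(0, 0, 500, 1000)
        b = box(500, 0, 1000, 1000)
        units = AdminSet([unit(1, a), unit(2, b)])
        ur = rasterize_units(units, 100)
        assert (ur.values[:, :5] == 1).all()
        assert (ur.values[:, 5:] == 2).all()

    def test_outside_cells_nodata(self):
        units = AdminSet([unit(1, box(0, 0, 500, 500))])
        ur = rasterize_units(units, 100, extent=(0, 0, 1000, 1000))
        assert (ur.values[5:, :5] == 1).all()
        assert (ur.values[:5, :] == ur.nodata).all()

    def test_shared_edge_goes_to_smaller_id(self):
        # centres at x=50, 150; shared edge exactly at a centre column
        a = box(0, 0, 150, 100)
        b = box(150, 0, 300, 100)
        units = AdminSet([unit(2, a), unit(1, b)])
        ur = rasterize_units(units, 100)
        # centre x=150 lies on the shared edge -> id 1 wins
        assert ur.values[0, 1] == 1

    def test_tiny_unit_gets_a_cell(self):
        big = box(0, 0, 1000, 1000)
        tiny = box(420, 420, 430, 430)  # smaller than a cell
        units = AdminSet([unit(1, big), unit(2, tiny)])
        ur = rasterize_units(units, 100)
        assert (ur.values == 2).sum() == 1

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            rasterize_units(AdminSet([]), 100)

    def test_nonpolygonal_rejected(self):
        with pytest.raises(ValueError):
            AdminUnit(1, 1, Point(0, 0), 1, 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_point_in_polygon(self, seed):
        rng = np.random.default_rng(seed)
        units = []
        for uid in range(1, 5):
            cx, cy = rng.uniform(300, 2700, size=2)
            pts = rng.uniform(-600, 600, size=(8, 2)) + [cx, cy]
            hull = box(0, 0, 1, 1).union(Point(0, 0))  # placeholder
            import shapely
            hull = shapely.MultiPoint(pts).convex_hull
            units.append(unit(uid, hull))
        aset = AdminSet(units)
        ur = rasterize_units(aset, 100, extent=(0, 0, 3000, 3000))
        expected = brute_rasterize(aset, ur)
        np.testing.assert_array_equal(ur.values, expected)

    def test_idempotent_footprint(self):
        units = AdminSet([unit(1, box(0, 0, 700, 500)),
                          unit(2, box(700, 0, 1200, 500))])
        a = rasterize_units(units, 100)
        b = rasterize_units(units, 100, extent=a.bounds)
        np.testing.assert_array_equal(a.values, b.values)


class TestBufferRegion:
    def test_zero_buffer_is_union(self):
        g = box(0, 0, 1000, 1000)
        out = buffer_region(AdminSet([unit(1, g)]), 0)
        assert out.equals(g)

    def test_minkowski_bound(self):
        g = box(0, 0, 1000, 1000)
        out = buffer_region(AdminSet([unit(1, g)]), 10_000)
        minx, miny, maxx, maxy = out.bounds
        assert maxx - minx == pytest.approx(21_000)
        assert maxy - miny == pytest.approx(21_000)

    def test_circle_area_closed_form(self):
        r, d = 2000.0, 5000.0
        circle = Point(0, 0).buffer(r, quad_segs=256)
        out = buffer_region(AdminSet([unit(1, circle)]), d)
        assert out.area == pytest.approx(math.pi * (r + d) ** 2, rel=1e-3)

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            buffer_region(AdminSet([unit(1, box(0, 0, 1, 1))]), -1)


def full_mask(shape, cell_size=100.0):
    return Grid(np.ones(shape), cell_size=cell_size)


class TestNibbleFill:
    def test_identity_without_nodata(self):
        g = Grid(np.arange(12.0).reshape(3, 4))
        out = nibble_fill(g, full_mask((3, 4)))
        np.testing.assert_array_equal(out.values, g.values)

    def test_single_hole_unique_neighbour(self):
        v = np.full((3, 3), 5.0)
        v[1, 1] = DEFAULT_NODATA
        out = nibble_fill(Grid(v, nodata=DEFAULT_NODATA), full_mask((3, 3)))
        assert out.values[1, 1] == 5.0

    def test_never_alters_valid_cells_and_clears_holes(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(20, 20))
        holes = rng.random((20, 20)) < 0.25
        v[holes] = DEFAULT_NODATA
        g = Grid(v, nodata=DEFAULT_NODATA)
        out = nibble_fill(g, full_mask((20, 20)))
        assert (out.values != DEFAULT_NODATA).all()
        np.testing.assert_array_equal(out.values[~holes], g.values[~holes])

    def test_outside_mask_untouched(self):
        v = np.full((4, 4), DEFAULT_NODATA)
        v[0, 0] = 1.0
        mask_v = np.full((4, 4), DEFAULT_NODATA)
        mask_v[:2, :2] = 1.0
        out = nibble_fill(Grid(v, nodata=DEFAULT_NODATA),
                          Grid(mask_v, nodata=DEFAULT_NODATA))
        assert (out.values[2:, :] == DEFAULT_NODATA).all()
        assert (out.values[:2, :2] == 1.0).all()

    def test_all_nodata_raises(self):
        v = np.full((3, 3), DEFAULT_NODATA)
        with pytest.raises(ValueError):
            nibble_fill(Grid(v, nodata=DEFAULT_NODATA), full_mask((3, 3)))

    def test_misaligned_raises(self):
        g = Grid(np.zeros((3, 3)))
        m = Grid(np.ones((4, 4)))
        with pytest.raises(ValueError):
            nibble_fill(g, m)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        v = np.round(rng.normal(size=(40, 40)), 3)
        v[rng.random((40, 40)) < 0.2] = DEFAULT_NODATA
        g = Grid(v, nodata=DEFAULT_NODATA)
        m = full_mask((40, 40))
        out = nibble_fill(g, m)
        np.testing.assert_array_equal(out.values, brute_nibble(g, m))


class TestDistanceTo:
    def test_feature_cell_is_zero(self):
        v = np.zeros((3, 3))
        v[1, 1] = 1
        out = distance_to(Grid(v))
        assert out.values[1, 1] == 0.0

    def test_orthogonal_neighbour_is_one_cell(self):
        v = np.zeros((3, 3))
        v[1, 1] = 1
        out = distance_to(Grid(v, cell_size=100))
        assert out.values[1, 2] == 100.0
        assert out.values[0, 0] == pytest.approx(100 * math.sqrt(2))

    def test_no_feature_raises(self):
        with pytest.raises(ValueError):
            distance_to(Grid(np.zeros((3, 3))))

    def test_nonbinary_raises(self):
        with pytest.raises(ValueError):
            distance_to(Grid(np.full((2, 2), 3.0)))

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        v = (rng.random((20, 20)) < 0.1).astype(float)
        v[0, 0] = 1
        a = distance_to(Grid(v, origin=(0, 2000)))
        b = distance_to(Grid(v, origin=(5e5, 9e5)))
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        v = (rng.random((50, 50)) < 0.05).astype(float)
        v[rng.integers(50), rng.integers(50)] = 1
        g = Grid(v, cell_size=100)
        np.testing.assert_array_equal(distance_to(g).values, brute_distance_to(g))


class TestFocalProportion:
    def test_all_ones(self):
        out = focal_proportion(Grid(np.ones((8, 8))), 500)
        np.testing.assert_array_equal(out.values, np.ones((8, 8)))

    def test_all_zeros(self):
        out = focal_proportion(Grid(np.zeros((8, 8))), 500)
        np.testing.assert_array_equal(out.values, np.zeros((8, 8)))

    def test_bounded(self):
        rng = np.random.default_rng(1)
        v = (rng.random((30, 30)) < 0.4).astype(float)
        out = focal_proportion(Grid(v), 500)
        assert (out.values >= 0).all() and (out.values <= 1).all()

    def test_small_radius_window_is_self(self):
        v = np.zeros((4, 4))
        v[2, 2] = 1
        out = focal_proportion(Grid(v, cell_size=100), 40)
        assert out.values[2, 2] == 1.0
        assert out.values[0, 0] == 0.0

    def test_nonpositive_radius_raises(self):
        with pytest.raises(ValueError):
            focal_proportion(Grid(np.ones((3, 3))), 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(300 + seed)
        v = (rng.random((30, 30)) < 0.3).astype(float)
        g = Grid(v, cell_size=100)
        np.testing.assert_array_equal(focal_proportion(g, 500).values,
                                      brute_focal_proportion(g, 500))


class TestSlope:
    def test_flat_dem(self):
        out = slope_from_dem(Grid(np.full((5, 5), 42.0)))
        np.testing.assert_array_equal(out.values, np.zeros((5, 5)))

    def test_unit_gradient_is_45_degrees(self):
        v = np.tile(np.arange(6.0) * 100, (5, 1))
        out = slope_from_dem(Grid(v, cell_size=100))
        np.testing.assert_allclose(out.values[:, 1:-1], 45.0)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            slope_from_dem(Grid(np.zeros((1, 5))))

    def test_matches_independent_finite_differences(self):
        rng = np.random.default_rng(9)
        from scipy import ndimage
        v = ndimage.uniform_filter(rng.normal(size=(25, 25)) * 500, size=5)
        g = Grid(v, cell_size=100)
        np.testing.assert_allclose(slope_from_dem(g).values, brute_slope(g),
                                   atol=1e-9)
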