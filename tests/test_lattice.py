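import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import catchwalk as cw
from catchwalk.lattice import ConfigError

SQRT2 = math.sqrt(2.0)


class TestNeighbourOffsets:
    def test_square_moore_ring_has_eight_offsets(self):
        offs = cw.neighbour_offsets("square")
        assert len(offs) == 8
        assert (0, 0) not in offs
        assert set(offs) == {
            (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
        }

    def test_hex_ring_has_six_axial_offsets(self):
        offs = cw.neighbour_offsets("hex")
        assert len(offs) == 6
        assert set(offs) == {(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)}

    def test_unknown_shape_rejected(self):
        with pytest.raises(ConfigError):
            cw.neighbour_offsets("triangle")
        with pytest.raises(ConfigError):
            cw.NeighbourhoodSpec("triangle", 10.0)


class TestCellCentre:
    def test_square_origin_cell_centre_convention(self):
        spec = cw.NeighbourhoodSpec("square", 100.0)
        assert cw.cell_centre((0, 0), spec, (0.0, 0.0)) == (50.0, -50.0)

    def test_hex_east_neighbour_is_nsize_away(self):
        spec = cw.NeighbourhoodSpec("hex", 100.0)
        assert cw.cell_centre((1, 0), spec, (0.0, 0.0)) == (100.0, 0.0)

    @given(
        nsize=st.floats(0.1, 1e4),
        q=st.integers(-50, 50),
        r=st.integers(-50, 50),
    )
    def test_hex_ring_distances_all_equal_nsize(self, nsize, q, r):
        spec = cw.NeighbourhoodSpec("hex", nsize)
        c0 = np.array(cw.cell_centre((q, r), spec))
        for dq, dr in cw.neighbour_offsets("hex"):
            c = np.array(cw.cell_centre((q + dq, r + dr), spec))
            assert abs(np.hypot(*(c - c0)) - nsize) <= 1e-9 * nsize

    @given(
        nsize=st.floats(0.1, 1e4),
        i=st.integers(-50, 50),
        j=st.integers(-50, 50),
    )
    def test_square_ring_distances_are_nsize_or_diagonal(self, nsize, i, j):
        spec = cw.NeighbourhoodSpec("square", nsize)
        c0 = np.array(cw.cell_centre((i, j), spec))
        dists = sorted(
            float(np.hypot(*(np.array(cw.cell_centre((i + di, j + dj), spec)) - c0)))
            for di, dj in cw.neighbour_offsets("square")
        )
        for d in dists[:4]:
            assert abs(d - nsize) <= 1e-9 * nsize
        for d in dists[4:]:
            assert abs(d - nsize * SQRT2) <= 1e-9 * nsize


class TestAggregation:
    def test_200m_cell_over_100m_raster_aggregates_four_values(self, grid_surface):
        spec = cw.NeighbourhoodSpec("square", 200.0)
        fp = cw.cell_footprint((2, 3), spec, anchor=grid_surface.origin)
        rows, cols = cw.footprint_members(grid_surface, fp)
        assert len(rows) == 4
        # members are the 2x2 block at raster rows 4-5, cols 6-7
        assert sorted(zip(rows.tolist(), cols.tolist())) == [
            (4, 6), (4, 7), (5, 6), (5, 7)
        ]

    def test_mean_of_2_4_6_8_is_5(self):
        values = np.full((4, 4), 99.0)
        values[0:2, 0:2] = [[2.0, 4.0], [6.0, 8.0]]
        surf = cw.CostSurface(values, 100.0, origin=(0.0, 400.0))
        fp = cw.cell_footprint(
            (0, 0), cw.NeighbourhoodSpec("square", 200.0), anchor=(0.0, 400.0)
        )
        assert cw.aggregate_cell_cost(surf, fp) == 5.0

    @given(
        const=st.floats(-1e3, 1e3),
        shape=st.sampled_from(["square", "hex"]),
        coords=st.tuples(st.integers(0, 3), st.integers(0, 3)),
        nsize=st.sampled_from([50.0, 100.0, 150.0, 250.0]),
    )
    def test_constant_surface_aggregates_to_constant(self, const, shape, coords, nsize):
        surf = cw.CostSurface(
            np.full((10, 10), const), 100.0, origin=(0.0, 1000.0)
        )
        fp = cw.cell_footprint(
            coords, cw.NeighbourhoodSpec(shape, nsize), anchor=(0.0, 1000.0)
        )
        got = cw.aggregate_cell_cost(surf, fp)
        assert got is not None
        assert math.isclose(got, const, rel_tol=1e-12, abs_tol=1e-9)

    def test_mean_matches_arithmetic_oracle_on_random_fixtures(self, rng):
        surf = cw.CostSurface(
            rng.uniform(0, 60, size=(12, 12)), 100.0, origin=(0.0, 1200.0)
        )
        for shape, nsize in [("square", 300.0), ("square", 200.0), ("hex", 250.0)]:
            spec = cw.NeighbourhoodSpec(shape, nsize)
            for coords in [(1, 1), (2, 1), (1, 2), (2, 2)]:
                fp = cw.cell_footprint(coords, spec, anchor=surf.origin)
                rows, cols = cw.footprint_members(surf, fp)
                assert rows.size > 0
                expected = float(np.mean(surf.values[rows, cols]))
                assert cw.aggregate_cell_cost(surf, fp) == pytest.approx(
                    expected, rel=1e-12
                )
                # mean is bounded by member extremes
                got = cw.aggregate_cell_cost(surf, fp)
                assert surf.values[rows, cols].min() <= got <= surf.values[rows, cols].max()

    def test_nsize_equal_resolution_recovers_single_pixel(self, grid_surface):
        spec = cw.NeighbourhoodSpec("square", 100.0)
        for coords in [(0, 0), (3, 7), (9, 9)]:
            fp = cw.cell_footprint(coords, spec, anchor=grid_surface.origin)
            assert cw.aggregate_cell_cost(grid_surface, fp) == grid_surface.values[coords]

    def test_half_open_boundary_left_top_inclusive(self):
        # 100 m pixels, 50 m lattice: pixel centre x=50 sits exactly on the
        # right edge of lattice column 0 and the left edge of column 1.
        surf = cw.CostSurface(np.arange(4.0).reshape(2, 2), 100.0, origin=(0.0, 200.0))
        spec = cw.NeighbourhoodSpec("square", 50.0)
        fp_left = cw.cell_footprint((1, 0), spec, anchor=(0.0, 200.0))
        fp_right = cw.cell_footprint((1, 1), spec, anchor=(0.0, 200.0))
        r0, c0 = cw.footprint_members(surf, fp_left)
        r1, c1 = cw.footprint_members(surf, fp_right)
        assert len(r0) == 0  # centre excluded from the cell it right-bounds
        assert list(zip(r1.tolist(), c1.tolist())) == [(0, 0)]

    def test_sub_resolution_cell_falls_back_to_centroid_sample(self, grid_surface):
        spec = cw.NeighbourhoodSpec("square", 20.0)
        fp = cw.cell_footprint((10, 10), spec, anchor=grid_surface.origin)
        # footprint [200,220]x[-220,-200] from top: inside pixel (2,2)
        assert cw.aggregate_cell_cost(grid_surface, fp) == grid_surface.values[2, 2]

    def test_nodata_excluded_and_all_nodata_invalid(self):
        values = np.array([[2.0, 4.0], [6.0, 8.0]])
        mask = np.array([[True, False], [False, False]])
        surf = cw.CostSurface(values, 100.0, origin=(0.0, 200.0), nodata_mask=mask)
        fp = cw.cell_footprint(
            (0, 0), cw.NeighbourhoodSpec("square", 200.0), anchor=(0.0, 200.0)
        )
        assert cw.aggregate_cell_cost(surf, fp) == pytest.approx((4 + 6 + 8) / 3)
        surf_all = cw.CostSurface(
            values, 100.0, origin=(0.0, 200.0), nodata_mask=np.ones((2, 2), bool)
        )
        assert cw.aggregate_cell_cost(surf_all, fp) is None

    def test_footprint_outside_extent_is_invalid_not_an_exception(self, grid_surface):
        fp = cw.cell_footprint(
            (50, 50), cw.NeighbourhoodSpec("square", 100.0), anchor=grid_surface.origin
        )
        assert cw.aggregate_cell_cost(grid_surface, fp) is None


class TestNeighbourhoodCosts:
    def test_square_interior_matches_direct_index_lookup(self):
        rng = np.random.default_rng(5)
        surf = cw.CostSurface(rng.uniform(1, 9, (5, 5)), 100.0, origin=(0.0, 500.0))
        spec = cw.NeighbourhoodSpec("square", 100.0)
        costs = cw.neighbourhood_costs(surf, (2, 2), spec, anchor=surf.origin)
        assert len(costs) == 8
        for (di, dj), c in costs.items():
            assert c == surf.values[2 + di, 2 + dj]

    def test_hex_interior_has_six_entries(self, random_field):
        spec = cw.NeighbourhoodSpec("hex", 30.0)
        centre = cw.cell_containing((320.0, -320.0), spec)
        costs = cw.neighbourhood_costs(random_field, centre, spec)
        assert len(costs) == 6

    def test_boundary_centre_yields_truncated_ring(self, grid_surface):
        spec = cw.NeighbourhoodSpec("square", 100.0)
        costs = cw.neighbourhood_costs(
            grid_surface, (0, 0), spec, anchor=grid_surface.origin
        )
        assert 0 < len(costs) < 8
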