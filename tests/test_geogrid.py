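import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from satgai.geogrid import (
    DatePairing,
    GridLayer,
    GridSpec,
    Raster,
    aggregate_to_grid,
    build_grid,
    exclude_cells,
    match_dates,
    resample_layer,
)

DATE = dt.date(2019, 5, 1)


def raster(values, origin_x=0.0, origin_y=None, pixel=1.0, band="nir"):
    values = np.asarray(values, dtype=float)
    if origin_y is None:
        origin_y = values.shape[0] * pixel
    return Raster(values, origin_x, origin_y, pixel, band, "uav", DATE)


def brute_force_aggregate(r: Raster, grid: GridSpec):
    """Independent per-pixel assignment oracle: loop over cells, mask pixels."""
    xs, ys = r.pixel_centers()
    X, Y = np.meshgrid(xs, ys)
    values = np.full(grid.shape, np.nan)
    counts = np.zeros(grid.shape)
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            x0, y0, x1, y1 = grid.cell_bounds(row, col)
            inside = (X >= x0) & (X < x1) & (Y >= y0) & (Y < y1)
            vals = r.values[inside]
            vals = vals[np.isfinite(vals)]
            counts[row, col] = vals.size
            if vals.size:
                values[row, col] = vals.mean()
    return values, counts


class TestRasterValidation:
    def test_rejects_reflectance_above_tolerance(self):
        with pytest.raises(ValueError, match="reflectance"):
            raster(np.full((3, 3), 1.6))

    def test_rejects_negative_reflectance(self):
        with pytest.raises(ValueError, match="reflectance"):
            raster(np.full((3, 3), -0.1))

    def test_rejects_nonpositive_pixel(self):
        with pytest.raises(ValueError, match="pixel_size"):
            Raster(np.ones((2, 2)), 0, 2, 0.0, "nir", "uav", DATE)

    def test_slight_super_unity_tolerated(self):
        raster(np.full((2, 2), 1.4))  # no error


class TestBuildGrid:
    @pytest.mark.parametrize(
        "bounds,cell,origin,shape",
        [
            ((10, 10, 30, 30), 10, (10, 30), (2, 2)),  # aligned bounds
            ((3, 7, 38, 27), 10, (0, 30), (3, 4)),  # snapped outward
            ((0, 0, 5, 5), 20, (0, 20), (1, 1)),  # single covering cell
        ],
    )
    def test_covers_bounds_with_snapped_cells(self, bounds, cell, origin, shape):
        g = build_grid(bounds, cell)
        assert (g.origin_x, g.origin_y) == origin
        assert (g.n_rows, g.n_cols) == shape
        xmin, ymin, xmax, ymax = g.bounds
        assert xmin <= bounds[0] and ymin <= bounds[1]
        assert xmax >= bounds[2] and ymax >= bounds[3]

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            build_grid((0, 0, 10, 10), 0)
        with pytest.raises(ValueError):
            build_grid((5, 5, 5, 9), 10)

    @given(
        x0=st.integers(-50, 50),
        y0=st.integers(-50, 50),
        ncols=st.integers(1, 6),
        nrows=st.integers(1, 6),
        cell=st.sampled_from([10.0, 20.0]),
    )
    def test_idempotent_on_own_extent(self, x0, y0, ncols, nrows, cell):
        g = GridSpec(x0 * cell, y0 * cell, cell, ncols, nrows)
        assert build_grid(g.bounds, cell) == g

    def test_origin_must_be_snapped(self):
        with pytest.raises(ValueError, match="multiples"):
            GridSpec(5.0, 0.0, 10.0, 1, 1)


class TestAggregateToGrid:
    def test_constant_raster_gives_constant_cells(self):
        r = raster(np.full((100, 100), 0.5), pixel=0.1)
        layer = aggregate_to_grid(r, build_grid(r.bounds, 5))
        assert layer.valid.all()
        assert np.allclose(layer.values, 0.5)

    def test_half_half_cell_averages(self):
        vals = np.full((10, 10), 0.2)
        vals[:, 5:] = 0.4
        layer = aggregate_to_grid(raster(vals, pixel=1.0), build_grid((0, 0, 10, 10), 10))
        assert layer.values[0, 0] == pytest.approx(0.3)

    def test_low_coverage_flagged_invalid(self):
        # 10 of 100 pixels carry data -> 10% coverage
        vals = np.full((10, 10), np.nan)
        vals[0, :] = 0.3
        layer = aggregate_to_grid(
            raster(vals, pixel=1.0), build_grid((0, 0, 10, 10), 10), min_coverage=0.5
        )
        assert not layer.valid[0, 0]
        # but the same cell passes a 5% threshold
        layer2 = aggregate_to_grid(
            raster(vals, pixel=1.0), build_grid((0, 0, 10, 10), 10), min_coverage=0.05
        )
        assert layer2.valid[0, 0]
        assert layer2.values[0, 0] == pytest.approx(0.3)

    def test_no_overlap_raises(self):
        r = raster(np.ones((4, 4)) * 0.5, origin_x=100.0, origin_y=104.0)
        with pytest.raises(ValueError, match="overlap"):
            aggregate_to_grid(r, GridSpec(0, 10, 10, 1, 1))

    def test_matches_brute_force_oracle_on_random_rasters(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            vals = rng.uniform(0, 1, (50, 50))
            vals[rng.uniform(size=vals.shape) < 0.1] = np.nan
            ox, oy = rng.uniform(-3, 3, 2)
            r = raster(vals, origin_x=ox, origin_y=25 + oy, pixel=0.5)
            grid = build_grid(r.bounds, 5)
            layer = aggregate_to_grid(r, grid, min_coverage=0.05)
            expected, counts = brute_force_aggregate(r, grid)
            ok = layer.valid
            assert np.allclose(layer.values[ok], expected[ok], rtol=0, atol=1e-12)
            np.testing.assert_array_equal(
                ok, counts * r.pixel_size**2 / grid.cell_size**2 >= 0.05 - 1e-12
            )

    def test_area_weighted_conservation(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (40, 60))
        r = raster(vals, pixel=0.5)  # exactly tiles a 10 m grid: 30 x 20 m
        grid = build_grid(r.bounds, 10)
        layer = aggregate_to_grid(r, grid)
        assert layer.valid.all()
        assert np.mean(layer.values) == pytest.approx(vals.mean(), rel=1e-9)


class TestExcludeCells:
    def make_layer(self):
        grid = GridSpec(0, 20, 10, 2, 2)
        return GridLayer(grid, np.arange(4.0).reshape(2, 2), np.ones((2, 2), bool))

    def test_all_false_mask_is_identity(self):
        layer = self.make_layer()
        out = exclude_cells(layer, np.zeros((2, 2), bool))
        np.testing.assert_array_equal(out.valid, layer.valid)
        np.testing.assert_array_equal(out.values, layer.values)

    def test_all_true_mask_invalidates_everything(self):
        out = exclude_cells(self.make_layer(), np.ones((2, 2), bool))
        assert not out.valid.any()

    def test_single_flag_removes_one_cell(self):
        mask = np.zeros((2, 2), bool)
        mask[0, 1] = True
        out = exclude_cells(self.make_layer(), mask)
        assert out.valid.sum() == 3
        assert not out.valid[0, 1]

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            exclude_cells(self.make_layer(), np.zeros((3, 3), bool))


class TestResampleLayer:
    def test_refine_broadcasts_parent_value(self):
        coarse = GridSpec(0, 20, 20, 1, 1)
        layer = GridLayer(coarse, np.array([[1.2]]), np.ones((1, 1), bool))
        fine = resample_layer(layer, GridSpec(0, 20, 10, 2, 2))
        assert np.allclose(fine.values, 1.2)
        assert fine.valid.all()

    def test_coarsen_means_children(self):
        fine = GridSpec(0, 20, 10, 2, 2)
        layer = GridLayer(fine, np.array([[1.0, 2.0], [3.0, 4.0]]), np.ones((2, 2), bool))
        coarse = resample_layer(layer, GridSpec(0, 20, 20, 1, 1))
        assert coarse.values[0, 0] == pytest.approx(2.5)

    def test_coarsen_skips_invalid_children(self):
        fine = GridSpec(0, 20, 10, 2, 2)
        valid = np.ones((2, 2), bool)
        valid[1, 1] = False
        layer = GridLayer(fine, np.array([[1.0, 2.0], [3.0, 4.0]]), valid)
        coarse = resample_layer(layer, GridSpec(0, 20, 20, 1, 1))
        assert coarse.values[0, 0] == pytest.approx(2.0)
        # all children invalid -> parent invalid
        layer2 = GridLayer(fine, np.ones((2, 2)), np.zeros((2, 2), bool))
        coarse2 = resample_layer(layer2, GridSpec(0, 20, 20, 1, 1))
        assert not coarse2.valid[0, 0]

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(3)
        coarse = GridSpec(0, 40, 20, 3, 2)
        layer = GridLayer(coarse, rng.uniform(0, 5, (2, 3)), np.ones((2, 3), bool))
        back = resample_layer(resample_layer(layer, GridSpec(0, 40, 10, 6, 4)), coarse)
        np.testing.assert_allclose(back.values, layer.values, rtol=1e-12)
        assert back.valid.all()

    def test_incompatible_lattice_raises(self):
        layer = GridLayer(GridSpec(0, 20, 10, 2, 2), np.ones((2, 2)), np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="lattice"):
            resample_layer(layer, GridSpec(0, 30, 15, 2, 2))


class TestMatchDates:
    def test_five_day_gap_pairs(self):
        pairs = match_dates([dt.date(2019, 5, 10)], [dt.date(2019, 5, 15)])
        assert len(pairs) == 1 and pairs[0].gap_days == 5

    def test_six_day_gap_does_not_pair(self):
        assert match_dates([dt.date(2019, 5, 10)], [dt.date(2019, 5, 16)]) == []

    def test_tie_breaks_toward_earlier_uav_date(self):
        pairs = match_dates(
            [dt.date(2019, 5, 8), dt.date(2019, 5, 12)], [dt.date(2019, 5, 10)]
        )
        assert len(pairs) == 1
        assert pairs[0].uav_date == dt.date(2019, 5, 8)

    def test_one_to_one(self):
        pairs = match_dates(
            [dt.date(2019, 5, 10)],
            [dt.date(2019, 5, 9), dt.date(2019, 5, 11)],
        )
        assert len(pairs) == 1  # the single UAV date is consumed once

    def test_empty_lists_raise(self):
        with pytest.raises(ValueError):
            match_dates([], [dt.date(2019, 5, 1)])

    def test_pairing_invariant_enforced(self):
        with pytest.raises(ValueError):
            DatePairing(dt.date(2019, 5, 1), dt.date(2019, 5, 9), 8, max_gap_days=5)
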