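"""Bridge variance estimation, rasterization and probability contours."""

import numpy as np
import pytest

from migoverlap.bbmm import (
    BBMMParams,
    ContourRegion,
    Grid,
    ProbabilityRaster,
    contour,
    estimate_motion_variance,
    occurrence_distribution,
)

from conftest import brownian_track, make_track, regular_track


class TestMotionVariance:
    def test_linear_track_gives_zero(self):
        th = np.arange(30) * 4.0
        tr = make_track(th, np.column_stack([th * 500.0, th * 200.0]))
        est = estimate_motion_variance(tr, location_error_sd=1e-3)
        assert est < 1.0  # bridge mean is exact, nothing left to explain

    def test_translation_invariance(self):
        tr = brownian_track(200, 2000.0, 20.0, seed=5)
        moved = tr.subset(np.arange(tr.n))
        moved.xy[:] = tr.xy + np.array([1e6, 1e6])
        a = estimate_motion_variance(tr, 20.0)
        b = estimate_motion_variance(moved, 20.0)
        assert a == pytest.approx(b, rel=1e-6)

    def test_recovers_simulated_variance(self):
        errs = [
            abs(estimate_motion_variance(brownian_track(500, 2000.0, 20.0, s), 20.0) - 2000.0)
            / 2000.0
            for s in range(10)
        ]
        assert np.median(errs) < 0.15

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError):
            estimate_motion_variance(regular_track([[0, 0], [1, 1]]), 20.0)


class TestOccurrenceDistribution:
    def _params(self, **kw):
        base = dict(motion_variance=40000.0, location_error_sd=30.0)
        base.update(kw)
        return BBMMParams(**base)

    def test_mass_is_one(self):
        tr = brownian_track(40, 5000.0, 30.0, seed=2)
        grid = Grid.from_tracks([tr], 50.0, margin=2500.0)
        r = occurrence_distribution(tr, self._params(motion_variance=5000.0), grid)
        assert r.mass == pytest.approx(1.0, abs=1e-9)

    def test_long_gap_bridge_skipped(self):
        # 12-h gap at a 9-h max lag: identical to dropping that bridge
        xy = np.array([[0.0, 0.0], [300.0, 0.0], [3000.0, 3000.0], [3300.0, 3000.0]])
        gap = make_track([0.0, 4.0, 16.0, 20.0], xy)
        grid = Grid.from_bounds(-1200, -1200, 4500, 4200, 50.0)
        r_gap = occurrence_distribution(gap, self._params(), grid)
        a = occurrence_distribution(make_track([0, 4.0], xy[:2]), self._params(), grid)
        b = occurrence_distribution(make_track([0, 4.0], xy[2:]), self._params(), grid)
        # equal-duration bridges: skipping the gap = average of the two halves
        assert np.allclose(r_gap.values, (a.values + b.values) / 2, atol=1e-12)

    def test_no_pair_within_lag_rejected(self):
        tr = make_track([0.0, 20.0], [[0, 0], [100, 0]])
        grid = Grid.from_bounds(-500, -500, 600, 500, 50.0)
        with pytest.raises(ValueError):
            occurrence_distribution(tr, self._params(), grid)

    def test_requires_motion_variance(self):
        tr = regular_track([[0, 0], [100, 0], [150, 0]])
        grid = Grid.from_bounds(-500, -500, 600, 500, 50.0)
        with pytest.raises(ValueError):
            occurrence_distribution(tr, BBMMParams(), grid)

    def test_smooth_path_matches_exact_path(self):
        # the histogram+convolution evaluation (active for lag groups of
        # >= 16 bridges with wide bandwidths) agrees with the per-bridge
        # exact evaluation obtained by splitting the track into short chunks
        tr = brownian_track(121, 30000.0, 20.0, seed=9)
        grid = Grid.from_tracks([tr], 50.0, margin=4000.0)
        p_big = self._params(motion_variance=3e5)
        r_fast = occurrence_distribution(tr, p_big, grid)
        chunks = [
            occurrence_distribution(
                tr.subset(np.arange(i, min(i + 11, tr.n))), p_big, grid
            ).values
            for i in range(0, 120, 10)  # 10 bridges each -> exact path
        ]
        reference = np.mean(chunks, axis=0)  # equal-duration chunks
        assert np.abs(r_fast.values - reference).max() < 2e-6
        assert np.all(r_fast.values >= 0)


class TestRasterIO:
    def test_ascii_round_trip(self, tmp_path):
        grid = Grid.from_bounds(0, 0, 400, 300, 50.0)
        rng = np.random.default_rng(0)
        v = rng.random((grid.n_rows, grid.n_cols))
        r = ProbabilityRaster(grid, v / v.sum())
        r.write_ascii(tmp_path / "r.asc")
        back = ProbabilityRaster.read_ascii(tmp_path / "r.asc")
        assert back.grid == grid
        assert np.allclose(back.values, r.values)


class TestContour:
    def test_uniform_block_minimal_cell_count(self):
        grid = Grid.from_bounds(0, 0, 1000, 1000, 50.0)
        v = np.zeros((grid.n_rows, grid.n_cols))
        v[5:15, 5:15] = 1.0  # uniform 10x10 block
        r = ProbabilityRaster(grid, v / v.sum())
        c = contour(r, 0.95)
        assert int(c.mask.sum()) == 95
        assert c.area_km2 == pytest.approx(95 * 2500 / 1e6)

    def test_single_cell(self):
        grid = Grid.from_bounds(0, 0, 500, 500, 50.0)
        v = np.zeros((grid.n_rows, grid.n_cols))
        v[3, 4] = 1.0
        c = contour(ProbabilityRaster(grid, v), 0.95)
        assert int(c.mask.sum()) == 1
        assert c.area_km2 == pytest.approx(2500 / 1e6)

    def test_gaussian_region_is_chi2_disc(self):
        grid = Grid.from_bounds(-2000, -2000, 2000, 2000, 50.0)
        xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)
        sigma = 300.0
        v = np.exp(-(xc**2 + yc**2) / (2 * sigma**2))
        r = ProbabilityRaster(grid, v / v.sum())
        c = contour(r, 0.95)
        radius = sigma * np.sqrt(-2 * np.log(0.05))  # chi^2_2 95% quantile
        rows, cols = np.nonzero(c.mask)
        d = np.hypot(xc[rows, cols], yc[rows, cols])
        assert d.max() <= radius + grid.resolution
        outside = np.hypot(xc[~c.mask], yc[~c.mask])
        assert outside.min() >= radius - grid.resolution

    def test_levels_nest(self):
        tr = brownian_track(60, 20000.0, 20.0, seed=3)
        grid = Grid.from_tracks([tr], 50.0, margin=2500.0)
        r = occurrence_distribution(
            tr, BBMMParams(motion_variance=20000.0), grid
        )
        c50 = contour(r, 0.50)
        c95 = contour(r, 0.95)
        assert c95.contains(c50)
        assert c50.area_km2 < c95.area_km2

    def test_resolution_halving_stable_area(self):
        sigma = 400.0
        areas = []
        for res in (50.0, 25.0):
            grid = Grid.from_bounds(-2200, -2200, 2200, 2200, res)
            xc, yc = np.meshgrid(grid.x_centers, grid.y_centers)
            v = np.exp(-(xc**2 + yc**2) / (2 * sigma**2))
            areas.append(contour(ProbabilityRaster(grid, v / v.sum()), 0.95).area_km2)
        assert abs(areas[0] - areas[1]) / areas[1] < 0.02

    def test_degenerate_raster_rejected(self):
        grid = Grid.from_bounds(0, 0, 200, 200, 50.0)
        v = np.zeros((grid.n_rows, grid.n_cols))
        v[0, 0] = 1.0
        r = ProbabilityRaster(grid, v)
        r.values[0, 0] = 0.0  # all mass gone
        with pytest.raises(ValueError):
            contour(r, 0.95)

    def test_bad_level_rejected(self):
        grid = Grid.from_bounds(0, 0, 200, 200, 50.0)
        v = np.full((grid.n_rows, grid.n_cols), 1.0)
        r = ProbabilityRaster(grid, v / v.sum())
        with pytest.raises(ValueError):
            contour(r, 1.0)


class TestContourRegionGeometry:
    def test_polygons_from_mask_area_matches(self):
        grid = Grid.from_bounds(0, 0, 500, 500, 50.0)
        v = np.zeros((grid.n_rows, grid.n_cols))
        v[2:5, 2:5] = 1.0
        c = contour(ProbabilityRaster(grid, v / v.sum()), 0.5)
        assert c.polygons.area / 1e6 == pytest.approx(c.area_km2)
        # a cell-center point inside the region is covered
        assert c.covers_points(np.array([[125.0, 125.0]]))[0]
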