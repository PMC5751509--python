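"""Canopy raster tests: max-z projection, hole interpolation vs the
re-scan oracle, ground-plane recovery, subtraction, region growing vs a
set-based simulation, and parcel metrics."""

import numpy as np
import pytest

from croplidar.cloud import ParcelPolygon, PointCloud, voxelize
from croplidar.grid import (
    DegenerateSupportError,
    GroundPlane,
    PixelGrid,
    RegionMask,
    fill_missing_pixels,
    fit_ground_plane,
    grow_crop_region,
    max_z_projection,
    parcel_metrics,
    subtract_ground,
)
from oracles import fill_oracle, region_growing_oracle


def make_grid(values, res=(0.04, 0.04), origin=(0.0, 0.0)):
    return PixelGrid(np.asarray(values, dtype=float), res, np.asarray(origin))


class TestMaxZProjection:
    def test_highest_voxel_centre_wins(self):
        pts = np.array([[0.01, 0.01, 0.0105], [0.01, 0.01, 0.1234]])
        grid = voxelize(PointCloud(pts), origin=np.zeros(3))
        pix = max_z_projection(grid)
        assert pix.values.shape == (1, 1)
        assert pix.values[0, 0] == pytest.approx(0.1235)  # centre of k=123

    def test_single_voxel_gives_its_centre(self):
        grid = voxelize(PointCloud(np.array([[0.0, 0.0, 0.0003]])), origin=np.zeros(3))
        pix = max_z_projection(grid)
        assert pix.values[0, 0] == pytest.approx(0.0005)

    def test_unobserved_column_is_missing(self):
        pts = np.array([[0.01, 0.01, 0.01], [0.13, 0.01, 0.02]])  # columns 0 and 3
        pix = max_z_projection(voxelize(PointCloud(pts), origin=np.zeros(3)))
        assert pix.values.shape == (4, 1)
        assert np.isnan(pix.values[1, 0]) and np.isnan(pix.values[2, 0])

    def test_empty_grid_rejected(self):
        grid = voxelize(PointCloud(np.empty((0, 3))), origin=np.zeros(3))
        with pytest.raises(ValueError):
            max_z_projection(grid)


class TestFillMissingPixels:
    def test_fully_surrounded_hole_takes_neighbour_mean(self):
        v = np.full((3, 3), 0.5)
        v[1, 1] = np.nan
        out = fill_missing_pixels(make_grid(v))
        assert out.values[1, 1] == pytest.approx(0.5)
        assert out.interpolated[1, 1]

    def test_five_neighbours_insufficient(self):
        v = np.full((3, 3), 0.5)
        v[1, 1] = np.nan
        v[0, 0] = v[0, 1] = v[0, 2] = np.nan  # leaves exactly 5 valued neighbours
        out = fill_missing_pixels(make_grid(v))
        assert np.isnan(out.values[1, 1])

    def test_measured_pixels_never_change(self, rng):
        v = np.where(rng.random((12, 12)) < 0.7, rng.normal(size=(12, 12)), np.nan)
        out = fill_missing_pixels(make_grid(v))
        measured = ~np.isnan(v)
        assert np.array_equal(out.values[measured], v[measured])

    def test_three_by_three_hole_matches_rescan_oracle(self, rng):
        v = rng.normal(0.5, 0.02, size=(9, 9))
        v[3:6, 3:6] = np.nan
        out = fill_missing_pixels(make_grid(v))
        expected = fill_oracle(v)
        assert np.allclose(out.values, expected, atol=1e-12, equal_nan=True)

    @pytest.mark.parametrize("density", [0.4, 0.6, 0.8])
    def test_random_grids_match_rescan_oracle(self, rng, density):
        for _ in range(4):
            v = np.where(rng.random((14, 14)) < density, rng.normal(size=(14, 14)), np.nan)
            out = fill_missing_pixels(make_grid(v))
            assert np.allclose(out.values, fill_oracle(v), atol=1e-12, equal_nan=True)

    def test_valued_set_grows_monotonically(self, rng):
        v = np.where(rng.random((14, 14)) < 0.6, 1.0, np.nan)
        out = fill_missing_pixels(make_grid(v))
        assert np.all(out.valid[~np.isnan(v)])
        assert out.valid.sum() >= np.isfinite(v).sum()


class TestFitGroundPlane:
    GROSS = ParcelPolygon(np.array([[0, 0], [2.28, 0], [2.28, 8], [0, 8]], dtype=float), "p")
    NET = ParcelPolygon(np.array([[0, 1], [2.28, 1], [2.28, 7], [0, 7]], dtype=float), "p")

    def _grid_from_plane(self, a0, a1, a2, noise=None, rng=None):
        nx, ny = 57, 200
        g = make_grid(np.full((nx, ny), np.nan))
        xs, ys = g.cell_centers()
        v = a0 * xs + a1 * ys + a2
        if noise is not None:
            v = v + rng.uniform(-noise, noise, size=v.shape)
        return PixelGrid(v, g.resolution, g.origin)

    def test_exact_plane_recovered_to_machine_precision(self):
        grid = self._grid_from_plane(0.01, 0.02, 1.0)
        plane = fit_ground_plane(grid, self.GROSS, self.NET)
        assert plane.a0 == pytest.approx(0.01, abs=1e-12)
        assert plane.a1 == pytest.approx(0.02, abs=1e-12)
        assert plane.a2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_support_recovers_coefficients(self, rng):
        # end strips hold ~2850 support pixels; +-0.03 m uniform noise
        errs = []
        for _ in range(20):
            grid = self._grid_from_plane(0.01, -0.005, 0.5, noise=0.03, rng=rng)
            plane = fit_ground_plane(grid, self.GROSS, self.NET)
            errs.append([plane.a0 - 0.01, plane.a1 + 0.005, plane.a2 - 0.5])
        assert np.max(np.abs(errs)) < 0.005

    def test_collinear_support_rejected(self):
        v = np.full((57, 200), np.nan)
        v[10, :] = 1.0  # a single pixel column: all support collinear
        grid = make_grid(v)
        with pytest.raises(DegenerateSupportError):
            fit_ground_plane(grid, self.GROSS, self.NET)

    def test_too_few_support_pixels_rejected(self):
        v = np.full((57, 200), np.nan)
        v[5, 5] = 1.0
        with pytest.raises(DegenerateSupportError):
            fit_ground_plane(make_grid(v), self.GROSS, self.NET)


class TestSubtractGround:
    def test_flat_grid_minus_matching_plane_is_zero(self):
        g = make_grid(np.full((4, 4), 1.0))
        out = subtract_ground(g, GroundPlane(0.0, 0.0, 1.0))
        assert np.allclose(out.values, 0.0)

    def test_zero_plane_is_identity(self, rng):
        v = rng.normal(size=(5, 5))
        out = subtract_ground(make_grid(v), GroundPlane(0.0, 0.0, 0.0))
        assert np.array_equal(out.values, v)

    def test_tilted_plane_matches_hand_computed_table(self):
        # 3x3 grid, res 1 m, origin 0: centres at 0.5, 1.5, 2.5
        g = PixelGrid(np.full((3, 3), 2.0), (1.0, 1.0), np.zeros(2))
        out = subtract_ground(g, GroundPlane(0.1, 0.2, 0.5))
        expected = 2.0 - np.array(
            [
                [0.65, 0.85, 1.05],
                [0.75, 0.95, 1.15],
                [0.85, 1.05, 1.25],
            ]
        )
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_missing_pixels_stay_missing_and_negatives_kept(self):
        v = np.array([[0.1, np.nan], [0.3, 0.0]])
        out = subtract_ground(make_grid(v), GroundPlane(0.0, 0.0, 0.2))
        assert np.isnan(out.values[0, 1])
        assert out.values[0, 0] == pytest.approx(-0.1)


class TestGrowCropRegion:
    def test_tall_block_excludes_low_surround(self):
        v = np.full((5, 5), 0.05)
        v[1:4, 1:4] = 0.50
        mask = grow_crop_region(make_grid(v), threshold=0.1)
        assert mask.size == 9
        assert mask.mask[1:4, 1:4].all()

    def test_uniform_grid_grows_everywhere(self):
        v = np.full((6, 7), 0.4)
        v[0, 0] = np.nan
        mask = grow_crop_region(make_grid(v), threshold=0.1)
        assert mask.size == 41

    def test_staircase_matches_set_based_oracle(self):
        # concentric rings stepping down 0.05 per ring: all join incrementally
        v = np.full((9, 9), np.nan)
        for ring, h in enumerate([0.50, 0.45, 0.40, 0.35]):
            lo, hi = ring, 9 - ring
            v[lo:hi, lo:hi] = h
        v = v[::-1]  # put the max away from index 0 for a nontrivial seed
        out = grow_crop_region(make_grid(v), threshold=0.1)
        assert np.array_equal(out.mask, region_growing_oracle(v, 0.1))

    def test_random_grids_match_set_based_oracle(self, rng):
        for _ in range(8):
            v = np.where(rng.random((10, 10)) < 0.85, rng.uniform(0.0, 0.6, (10, 10)), np.nan)
            if not np.isfinite(v).any():
                continue
            out = grow_crop_region(make_grid(v), threshold=0.1)
            assert np.array_equal(out.mask, region_growing_oracle(v, 0.1))

    def test_invariant_under_global_height_offset(self, rng):
        v = np.where(rng.random((12, 12)) < 0.9, rng.uniform(0.0, 0.6, (12, 12)), np.nan)
        a = grow_crop_region(make_grid(v), threshold=0.1)
        b = grow_crop_region(make_grid(v + 3.7), threshold=0.1)
        assert np.array_equal(a.mask, b.mask)
        assert a.seed == b.seed

    def test_mask_is_eight_connected_and_contains_seed(self, rng):
        from scipy import ndimage

        v = np.where(rng.random((15, 15)) < 0.7, rng.uniform(0.3, 0.5, (15, 15)), np.nan)
        out = grow_crop_region(make_grid(v), threshold=0.1)
        assert out.mask[out.seed]
        _, n_comp = ndimage.label(out.mask, structure=np.ones((3, 3)))
        assert n_comp == 1

    def test_all_missing_grid_rejected(self):
        with pytest.raises(ValueError):
            grow_crop_region(make_grid(np.full((3, 3), np.nan)))


class TestParcelMetrics:
    def test_worked_example(self):
        v = np.full((10, 10), 0.5)
        mask = RegionMask(np.ones((10, 10), dtype=bool), (0, 0))
        s = parcel_metrics(make_grid(v), mask, cell_area=0.0016, parcel_id="p")
        assert s.mean_height == pytest.approx(0.5)
        assert s.volume == pytest.approx(0.08)
        assert s.n_pixels == 100

    def test_zero_heights_zero_volume(self):
        mask = RegionMask(np.ones((4, 4), dtype=bool), (0, 0))
        s = parcel_metrics(make_grid(np.zeros((4, 4))), mask)
        assert s.volume == 0.0

    def test_volume_linear_in_height_scale(self, rng):
        v = rng.uniform(0.1, 0.6, (8, 8))
        mask = RegionMask(np.ones((8, 8), dtype=bool), (0, 0))
        s1 = parcel_metrics(make_grid(v), mask)
        s3 = parcel_metrics(make_grid(3.0 * v), mask)
        assert s3.volume == pytest.approx(3.0 * s1.volume)

    def test_negative_heights_clamped_in_volume_only(self):
        v = np.array([[0.5, -0.5]])
        mask = RegionMask(np.ones((1, 2), dtype=bool), (0, 0))
        s = parcel_metrics(make_grid(v), mask, cell_area=1.0)
        assert s.mean_height == pytest.approx(0.0)
        assert s.volume == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        v = np.array([[np.nan, 0.5]])
        mask = RegionMask(np.array([[False, True]]), (0, 1))
        bad = make_grid(np.full((1, 2), np.nan))
        with pytest.raises(ValueError):
            parcel_metrics(bad, mask)
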