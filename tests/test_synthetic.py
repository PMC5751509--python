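"""Synthetic-field generator tests: layout geometry, logistic truth,
Poisson sampling statistics, determinism, outlier injection, and the
simulated flight round-trip."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from croplidar.nitrogen import NResponseParams
from croplidar.synthetic import (
    CANOPY,
    GROUND,
    OUTLIER,
    LayoutError,
    SimConfig,
    build_field_layout,
    inject_outliers,
    sample_field_cloud,
    sample_parcel_cloud,
    simulate_flight,
    true_height,
)


class TestBuildFieldLayout:
    def test_trial_design_has_84_parcels(self):
        layout = build_field_layout()
        assert len(layout.parcels) == 84
        assert layout.blocks == 4
        assert layout.n_columns == 21

    def test_net_is_gross_trimmed_one_metre_each_end(self):
        layout = build_field_layout(blocks=1, treatments=[100.0])
        p = layout.parcels[0]
        assert p.gross.area == pytest.approx(2.28 * 8.0)
        assert p.net.area == pytest.approx(2.28 * 6.0)
        assert p.net.geometry.within(p.gross.geometry.buffer(1e-12))

    def test_parcels_pairwise_disjoint(self):
        layout = build_field_layout(blocks=2, treatments=[0.0, 100.0, 200.0])
        polys = [p.gross.geometry for p in layout.parcels]
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                assert not polys[i].intersects(polys[j])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"parcel_size": (0.0, 8.0)},
            {"parcel_size": (2.28, -1.0)},
            {"blocks": 0},
            {"treatments": []},
            {"track_width": 0.0},
        ],
    )
    def test_degenerate_configs_rejected(self, kwargs):
        with pytest.raises(LayoutError):
            build_field_layout(**kwargs)


class TestTrueHeight:
    PARAMS = NResponseParams(c0=0.02, c1=0.20, hmin=0.38)

    def test_zero_dose_is_half_rise_plus_offset(self):
        assert true_height(0.0, self.PARAMS) == pytest.approx(0.38 + 0.10)

    def test_saturates_at_full_rise_plus_offset(self):
        assert true_height(1e6, self.PARAMS) == pytest.approx(0.58)

    def test_zero_steepness_gives_constant_curve(self):
        flat = NResponseParams(c0=0.0, c1=0.20, hmin=0.38)
        for n in (0.0, 50.0, 300.0):
            assert true_height(n, flat) == pytest.approx(0.48)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            true_height(-1.0, self.PARAMS)


class TestSampleParcelCloud:
    def test_fixed_seed_reproduces_cloud_exactly(self, small_layout):
        cfg = SimConfig(seed=42)
        a = sample_parcel_cloud(small_layout, "b1p01", cfg)
        b = sample_parcel_cloud(small_layout, "b1p01", cfg)
        assert np.array_equal(a.cloud.points, b.cloud.points)
        assert np.array_equal(a.labels, b.labels)

    def test_expected_count_is_density_times_gross_area(self, small_layout):
        # Poisson mean 500 * 18.24 = 9120; check the sample mean over seeds
        cfg_counts = []
        n_seeds = 100
        for seed in range(n_seeds):
            lc = sample_parcel_cloud(small_layout, "b1p02", SimConfig(seed=seed))
            cfg_counts.append(len(lc))
        mean_expected = 500.0 * 2.28 * 8.0
        tol = 3.0 * np.sqrt(mean_expected / n_seeds)  # 3 std errors of the mean
        assert abs(np.mean(cfg_counts) - mean_expected) < tol

    def test_noise_free_flat_ground_gives_exact_heights(self):
        layout = build_field_layout(
            blocks=1, treatments=[150.0], ground_plane=(0.0, 0.0, 0.0)
        )
        cfg = SimConfig(noise_half_width=0.0, row_amplitude=0.0, seed=3)
        lc = sample_parcel_cloud(layout, "b1p01", cfg)
        canopy = lc.labels == CANOPY
        h = layout.true_height("b1p01")
        assert np.allclose(lc.cloud.points[canopy, 2], h, atol=1e-12)
        assert np.allclose(lc.cloud.points[~canopy, 2], 0.0, atol=1e-12)

    def test_labels_partition_and_canopy_above_ground(self, small_layout):
        cfg = SimConfig(seed=5)
        lc = sample_parcel_cloud(small_layout, "b1p03", cfg)
        assert np.all(np.isin(lc.labels, [GROUND, CANOPY, OUTLIER]))
        canopy = lc.labels == CANOPY
        ground_z = small_layout.ground_height(
            lc.cloud.points[canopy, 0], lc.cloud.points[canopy, 1]
        )
        assert np.all(lc.cloud.points[canopy, 2] > ground_z)

    def test_mean_canopy_height_matches_logistic_truth(self, small_layout):
        cfg = SimConfig(seed=11)
        lc = sample_parcel_cloud(small_layout, "b1p02", cfg)
        canopy = lc.labels == CANOPY
        pts = lc.cloud.points[canopy]
        above = pts[:, 2] - small_layout.ground_height(pts[:, 0], pts[:, 1])
        h = small_layout.true_height("b1p02")
        assert abs(above.mean() - h) < cfg.noise_half_width

    def test_ground_points_only_in_end_strips(self, small_layout):
        cfg = SimConfig(seed=9)
        lc = sample_parcel_cloud(small_layout, "b1p01", cfg)
        ground = lc.labels == GROUND
        parcel = small_layout.parcel("b1p01")
        minx, miny, maxx, maxy = parcel.bounds
        y = lc.cloud.points[ground, 1]
        in_strips = (y <= miny + small_layout.end_trim) | (y >= maxy - small_layout.end_trim)
        assert in_strips.all()

    def test_unknown_parcel_rejected(self, small_layout):
        with pytest.raises(KeyError):
            sample_parcel_cloud(small_layout, "nope", SimConfig())


class TestInjectOutliers:
    def test_zero_fraction_is_identity(self, small_layout, rng):
        lc = sample_parcel_cloud(small_layout, "b1p01", SimConfig(seed=1))
        out = inject_outliers(lc, 0.0, 1.0, rng)
        assert out is lc

    def test_ceiling_count(self, small_layout, rng):
        lc = sample_parcel_cloud(small_layout, "b1p01", SimConfig(seed=1))
        n = len(lc)
        out = inject_outliers(lc, 0.01, 1.0, rng)
        assert (out.labels == OUTLIER).sum() == int(np.ceil(0.01 * n))

    def test_outliers_at_least_magnitude_from_any_inlier(self, small_layout, rng):
        lc = sample_parcel_cloud(small_layout, "b1p01", SimConfig(seed=2))
        magnitude = 0.8
        out = inject_outliers(lc, 0.02, magnitude, rng)
        inliers = out.cloud.points[out.labels != OUTLIER]
        injected = out.cloud.points[out.labels == OUTLIER]
        d, _ = cKDTree(inliers).query(injected, k=1)
        assert d.min() >= magnitude


class TestSimulateFlight:
    def test_zero_noise_round_trip_is_exact(self, small_layout, noiseless_config):
        rec = simulate_flight(small_layout, "A", noiseless_config)
        mapped = rec.mapped_points()
        truth = rec.truth.cloud.points[rec.observed]
        a = mapped[np.lexsort(mapped.T)]
        b = truth[np.lexsort(truth.T)]
        assert a.shape == b.shape
        assert np.max(np.abs(a - b)) < 1e-9

    def test_path_a_covers_all_parcels_path_b_a_third(self):
        layout = build_field_layout()  # 84 parcels, 21 columns
        cfg = SimConfig(seed=1, density=20.0)  # sparse: coverage logic only
        rec_a = simulate_flight(layout, "A", cfg)
        rec_b = simulate_flight(layout, "B", cfg)
        assert len(rec_a.covered_parcel_ids) == 84
        assert len(rec_b.covered_parcel_ids) == int(np.ceil(84 / 3))

    def test_covered_parcels_actually_observed(self, small_layout):
        cfg = SimConfig(seed=4, density=100.0)
        rec = simulate_flight(small_layout, "B", cfg)
        pts = rec.truth.cloud.points[rec.observed]
        for pid in rec.covered_parcel_ids:
            parcel = small_layout.parcel(pid)
            minx, miny, maxx, maxy = parcel.bounds
            inside = (
                (pts[:, 0] >= minx) & (pts[:, 0] <= maxx)
                & (pts[:, 1] >= miny) & (pts[:, 1] <= maxy)
            )
            assert inside.any()

    def test_pose_stream_strictly_increasing(self, small_layout, noiseless_config):
        rec = simulate_flight(small_layout, "A", noiseless_config)
        ts = np.array([p.timestamp for p in rec.pose_stream])
        assert np.all(np.diff(ts) > 0)

    def test_scan_timestamps_covered_by_pose_stream(self, small_layout, noiseless_config):
        rec = simulate_flight(small_layout, "A", noiseless_config)
        t0 = rec.pose_stream[0].timestamp
        t1 = rec.pose_stream[-1].timestamp
        assert all(t0 <= s.timestamp <= t1 for s in rec.scans)
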