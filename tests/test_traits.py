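"""Trait estimators: plant height, tangent-plane stem diameter, main stem
length, 5 cm region partitioning, convex-hull leaf length, distance density,
the linear leaf-count model, and the accuracy metrics."""

import numpy as np
import pytest

from conftest import make_cylinder
from seedlingpheno import traits
from seedlingpheno.core import PointCloud
from seedlingpheno.errors import (
    BelowSoilError,
    InsufficientPointsError,
    SingularFitError,
    ZeroVarianceError,
)
from seedlingpheno.stem_segmentation import StemPath, segment


def straight_path(length, step=0.005, z0=0.0):
    n = int(round(length / step)) + 1
    coords = np.column_stack([np.zeros(n), np.zeros(n), z0 + np.arange(n) * step])
    return StemPath(nodes=np.arange(n), coords=coords)


class TestPlantHeight:
    def test_hand_evaluated(self):
        cloud = PointCloud(np.array([[0, 0, 0.42], [0, 0, 0.2]]))
        assert np.isclose(traits.plant_height(cloud, 0.12), 0.30)

    def test_noiseless_plant_exact(self, noiseless_seedling):
        plant, truth = noiseless_seedling
        h = traits.plant_height(plant, truth.z_soil)
        assert np.isclose(h, truth.height, atol=1e-12)

    def test_below_soil_errors(self):
        cloud = PointCloud(np.array([[0, 0, 0.1]]))
        with pytest.raises(BelowSoilError):
            traits.plant_height(cloud, 0.12)


class TestStemDiameter:
    def test_vertical_cylinder_within_5_percent(self):
        cyl = make_cylinder(radius=0.002, height=0.10)
        path = straight_path(0.10, z0=0.12)
        d = traits.stem_diameter(cyl, path)
        assert abs(d - 0.004) / 0.004 < 0.05

    def test_tilted_cylinder_tangent_plane_stays_exact(self):
        tilt = np.deg2rad(30)
        cyl = make_cylinder(radius=0.002, height=0.10, tilt=tilt)
        n = 21
        axis = np.array([np.sin(tilt), 0, np.cos(tilt)])
        coords = np.array([[0, 0, 0.12]]) + np.outer(np.arange(n) * 0.005, axis)
        path = StemPath(nodes=np.arange(n), coords=coords)
        d_tan = traits.stem_diameter(cyl, path, projection="tangent")
        d_xoy = traits.stem_diameter(cyl, path, projection="xoy")
        assert abs(d_tan - 0.004) / 0.004 < 0.02
        # the horizontal-plane variant distorts oblique sections
        assert abs(d_xoy - 0.004) > abs(d_tan - 0.004)

    def test_band_with_too_few_points(self):
        path = straight_path(0.10)
        tiny = PointCloud(np.array([[0.001, 0, 0.025], [0, 0.001, 0.025], [0, 0, 0.03]]))
        with pytest.raises(InsufficientPointsError):
            traits.stem_diameter(tiny, path)

    def test_rigid_motion_invariance(self):
        cyl = make_cylinder(radius=0.002, height=0.10)
        path = straight_path(0.10, z0=0.12)
        d0 = traits.stem_diameter(cyl, path)
        ang = 0.7
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        shift = np.array([0.3, -0.2, 0.0])
        moved = PointCloud(cyl.points @ rot.T + shift, cyl.intensity)
        moved_path = StemPath(nodes=path.nodes, coords=path.coords @ rot.T + shift)
        assert abs(traits.stem_diameter(moved, moved_path) - d0) < 1e-6


class TestMainStemLength:
    def test_collinear_chain(self):
        path = straight_path(0.10, step=0.01)
        assert np.isclose(traits.main_stem_length(path), 0.10)

    def test_semicircle_matches_arc_length(self):
        theta = np.deg2rad(np.arange(0, 181, 1))
        coords = np.column_stack([0.1 * np.cos(theta), np.zeros(len(theta)),
                                  0.1 * np.sin(theta)])
        path = StemPath(nodes=np.arange(len(theta)), coords=coords)
        assert abs(traits.main_stem_length(path) - np.pi * 0.1) / (np.pi * 0.1) < 1e-3

    def test_matches_pairwise_sum_oracle(self):
        rng = np.random.default_rng(0)
        coords = np.cumsum(rng.uniform(0.001, 0.01, (30, 3)), axis=0)
        path = StemPath(nodes=np.arange(30), coords=coords)
        oracle = sum(
            float(np.linalg.norm(coords[i + 1] - coords[i])) for i in range(29)
        )
        assert abs(traits.main_stem_length(path) - oracle) < 1e-12

    def test_single_point_warns_and_returns_zero(self):
        path = StemPath(nodes=[0], coords=[[0, 0, 0]])
        with pytest.warns(UserWarning):
            assert traits.main_stem_length(path) == 0.0

    def test_z_rotation_invariance(self):
        rng = np.random.default_rng(1)
        coords = np.cumsum(rng.uniform(0.001, 0.01, (15, 3)), axis=0)
        path = StemPath(nodes=np.arange(15), coords=coords)
        ang = 1.1
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = StemPath(nodes=path.nodes, coords=coords @ rot.T + [0.5, 0.5, 0])
        assert abs(traits.main_stem_length(moved) - traits.main_stem_length(path)) < 1e-12


class TestPartitionRegions:
    def test_exact_division(self):
        regions = traits.partition_regions(straight_path(0.20))
        assert len(regions) == 4
        assert all(np.isclose(r.arc_range[1] - r.arc_range[0], 0.05) for r in regions)

    def test_partial_window_kept(self):
        regions = traits.partition_regions(straight_path(0.225))
        assert len(regions) == 5
        assert np.isclose(regions[-1].arc_range[1] - regions[-1].arc_range[0], 0.025)

    def test_degenerate_short_path_single_region(self):
        regions = traits.partition_regions(straight_path(0.004, step=0.002))
        assert len(regions) == 1

    def test_tiny_partial_merged_into_previous(self):
        regions = traits.partition_regions(straight_path(0.105, step=0.005))
        assert len(regions) == 2
        assert np.isclose(regions[-1].arc_range[1], 0.105)


class TestRegionalLeafLength:
    def _region(self, path):
        return traits.partition_regions(path, 0.05)[0]

    def test_stem_only_region_reports_no_leaves(self):
        path = straight_path(0.05, z0=0.12)
        cyl = make_cylinder(radius=0.002, height=0.05)
        region = self._region(path)
        assert traits.regional_leaf_length(cyl, region, stem_diam=0.01) is None

    def test_symmetric_ring_gives_radius(self):
        path = straight_path(0.05)
        region = self._region(path)
        ang = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        ring = np.column_stack([0.04 * np.cos(ang), 0.04 * np.sin(ang), np.full(200, 0.025)])
        val = traits.regional_leaf_length(PointCloud(ring), region, stem_diam=0.004)
        assert abs(val - 0.04) < 1e-9

    def test_perpendicular_needles_recovered_within_band(self):
        rng = np.random.default_rng(3)
        path = straight_path(0.05)
        region = self._region(path)
        L = 0.04
        pts = [make_cylinder(radius=0.002, height=0.05, z0=0.0).points]
        for _ in range(40):
            phi = rng.uniform(0, 2 * np.pi)
            z = rng.uniform(0.005, 0.045)
            t = np.linspace(0.002, L, 20)
            pts.append(np.column_stack([
                t * np.cos(phi), t * np.sin(phi), np.full(20, z)
            ]))
        cloud = PointCloud(np.vstack(pts))
        val = traits.regional_leaf_length(cloud, region, stem_diam=0.004)
        assert 0.6 * L <= val <= 1.2 * L


class TestDistanceDensity:
    def test_symmetric_pair(self):
        pts = np.array([[0, 0, 0], [0.013, 0, 0]])
        assert np.isclose(traits.distance_density(pts), 0.013)

    def test_regular_grid_equals_spacing(self):
        s = 0.002
        g = np.arange(20) * s
        pts = np.array([[x, y, 0.0] for x in g for y in g])
        assert np.isclose(traits.distance_density(pts), s, atol=1e-12)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(size=(500, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        oracle = d.min(axis=1).mean()
        assert abs(traits.distance_density(pts) - oracle) < 1e-12

    def test_scales_linearly(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(100, 3))
        d1 = traits.distance_density(pts)
        assert np.isclose(traits.distance_density(3.5 * pts), 3.5 * d1, rtol=1e-12)

    def test_fewer_than_two_points(self):
        with pytest.raises(InsufficientPointsError):
            traits.distance_density(np.zeros((1, 3)))


class TestDensityModel:
    def test_noiseless_line_recovered_exactly(self):
        d = np.array([0.001, 0.002, 0.003, 0.004])
        model = traits.fit_density_model(list(zip(d, 10 * d + 2)))
        assert np.isclose(model.slope, 10) and np.isclose(model.intercept, 2)
        assert np.isclose(model.r_squared, 1.0)

    def test_slope_within_3_standard_errors_across_seeded_trials(self):
        # Monte-Carlo calibration: count = -3000 d + 80 with sigma = 5 noise
        a_true, b_true, sigma, n = -3000.0, 80.0, 5.0, 40
        hits = 0
        for trial in range(100):
            rng = np.random.default_rng(trial)
            d = rng.uniform(0.001, 0.003, n)
            c = a_true * d + b_true + rng.normal(0, sigma, n)
            model = traits.fit_density_model(list(zip(d, c)))
            sxx = ((d - d.mean()) ** 2).sum()
            resid = c - (model.slope * d + model.intercept)
            se = np.sqrt((resid**2).sum() / (n - 2) / sxx)
            hits += abs(model.slope - a_true) <= 3 * se
        assert hits >= 97

    def test_degenerate_inputs(self):
        with pytest.raises(SingularFitError):
            traits.fit_density_model([(0.001, 5.0)])
        with pytest.raises(SingularFitError):
            traits.fit_density_model([(0.001, 5.0), (0.001, 7.0)])


class TestLeafCount:
    def test_leafless_regions_count_zero(self):
        cyl = make_cylinder(radius=0.002, height=0.15, z0=0.0)
        path = straight_path(0.15)
        regions = traits.partition_regions(path)
        model = traits.DensityModel(slope=-1000.0, intercept=50.0, r_squared=1.0, n_samples=10)
        total, counts = traits.leaf_count(cyl, regions, model, stem_diam=0.01)
        assert total == 0 and all(c == 0 for c in counts)

    def test_counts_sum_to_total(self, seedling):
        plant, truth = seedling
        res = segment(plant)
        path = res.skeleton
        regions = traits.partition_regions(path)
        leaf_cloud = plant.select(res.leaf_indices)
        model = traits.DensityModel(slope=-3000.0, intercept=60.0, r_squared=0.5, n_samples=30)
        total, counts = traits.leaf_count(leaf_cloud, regions, model,
                                          res.stem_diameter_prelim)
        assert total == sum(counts)
        assert all(c >= 0 for c in counts)


class TestEvaluate:
    def test_identity(self):
        ev = traits.evaluate([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert ev.r == 1.0 and ev.rmse == 0.0 and ev.mae == 0.0 and ev.accuracy == 100.0

    def test_hand_evaluated_offset(self):
        ev = traits.evaluate([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isclose(ev.mae, 1.0) and np.isclose(ev.rmse, 1.0)
        assert np.isclose(ev.r, 1.0)
        assert np.isclose(ev.accuracy, 50.0)  # 100 (1 - 1/2)

    def test_constant_actuals_error(self):
        with pytest.raises(ZeroVarianceError):
            traits.evaluate([1.0, 2.0], [3.0, 3.0])
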