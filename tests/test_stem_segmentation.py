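"""MST main-stem extraction: Kruskal tree vs exhaustive enumeration, longest
path vs path enumeration, canopy trimming, interpolation, stem restoration."""

import itertools

import numpy as np
import pytest

from conftest import make_cylinder
from seedlingpheno import PlantSpec, PointCloud, generate_plant
from seedlingpheno.errors import (
    EmptyStemError,
    InsufficientPointsError,
    MissingIntensityError,
    ShortPathError,
    StageError,
)
from seedlingpheno.skeleton import SkeletonPointSet
from seedlingpheno.stem_segmentation import (
    StemPath,
    build_mst,
    estimate_canopy_length,
    interpolate_skeleton,
    longest_path_from_root,
    preliminary_stem_diameter,
    remove_canopy,
    restore_stem,
    segment,
)
from seedlingpheno import traits


def _min_spanning_weight_bruteforce(pts):
    """Minimum spanning weight by enumerating all (n-1)-edge subsets."""
    n = len(pts)
    edges = [(i, j, float(np.linalg.norm(pts[i] - pts[j])))
             for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        ok = True
        for i, j, _ in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestBuildMST:
    def test_collinear_chain(self):
        pts = np.array([[0, 0, 0], [0, 0, 0.01], [0, 0, 0.02]])
        g = build_mst(pts)
        assert {frozenset((i, j)) for i, j, _ in g.edges} == {frozenset((0, 1)), frozenset((1, 2))}
        assert np.isclose(g.total_weight(), 0.02)
        assert g.root == 0 and g.parent[0] == -1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_weight_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(6, 3))
        g = build_mst(pts)
        assert np.isclose(g.total_weight(), _min_spanning_weight_bruteforce(pts), atol=1e-12)

    def test_single_point_errors(self):
        with pytest.raises(InsufficientPointsError):
            build_mst(np.zeros((1, 3)))

    def test_spanning_tree_invariants(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(25, 3))
        g = build_mst(pts)
        assert len(g.edges) == 24
        assert (g.parent >= 0).sum() == 24  # all but the root have parents


def _enumerate_root_leaf_paths(graph):
    kids = graph.children()
    paths = []

    def walk(node, acc, w):
        if not kids[node]:
            paths.append((w, acc))
            return
        for c in kids[node]:
            walk(c, acc + [c], w + float(np.linalg.norm(graph.points[c] - graph.points[node])))

    walk(graph.root, [graph.root], 0.0)
    return paths


class TestLongestPath:
    def test_pure_path_graph(self):
        pts = np.column_stack([np.zeros(8), np.zeros(8), np.arange(8) * 0.01])
        path = longest_path_from_root(build_mst(pts))
        np.testing.assert_array_equal(path.nodes, np.arange(8))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(rng.integers(4, 12), 3))
        g = build_mst(pts)
        path = longest_path_from_root(g)
        best_w = max(w for w, _ in _enumerate_root_leaf_paths(g))
        assert np.isclose(path.length, best_w, atol=1e-12)

    def test_three_arms_takes_heaviest(self):
        # star: root below centre, three arms of different lengths
        pts = np.array([
            [0, 0, 0.0],  # 0 root
            [0, 0, 0.01],  # 1 hub
            [0.01, 0, 0.011],  # 2 short arm
            [0, 0.02, 0.011],  # 3 medium arm
            [-0.03, 0, 0.011],  # 4 long arm
        ])
        path = longest_path_from_root(build_mst(pts))
        assert path.nodes[-1] == 4

    def test_equal_arms_tie_to_smaller_leaf_index(self):
        pts = np.array([
            [0, 0, 0.0],
            [0, 0, 0.01],
            [0.02, 0, 0.011],
            [-0.02, 0, 0.011],
        ])
        path = longest_path_from_root(build_mst(pts))
        assert path.nodes[-1] == 2


class TestRemoveCanopy:
    def _chain(self, n, step=0.005):
        pts = np.column_stack([np.zeros(n), np.zeros(n), np.arange(n) * step])
        return StemPath(nodes=np.arange(n), coords=pts)

    def test_hand_accumulated_stopping_rule(self):
        # steps of 0.5 cm, threshold 1.2 cm: cumulative sums from the top are
        # 0.5, 1.0, 1.5 -> stop at the 3rd step, top 3 points discarded
        path = self._chain(10)
        out = remove_canopy(path, 0.012)
        assert len(out) == 7
        np.testing.assert_array_equal(out.nodes, np.arange(7))

    def test_zero_threshold_discards_only_the_tip(self):
        out = remove_canopy(self._chain(10), 0.0)
        assert len(out) == 9

    def test_threshold_covering_path_errors(self):
        with pytest.raises(EmptyStemError):
            remove_canopy(self._chain(5), 1.0)

    def test_monotone_in_threshold(self):
        path = self._chain(20)
        sizes = [len(remove_canopy(path, t)) for t in (0.0, 0.01, 0.03, 0.05, 0.08)]
        assert sizes == sorted(sizes, reverse=True)


class TestInterpolateSkeleton:
    def test_insertion_rule_hand_evaluated(self):
        path = StemPath(nodes=[0, 1], coords=[[0, 0, 0], [0, 0, 0.01]])
        out = interpolate_skeleton(path, 0.005)
        np.testing.assert_allclose(
            out.points[:, 2], [0.0, 0.01 / 3, 0.02 / 3, 0.01], atol=1e-12
        )

    def test_large_step_is_noop(self):
        coords = np.array([[0, 0, 0], [0, 0, 0.01], [0.01, 0, 0.02]])
        path = StemPath(nodes=np.arange(3), coords=coords)
        out = interpolate_skeleton(path, 0.05)
        np.testing.assert_array_equal(out.points, coords)

    def test_inserted_points_collinear_and_length_preserved(self):
        rng = np.random.default_rng(0)
        coords = np.cumsum(rng.uniform(0.001, 0.02, size=(10, 3)), axis=0)
        path = StemPath(nodes=np.arange(10), coords=coords)
        out = interpolate_skeleton(path, 0.004)
        dense = StemPath(nodes=np.arange(len(out)), coords=out.points)
        assert abs(dense.length - path.length) < 1e-12
        assert dense.step_lengths.max() <= path.step_lengths.max() + 1e-12
        # each inserted point lies on the segment between original neighbours
        orig = {tuple(np.round(c, 12)) for c in coords}
        k = 0
        for a, b in zip(coords[:-1], coords[1:]):
            seg = b - a
            for p in out.points[k:]:
                if tuple(np.round(p, 12)) in orig and not np.allclose(p, a):
                    break
                cross = np.linalg.norm(np.cross(p - a, seg))
                assert cross < 1e-12 * max(1.0, np.linalg.norm(seg))
                k += 1

    def test_bad_step(self):
        path = StemPath(nodes=[0, 1], coords=[[0, 0, 0], [0, 0, 1]])
        with pytest.raises(ValueError):
            interpolate_skeleton(path, 0.0)


class TestCanopyEstimate:
    def test_symmetric_ring_gives_its_radius(self):
        # path straight up; ring of points above the anchor plane at radius R
        n = 8
        path = StemPath(nodes=np.arange(n),
                        coords=np.column_stack([np.zeros(n), np.zeros(n), np.arange(n) * 0.01]))
        r = 0.04
        ang = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        ring = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.full(100, 0.05)])
        est = estimate_canopy_length(PointCloud(ring), path, k_top=5)
        assert abs(est - r) < 1e-9

    def test_short_path_errors(self):
        path = StemPath(nodes=np.arange(4),
                        coords=np.column_stack([np.zeros(4), np.zeros(4), np.arange(4) * 0.01]))
        with pytest.raises(ShortPathError):
            estimate_canopy_length(PointCloud(np.zeros((5, 3))), path, k_top=5)


class TestRestoreStem:
    def test_partition_and_label_agreement(self, noiseless_seedling):
        plant, truth = noiseless_seedling
        skeleton = SkeletonPointSet(truth.spline)  # perfect skeleton as input
        res = restore_stem(plant, skeleton, radius=truth.stem_diameter)
        # partition invariants
        assert len(res.stem_indices) + len(res.leaf_indices) == len(plant)
        assert not set(res.stem_indices.tolist()) & set(res.leaf_indices.tolist())
        labels = truth.labels
        stem_mask = np.zeros(len(plant), bool)
        stem_mask[res.stem_indices] = True
        assert stem_mask[labels == "stem"].mean() >= 0.95
        # needle points beyond the radius must be classified leaf
        d = truth.spline_distance(plant.points)
        far_needles = (labels == "needle") & (d > truth.stem_diameter)
        assert (~stem_mask[far_needles]).mean() >= 0.95

    def test_tiny_radius_keeps_nothing(self, noiseless_seedling):
        plant, truth = noiseless_seedling
        skeleton = SkeletonPointSet(truth.spline + 1.0)  # far away
        res = restore_stem(plant, skeleton, radius=1e-9)
        assert len(res.stem_indices) == 0


class TestPreliminaryDiameter:
    def test_noiseless_cylinder_within_5_percent(self):
        cyl = make_cylinder(radius=0.002, height=0.25)
        seg_res = segment(cyl)
        # rebuild the uninterpolated lower path from the final skeleton
        d = preliminary_stem_diameter(cyl, seg_res.skeleton)
        assert abs(d - 0.004) / 0.004 < 0.05

    def test_band_without_points_errors(self):
        path = StemPath(nodes=np.arange(6),
                        coords=np.column_stack([np.zeros(6), np.zeros(6), np.arange(6) * 0.01]))
        far_cloud = PointCloud(np.random.default_rng(0).normal(size=(50, 3)) + 5.0)
        with pytest.raises(InsufficientPointsError):
            preliminary_stem_diameter(far_cloud, path)

    def test_consistent_with_public_estimator_on_cylinder(self):
        cyl = make_cylinder(radius=0.002, height=0.25)
        res = segment(cyl)
        d1 = preliminary_stem_diameter(cyl, res.skeleton)
        d2 = traits.stem_diameter(cyl, res.skeleton)
        assert abs(d1 - d2) < 1e-9


class TestSegmentPipeline:
    @pytest.mark.parametrize("height", [0.27, 0.22, 0.17])
    def test_three_height_classes_complete(self, height):
        plant, truth = generate_plant(PlantSpec(height=height, seed=8))
        res = segment(plant)
        assert len(res.stem_indices) + len(res.leaf_indices) == len(plant)
        assert res.skeleton.length > 0.5 * truth.main_stem_length

    def test_leafless_cylinder_has_almost_no_leaf_points(self):
        cyl = make_cylinder(radius=0.002, height=0.25, z0=0.12)
        res = segment(cyl)
        # only the very top of the cylinder (above the trimmed skeleton) can
        # fall outside the restoration radius
        leaf_frac = len(res.leaf_indices) / len(cyl)
        assert leaf_frac < 0.06
        if len(res.leaf_indices):
            z = cyl.points[res.leaf_indices, 2]
            near_rims = (z < 0.12 + 0.02) | (z > 0.12 + 0.25 - 0.02)
            assert near_rims.all()

    def test_missing_intensity_reported_with_stage_tag(self):
        cloud = PointCloud(np.random.default_rng(0).normal(size=(100, 3)))
        with pytest.raises(StageError) as err:
            segment(cloud)
        assert err.value.stage == "skeletonize"
        assert isinstance(err.value.original, MissingIntensityError)

    def test_noiseless_skeleton_tracks_spline(self, noiseless_seedling):
        plant, truth = noiseless_seedling
        res = segment(plant)
        d = truth.spline_distance(res.skeleton.coords)
        assert np.mean(d <= truth.stem_diameter) >= 0.95
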