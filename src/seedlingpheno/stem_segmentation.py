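"""Main-stem extraction and stem-leaf segmentation.

A Euclidean minimum spanning tree links the candidate skeleton points; the
heaviest root-to-leaf path in the tree (rooted at the lowest point) is the
main stem plus the apical canopy.  The canopy's extent is estimated by
projecting everything above a near-top skeleton point onto its tangent plane
and averaging the convex-hull radius; that much path length is trimmed from
the top.  The remaining skeleton is densified by linear interpolation at the
preliminary stem-diameter step, and every cloud point within one diameter of
the densified skeleton is restored as stem; the complement is leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .core import Plane, PointCloud, convex_hull_2d, project_to_plane
from .errors import (
    EmptyCloudError,
    EmptyStemError,
    InsufficientPointsError,
    ShortPathError,
    StageError,
)
from .skeleton import SkeletonPointSet, skeletonize

__all__ = [
    "SkeletonGraph",
    "StemPath",
    "SegmentationResult",
    "build_mst",
    "longest_path_from_root",
    "estimate_canopy_length",
    "remove_canopy",
    "interpolate_skeleton",
    "preliminary_stem_diameter",
    "restore_stem",
    "segment",
]


@dataclass
class SkeletonGraph:
    """Euclidean MST over skeleton points, rooted at the lowest point and
    oriented away from the root via a parent map."""

    points: np.ndarray
    edges: list  # (i, j, weight)
    root: int
    parent: np.ndarray  # parent[i] = parent node index, -1 at the root

    def children(self) -> dict:
        kids: dict[int, list[int]] = {i: [] for i in range(len(self.points))}
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[int(p)].append(i)
        return kids

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


@dataclass
class StemPath:
    """Ordered skeleton path from root to tip."""

    nodes: np.ndarray  # indices into the originating point set
    coords: np.ndarray  # (m, 3) path coordinates, root first

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=int)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.float64))

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    @property
    def length(self) -> float:
        return float(self.step_lengths.sum())

    @property
    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length from the root at each path point."""
        return np.concatenate([[0.0], np.cumsum(self.step_lengths)])


@dataclass
class SegmentationResult:
    """Partition of the plant cloud into stem and leaf points, plus the final
    interpolated main-stem skeleton."""

    stem_indices: np.ndarray
    leaf_indices: np.ndarray
    skeleton: StemPath
    stem_diameter_prelim: float
    diagnostics: dict = field(default_factory=dict)


def build_mst(skeleton: SkeletonPointSet | np.ndarray) -> SkeletonGraph:
    """Kruskal MST of the complete Euclidean graph over skeleton points,
    rooted at the point of minimum z; orientation by traversal from the root."""
    pts = skeleton.points if isinstance(skeleton, SkeletonPointSet) else np.atleast_2d(np.asarray(skeleton, float))
    n = len(pts)
    if n < 2:
        raise InsufficientPointsError(f"MST needs >= 2 skeleton points, got {n}")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    iu, ju = np.triu_indices(n, k=1)
    g.add_weighted_edges_from(zip(iu.tolist(), ju.tolist(), dist[iu, ju].tolist()))
    t = nx.minimum_spanning_tree(g, algorithm="kruskal")
    root = int(np.argmin(pts[:, 2]))
    parent = np.full(n, -1, dtype=int)
    for child, par in nx.bfs_predecessors(t, root):
        parent[child] = par
    edges = [(i, j, float(d["weight"])) for i, j, d in t.edges(data=True)]
    return SkeletonGraph(points=pts, edges=edges, root=root, parent=parent)


def longest_path_from_root(graph: SkeletonGraph) -> StemPath:
    """Heaviest root-to-leaf path of the rooted tree (the tree oriented away
    from the root is a DAG, so one post-order pass suffices).  Ties are broken
    toward the smaller leaf index."""
    kids = graph.children()
    n = len(graph.points)
    weight_to = {}
    best_leaf = {}
    order = []
    stack = [graph.root]
    seen = np.zeros(n, dtype=bool)
    while stack:  # iterative DFS, children pushed for post-order resolution
        node = stack.pop()
        seen[node] = True
        order.append(node)
        stack.extend(kids[node])
    for node in reversed(order):
        if not kids[node]:
            weight_to[node] = 0.0
            best_leaf[node] = node
            continue
        best_w, best_l, best_c = -1.0, None, None
        for c in kids[node]:
            w = weight_to[c] + float(np.linalg.norm(graph.points[c] - graph.points[node]))
            if w > best_w or (w == best_w and best_leaf[c] < best_l):
                best_w, best_l, best_c = w, best_leaf[c], c
        weight_to[node] = best_w
        best_leaf[node] = best_l
        kids[node] = [best_c] + [c for c in kids[node] if c != best_c]
    nodes = [graph.root]
    while kids[nodes[-1]]:
        nodes.append(kids[nodes[-1]][0])
    nodes = np.array(nodes, dtype=int)
    return StemPath(nodes=nodes, coords=graph.points[nodes])


def estimate_canopy_length(cloud: PointCloud, path: StemPath, k_top: int = 5) -> float:
    """Estimate the apical canopy's extent.

    The ``k_top``-th path point from the tip anchors a plane perpendicular to
    the local path direction; every cloud point above the plane is projected
    onto it and the mean distance of the projection's convex-hull vertices to
    the anchor is the canopy length.
    """
    if len(path) < k_top + 1:
        raise ShortPathError(f"path has {len(path)} points; need >= {k_top + 1}")
    if len(cloud) == 0:
        raise EmptyCloudError("cannot estimate canopy length from an empty cloud")
    anchor = len(path) - k_top
    center = path.coords[anchor]
    # direction toward the upper neighbours, averaged over two steps so a
    # single noisy skeleton point cannot tilt the projection plane
    upper = path.coords[min(anchor + 2, len(path) - 1)]
    normal = upper - center
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise ShortPathError("degenerate path step at the canopy anchor")
    plane = Plane(center=center, normal=normal / norm)
    above = plane.signed_distance(cloud.points) > 0
    proj = project_to_plane(cloud.points[above], plane)
    hull = convex_hull_2d(proj)  # raises DegenerateHullError when < 3 points
    return float(np.linalg.norm(hull, axis=1).mean())


def remove_canopy(path: StemPath, canopy_len: float) -> StemPath:
    """Trim the canopy from the top of the path.

    Walking down from the tip and accumulating step distances, the first
    point whose cumulative distance from the tip exceeds ``canopy_len`` is the
    canopy/stem boundary; everything strictly above it is discarded.
    """
    if canopy_len < 0:
        raise ValueError("canopy_len must be nonnegative")
    steps = path.step_lengths[::-1]  # from the top downward
    cum = np.concatenate([[0.0], np.cumsum(steps)])  # cum[i] = distance tip -> i-th from top
    keep_from_top = np.nonzero(cum > canopy_len)[0]
    if len(keep_from_top) == 0:
        raise EmptyStemError("canopy length covers the whole path; no stem remains")
    boundary = len(path) - 1 - int(keep_from_top[0])  # index from the root
    return StemPath(nodes=path.nodes[: boundary + 1], coords=path.coords[: boundary + 1])


def interpolate_skeleton(path: StemPath, step: float) -> SkeletonPointSet:
    """Densify the path: between each adjacent pair at distance D, insert
    floor(D/step) equally spaced points by linear interpolation.  Original
    points are preserved in order; total length is unchanged."""
    if step <= 0:
        raise ValueError("interpolation step must be positive")
    if len(path) < 2:
        raise ShortPathError("interpolation needs at least 2 path points")
    out = [path.coords[0]]
    for a, b in zip(path.coords[:-1], path.coords[1:]):
        d = float(np.linalg.norm(b - a))
        m = int(np.floor(d / step + 1e-9))
        for i in range(1, m + 1):
            out.append(a + (b - a) * (i / (m + 1)))
        out.append(b)
    return SkeletonPointSet(np.array(out))


def preliminary_stem_diameter(
    cloud: PointCloud,
    path: StemPath,
    capture_radius: float = 0.015,
    capture_arc: float = 0.06,
) -> float:
    """Stem diameter near the soil, used as interpolation step and restoration
    radius.  Candidate points are gathered in a generous cylinder around the
    lowest path segments (the near-soil stem carries no needles), then the
    tangent-plane ellipse estimator is applied."""
    from .traits import stem_diameter

    arc = path.arc_positions
    upto = int(np.searchsorted(arc, capture_arc, side="right"))
    seg_pts = path.coords[: max(upto, 2)]
    mask = _within_polyline_radius(cloud.points, seg_pts, capture_radius)
    if mask.sum() < 5:
        raise InsufficientPointsError("too few points near the lowest stem segment")
    return stem_diameter(cloud.select(mask), path)


def _within_polyline_radius(points: np.ndarray, poly: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of points within ``radius`` of any segment of ``poly``."""
    best = np.full(len(points), np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom < 1e-18:
            d = np.linalg.norm(points - a, axis=1)
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
            d = np.linalg.norm(points - (a + t[:, None] * ab), axis=1)
        best = np.minimum(best, d)
    return best <= radius


def restore_stem(
    cloud: PointCloud, expanded: SkeletonPointSet, radius: float
) -> SegmentationResult:
    """Restore the stem point cloud: every cloud point within ``radius`` of any
    expanded skeleton point is stem; the complement is leaves."""
    if radius <= 0:
        raise ValueError("restoration radius must be positive")
    if len(expanded) == 0:
        raise EmptyCloudError("expanded skeleton is empty")
    tree = cKDTree(expanded.points)
    d, _ = tree.query(cloud.points)
    stem_mask = d <= radius
    skeleton_path = StemPath(nodes=np.arange(len(expanded)), coords=expanded.points)
    return SegmentationResult(
        stem_indices=np.nonzero(stem_mask)[0],
        leaf_indices=np.nonzero(~stem_mask)[0],
        skeleton=skeleton_path,
        stem_diameter_prelim=radius,
    )


def segment(
    cloud: PointCloud,
    n_layers: int = 30,
    n_x: int = 5,
    x_thresh: float = 0.02,
    cluster_tol: float = 0.01,
    cluster_min_size: int = 30,
    k_top: int = 5,
) -> SegmentationResult:
    """Full stem-leaf segmentation of a preprocessed plant cloud.

    skeletonize -> MST -> longest path -> canopy estimate/removal ->
    preliminary stem diameter -> interpolation -> stem restoration.  Errors
    raised by a stage are wrapped in StageError with the stage name.
    """
    diag: dict = {"n_points": len(cloud)}

    def run(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage tag
            raise StageError(stage, exc) from exc

    candidates = run("skeletonize", skeletonize, cloud, n_layers, n_x, x_thresh,
                     cluster_tol, cluster_min_size)
    diag["n_skeleton_candidates"] = len(candidates)
    graph = run("build_mst", build_mst, candidates)
    path = run("longest_path", longest_path_from_root, graph)
    diag["n_path_points"] = len(path)
    canopy_len = run("canopy_estimate", estimate_canopy_length, cloud, path, k_top)
    diag["canopy_length"] = canopy_len
    stem_path = run("remove_canopy", remove_canopy, path, canopy_len)
    diag["n_stem_path_points"] = len(stem_path)
    z_lowest = float(cloud.z.min())
    z_extent = float(cloud.z.max()) - z_lowest
    if stem_path.coords[0, 2] > z_lowest + 0.1 * z_extent:
        diag["warning_root_above_bottom"] = True
    diameter = run("stem_diameter_prelim", preliminary_stem_diameter, cloud, stem_path)
    diag["stem_diameter_prelim"] = diameter
    expanded = run("interpolate", interpolate_skeleton, stem_path, diameter)
    diag["n_expanded_skeleton"] = len(expanded)
    result = run("restore", restore_stem, cloud, expanded, diameter)
    result.stem_diameter_prelim = diameter
    diag["n_stem_points"] = len(result.stem_indices)
    diag["n_leaf_points"] = len(result.leaf_indices)
    result.diagnostics = diag
    return result
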