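"""Slice-based grayscale skeletonization.

The preprocessed plant cloud is sliced into uniform height layers, each layer
is split into Euclidean clusters, and wide clusters (stem plus needles) are
subdivided into bins along x.  The stem is optically brighter than the
needles, so the x-bin with the largest mean grayscale marks the stem; its
centroid (or the whole-cluster centroid for narrow clusters) becomes a
candidate main-stem skeleton point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import PointCloud, centroid
from .errors import EmptyCloudError, MissingIntensityError

__all__ = [
    "SliceLayer",
    "SkeletonPointSet",
    "slice_z",
    "euclidean_cluster",
    "x_extent",
    "select_stem_subslice",
    "skeletonize",
]


@dataclass
class SliceLayer:
    """One height slice: half-open z interval [low, high) (top layer closed)
    and the indices of the parent cloud's points inside it."""

    index: int
    z_range: tuple
    point_indices: np.ndarray


@dataclass
class SkeletonPointSet:
    """Candidate skeleton points with provenance (z-layer, cluster id, x-bin;
    -1 where not applicable, e.g. interpolated points)."""

    points: np.ndarray
    layer: np.ndarray | None = None
    cluster: np.ndarray | None = None
    sublayer: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if not np.isfinite(self.points).all():
            raise ValueError("skeleton points must be finite")
        n = len(self.points)
        for name in ("layer", "cluster", "sublayer"):
            v = getattr(self, name)
            if v is None:
                setattr(self, name, np.full(n, -1, dtype=int))
            else:
                setattr(self, name, np.asarray(v, dtype=int))

    def __len__(self) -> int:
        return len(self.points)


def slice_z(cloud: PointCloud, n_layers: int = 30) -> list[SliceLayer]:
    """Partition the cloud into ``n_layers`` uniform-width z layers.

    Layer width is (z_max - z_min)/n_layers; every point lands in exactly one
    layer (the top boundary closes into the last layer); empty layers are
    kept so that layer index always equals floor((z - z_min)/width).
    """
    if len(cloud) == 0:
        raise EmptyCloudError("cannot slice an empty cloud")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    z = cloud.z
    z_min, z_max = float(z.min()), float(z.max())
    if z_max - z_min <= 0:
        raise ValueError("cloud has zero z-extent; slicing is undefined")
    width = (z_max - z_min) / n_layers
    idx = np.clip(np.floor((z - z_min) / width).astype(int), 0, n_layers - 1)
    layers = []
    for i in range(n_layers):
        layers.append(
            SliceLayer(
                index=i,
                z_range=(z_min + i * width, z_min + (i + 1) * width),
                point_indices=np.nonzero(idx == i)[0],
            )
        )
    return layers


def euclidean_cluster(points: np.ndarray, tol: float, min_size: int = 1) -> list[np.ndarray]:
    """Connected components of the graph linking points within ``tol``;
    components smaller than ``min_size`` are discarded.  Clusters are returned
    as index arrays, ordered by their smallest member index."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    pts = np.atleast_2d(np.asarray(points, float))
    n = len(pts)
    if n == 0:
        return []
    tree = cKDTree(pts)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        if len(members) >= min_size:
            clusters.append(members)
    clusters.sort(key=lambda m: int(m[0]))
    return clusters


def x_extent(points: np.ndarray) -> float:
    """max(x) - min(x) of a non-empty cluster."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        raise EmptyCloudError("x_extent of an empty cluster is undefined")
    return float(pts[:, 0].max() - pts[:, 0].min())


def select_stem_subslice(
    points: np.ndarray,
    intensity: np.ndarray | None,
    n_x: int = 5,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Split a cluster into ``n_x`` uniform x bins and pick the bin with the
    largest mean grayscale (the stem is brighter than the needles).

    Ties go to the bin whose centre is nearest the cluster's x median, then to
    the lower index.  Returns (chosen points, their centroid, bin index).
    """
    if intensity is None:
        raise MissingIntensityError("grayscale sub-slice selection needs intensities")
    if n_x < 2:
        raise ValueError("n_x must be >= 2")
    pts = np.atleast_2d(np.asarray(points, float))
    inten = np.asarray(intensity, float).ravel()
    if len(inten) != len(pts):
        raise ValueError("intensity length must match point count")
    x = pts[:, 0]
    x_min, x_max = x.min(), x.max()
    extent = x_max - x_min
    if extent <= 0:
        return pts, centroid(pts), 0
    width = extent / n_x
    bins = np.clip(np.floor((x - x_min) / width).astype(int), 0, n_x - 1)
    means = np.full(n_x, -np.inf)
    for b in range(n_x):
        mask = bins == b
        if mask.any():
            means[b] = inten[mask].mean()
    best = means.max()
    candidates = np.nonzero(means == best)[0]
    if len(candidates) > 1:
        med = np.median(x)
        centers = x_min + (candidates + 0.5) * width
        candidates = candidates[np.abs(centers - med) == np.abs(centers - med).min()]
    chosen = int(candidates[0])
    mask = bins == chosen
    return pts[mask], centroid(pts[mask]), chosen


def skeletonize(
    cloud: PointCloud,
    n_layers: int = 30,
    n_x: int = 5,
    x_thresh: float = 0.02,
    cluster_tol: float = 0.01,
    cluster_min_size: int = 30,
) -> SkeletonPointSet:
    """Candidate main-stem skeleton points for a preprocessed plant cloud.

    Per z layer and per Euclidean cluster: clusters wider than ``x_thresh``
    along x (stem plus needles) contribute the centroid of their brightest
    x bin; narrow clusters contribute their plain centroid.  Layers whose
    clusters all fall below ``cluster_min_size`` contribute nothing.
    """
    if cloud.intensity is None:
        raise MissingIntensityError("skeletonization requires grayscale intensities")
    layers = slice_z(cloud, n_layers)
    pts_out, layer_ids, cluster_ids, sub_ids = [], [], [], []
    for layer in layers:
        idx = layer.point_indices
        if len(idx) == 0:
            continue
        pts = cloud.points[idx]
        inten = cloud.intensity[idx]
        for ci, members in enumerate(euclidean_cluster(pts, cluster_tol, cluster_min_size)):
            cpts = pts[members]
            if x_extent(cpts) > x_thresh:
                _, c, b = select_stem_subslice(cpts, inten[members], n_x)
            else:
                c, b = centroid(cpts), -1
            pts_out.append(c)
            layer_ids.append(layer.index)
            cluster_ids.append(ci)
            sub_ids.append(b)
    if not pts_out:
        raise EmptyCloudError("no clusters large enough to yield skeleton points")
    return SkeletonPointSet(
        np.array(pts_out), np.array(layer_ids), np.array(cluster_ids), np.array(sub_ids)
    )
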