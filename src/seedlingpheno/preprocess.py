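"""Scene clean-up: pass-through background removal, RANSAC platform removal,
radius outlier filtering, soil/pot removal, normals and feature points.

The pipeline contract applies these in order background -> platform ->
radius -> soil; every filter returns a subset of its input with point order
preserved.  Two-view registration lives in :mod:`seedlingpheno.registration`
and is re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Plane, PointCloud
from .errors import EmptyCloudError, EmptyPlantError, InsufficientPointsError

__all__ = [
    "SceneGeometry",
    "passthrough_bounds",
    "passthrough_filter",
    "ransac_plane",
    "radius_outlier_filter",
    "remove_soil_and_pot",
    "estimate_normals",
    "detect_feature_points",
    "RigidTransform",
    "RegistrationParams",
    "RegistrationResult",
    "register",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class SceneGeometry:
    """Acquisition geometry: camera-to-curtain distance ``dcc``, camera-to-plant
    distance ``dcp``, flowerpot height and the soil band above the platform."""

    dcc: float
    dcp: float
    pot_height: float = 0.12
    soil_band: tuple = (0.07, 0.12)

    def __post_init__(self):
        if not (0 < self.dcp <= self.dcc):
            raise ValueError("require 0 < dcp <= dcc")
        low, high = self.soil_band
        if not (low < high):
            raise ValueError("soil_band must be (low, high) with low < high")
        if abs(high - self.pot_height) > 1e-9:
            raise ValueError("soil_band upper edge must equal pot_height")


def passthrough_bounds(geom: SceneGeometry, cloud: PointCloud) -> tuple[float, float]:
    """Depth-axis pass-through bounds: the far bound is the maximum depth in
    the cloud (the curtain), the near-of-curtain bound scales it by
    (dcc - dcp)/dcc — the platform-to-curtain distance."""
    if len(cloud) == 0:
        raise EmptyCloudError("cannot derive pass-through bounds from an empty cloud")
    pt_lb = float(cloud.y.max())
    pt_ub = (geom.dcc - geom.dcp) / geom.dcc * pt_lb
    return pt_lb, pt_ub


def passthrough_filter(cloud: PointCloud, axis: str, lower: float, upper: float) -> PointCloud:
    """Retain exactly the points whose ``axis`` coordinate lies in [lower, upper]."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of x/y/z, got {axis!r}")
    if not lower < upper:
        raise ValueError(f"inverted bounds: lower={lower} >= upper={upper}")
    coord = cloud.points[:, _AXES[axis]]
    return cloud.select((coord >= lower) & (coord <= upper))


def ransac_plane(
    cloud: PointCloud,
    dist_thresh: float = 0.005,
    iterations: int = 1000,
    seed: int = 0,
) -> tuple[Plane, np.ndarray]:
    """RANSAC plane fit: sampled point triples, inliers within ``dist_thresh``,
    least-squares refit on the winning inlier set.  Deterministic given seed."""
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise InsufficientPointsError(f"plane fit needs >= 3 points, got {n}")
    if dist_thresh <= 0:
        raise ValueError("dist_thresh must be positive")
    if np.allclose(pts, pts[0], atol=1e-12):
        raise InsufficientPointsError("all points identical; plane undefined")

    rng = np.random.default_rng(seed)
    triples = rng.integers(0, n, size=(iterations, 3))
    best_count, best_normal, best_point = -1, None, None
    for i, j, k in triples:
        p0, p1, p2 = pts[i], pts[j], pts[k]
        nrm = np.cross(p1 - p0, p2 - p0)
        norm = np.linalg.norm(nrm)
        if norm < 1e-12:
            continue
        nrm = nrm / norm
        count = int((np.abs((pts - p0) @ nrm) <= dist_thresh).sum())
        if count > best_count:
            best_count, best_normal, best_point = count, nrm, p0
    if best_normal is None:
        raise InsufficientPointsError("no non-degenerate sample triple found")

    # least-squares refit (total least squares via SVD) on the inliers
    inliers = np.abs((pts - best_point) @ best_normal) <= dist_thresh
    sub = pts[inliers]
    center = sub.mean(axis=0)
    _, _, vt = np.linalg.svd(sub - center, full_matrices=False)
    normal = vt[-1]
    # deterministic orientation: prefer +z, then +y, then +x
    for c in (2, 1, 0):
        if abs(normal[c]) > 1e-12:
            if normal[c] < 0:
                normal = -normal
            break
    inliers = np.abs((pts - center) @ normal) <= dist_thresh
    return Plane(center=center, normal=normal), np.nonzero(inliers)[0]


def radius_outlier_filter(cloud: PointCloud, r: float = 0.01, k: int = 10) -> PointCloud:
    """Keep points having at least ``k`` other points within radius ``r`` in the
    original cloud (single pass, no cascading re-evaluation)."""
    if r <= 0 or k < 1:
        raise ValueError("require r > 0 and k >= 1")
    if len(cloud) == 0:
        return cloud.select(np.zeros(0, dtype=int))
    tree = cKDTree(cloud.points)
    counts = tree.query_ball_point(cloud.points, r, return_length=True)
    return cloud.select(counts - 1 >= k)  # count includes the point itself


def remove_soil_and_pot(
    cloud: PointCloud, platform_z: float, geom: SceneGeometry
) -> tuple[PointCloud, float]:
    """Drop everything at or below the soil surface, which sits ``pot_height``
    above the detected platform plane.  Returns (plant cloud, z_soil)."""
    z_soil = platform_z + geom.pot_height
    mask = cloud.z > z_soil
    if not mask.any():
        raise EmptyPlantError(f"no points above the soil plane z={z_soil:.3f}")
    return cloud.select(mask), z_soil


def estimate_normals(cloud: PointCloud, k: int = 10) -> np.ndarray:
    """Per-point unit normals from PCA of the k nearest neighbours: the
    eigenvector of the local covariance with the smallest eigenvalue, sign
    oriented toward the camera (-y half-space)."""
    n = len(cloud)
    if n <= k:
        raise InsufficientPointsError(f"need more than k={k} points, got {n}")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k + 1)
    neigh = cloud.points[idx]  # (n, k+1, 3), includes the point itself
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nij,nik->njk", centered, centered) / (k + 1)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # eigenvector of the smallest eigenvalue
    # orient toward the camera: n_y <= 0; break exact ties toward +z then +x
    flip = normals[:, 1] > 0
    tie = normals[:, 1] == 0
    flip |= tie & (normals[:, 2] < 0)
    flip |= tie & (normals[:, 2] == 0) & (normals[:, 0] < 0)
    normals[flip] *= -1.0
    return normals


def detect_feature_points(
    cloud: PointCloud,
    normals: np.ndarray,
    k: int = 10,
    angle_thresh: float = np.deg2rad(15.0),
) -> np.ndarray:
    """Indices of points whose mean normal angle to their k neighbours exceeds
    ``angle_thresh`` (crease / high-curvature points used for registration)."""
    if angle_thresh < 0:
        raise ValueError("angle_thresh must be nonnegative")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k + 1)
    neigh_normals = normals[idx[:, 1:]]  # (n, k, 3)
    # normal sign is ambiguous locally; use the unsigned angle
    cosang = np.clip(np.abs(np.einsum("nj,nkj->nk", normals, neigh_normals)), 0.0, 1.0)
    mean_angle = np.arccos(cosang).mean(axis=1)
    return np.nonzero(mean_angle > angle_thresh)[0]


# registration (FPFH + SAC-IA + ICP) is defined in its own module
from .registration import (  # noqa: E402,F401
    RegistrationParams,
    RegistrationResult,
    RigidTransform,
    register,
)
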