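"""Two-view rigid registration: FPFH descriptors on feature points, SAC-IA
coarse alignment, then point-to-point ICP refinement on mutual nearest
neighbours.

The two views of a plant are taken 180 degrees apart on a turntable; the
recovered transform maps the target view into the source view's frame and the
merged cloud is (source + transformed target).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import PointCloud
from .errors import InsufficientPointsError

__all__ = ["RigidTransform", "RegistrationParams", "RegistrationResult", "register"]


@dataclass
class RigidTransform:
    """Proper rigid motion p -> R p + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(points, float)) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle(self) -> float:
        """Magnitude of the rotation, in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class RegistrationParams:
    normals_k: int = 10
    feature_angle_thresh: float = np.deg2rad(15.0)
    fpfh_radius: float = 0.025
    sacia_iterations: int = 500
    sacia_samples: int = 3
    sacia_min_sample_dist: float = 0.02
    icp_max_iterations: int = 50
    icp_correspondence_cap: float = 0.02
    icp_tolerance: float = 1e-7
    min_feature_points: int = 8
    seed: int = 0


@dataclass
class RegistrationResult:
    transform: RigidTransform
    merged: PointCloud
    rms: float
    converged: bool
    n_correspondences: int
    warnings: list = field(default_factory=list)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, cd - r @ cs)


def _spfh(points: np.ndarray, normals: np.ndarray, center_idx: np.ndarray,
          tree: cKDTree, radius: float, bins: int = 11) -> np.ndarray:
    """Simplified point feature histograms (alpha, phi, theta triplets binned
    into ``bins`` each, concatenated) at the given indices."""
    out = np.zeros((len(center_idx), 3 * bins))
    for row, i in enumerate(center_idx):
        p, n_p = points[i], normals[i]
        neigh = [j for j in tree.query_ball_point(p, radius) if j != i]
        if not neigh:
            continue
        q = points[neigh]
        n_q = normals[neigh]
        diff = q - p
        dist = np.linalg.norm(diff, axis=1)
        ok = dist > 1e-12
        if not ok.any():
            continue
        diff, dist, n_q = diff[ok], dist[ok], n_q[ok]
        d_unit = diff / dist[:, None]
        u = np.broadcast_to(n_p, d_unit.shape)
        v = np.cross(u, d_unit)
        vn = np.linalg.norm(v, axis=1)
        good = vn > 1e-12
        if not good.any():
            continue
        v = v[good] / vn[good, None]
        w = np.cross(n_p, v)
        n_q, d_unit = n_q[good], d_unit[good]
        alpha = np.einsum("ij,ij->i", v, n_q)
        phi = d_unit @ n_p
        theta = np.arctan2(np.einsum("ij,ij->i", w, n_q), n_q @ n_p)
        h = np.concatenate([
            np.histogram(alpha, bins=bins, range=(-1, 1))[0],
            np.histogram(phi, bins=bins, range=(-1, 1))[0],
            np.histogram(theta, bins=bins, range=(-np.pi, np.pi))[0],
        ]).astype(float)
        s = h.sum()
        if s > 0:
            out[row] = h / s
    return out


def fpfh_descriptors(cloud: PointCloud, normals: np.ndarray, indices: np.ndarray,
                     radius: float = 0.025, bins: int = 11) -> np.ndarray:
    """FPFH: each feature point's SPFH plus the distance-weighted mean of the
    SPFHs of neighbouring feature points within ``radius``."""
    pts = cloud.points
    tree = cKDTree(pts)
    spfh = _spfh(pts, normals, indices, tree, radius, bins)
    ftree = cKDTree(pts[indices])
    fpfh = spfh.copy()
    for row, i in enumerate(indices):
        neigh = [j for j in ftree.query_ball_point(pts[i], radius) if j != row]
        if not neigh:
            continue
        d = np.linalg.norm(pts[indices[neigh]] - pts[i], axis=1)
        wsum = (spfh[neigh] / np.maximum(d, 1e-6)[:, None]).sum(axis=0)
        fpfh[row] = spfh[row] + wsum / len(neigh)
    norms = np.linalg.norm(fpfh, axis=1, keepdims=True)
    return fpfh / np.maximum(norms, 1e-12)


def _sac_ia(src_pts, src_desc, tgt_pts, tgt_desc, params: RegistrationParams) -> RigidTransform:
    """Sample-consensus initial alignment: repeatedly sample well-separated
    target features, match them to source features by descriptor, estimate the
    rigid transform and keep the one with the lowest truncated error."""
    rng = np.random.default_rng(params.seed)
    dtree = cKDTree(src_desc)
    # candidate source matches per target feature (top 3 by descriptor distance)
    kcand = min(3, len(src_desc))
    _, cand = dtree.query(tgt_desc, k=kcand)
    cand = np.atleast_2d(cand.T).T if cand.ndim == 1 else cand
    score_tree = cKDTree(src_pts)
    trunc = params.icp_correspondence_cap
    best, best_score = RigidTransform.identity(), np.inf
    n_t = len(tgt_pts)
    sub = tgt_pts[rng.choice(n_t, size=min(n_t, 400), replace=False)]
    for _ in range(params.sacia_iterations):
        picks = rng.choice(n_t, size=params.sacia_samples, replace=False)
        if len(picks) == 3:
            d01 = np.linalg.norm(tgt_pts[picks[0]] - tgt_pts[picks[1]])
            d02 = np.linalg.norm(tgt_pts[picks[0]] - tgt_pts[picks[2]])
            d12 = np.linalg.norm(tgt_pts[picks[1]] - tgt_pts[picks[2]])
            if min(d01, d02, d12) < params.sacia_min_sample_dist:
                continue
        match = [cand[p][rng.integers(0, kcand)] for p in picks]
        try:
            t = _kabsch(tgt_pts[picks], src_pts[match])
        except ValueError:
            continue
        d, _ = score_tree.query(t.apply(sub))
        score = np.minimum(d, trunc).sum()
        if score < best_score:
            best_score, best = score, t
    return best


def _icp(src_pts, tgt_pts, init: RigidTransform, params: RegistrationParams):
    """Point-to-point ICP restricted to mutual nearest neighbours within the
    correspondence cap.  Returns (transform, rms, converged, n_corr)."""
    src_tree = cKDTree(src_pts)
    t = init
    prev_rms = np.inf
    converged = False
    n_corr = 0
    rms = np.inf
    for _ in range(params.icp_max_iterations):
        moved = t.apply(tgt_pts)
        d_ts, idx_ts = src_tree.query(moved)
        moved_tree = cKDTree(moved)
        _, idx_st = moved_tree.query(src_pts)
        mutual = idx_st[idx_ts] == np.arange(len(moved))
        keep = mutual & (d_ts <= params.icp_correspondence_cap)
        n_corr = int(keep.sum())
        if n_corr < 3:
            return t, np.inf, False, n_corr
        rms = float(np.sqrt((d_ts[keep] ** 2).mean()))
        if abs(prev_rms - rms) < params.icp_tolerance:
            converged = True
            break
        prev_rms = rms
        step = _kabsch(tgt_pts[keep], src_pts[idx_ts[keep]])
        t = step
    return t, rms, converged, n_corr


def register(
    source: PointCloud,
    target: PointCloud,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Register ``target`` onto ``source``.

    Normal estimation -> feature-point detection -> FPFH descriptors ->
    SAC-IA coarse transform -> ICP refinement.  Non-convergence and poor
    overlap are reported via the ``converged`` flag and ``warnings`` list,
    not as exceptions; genuinely insufficient feature points are an error.
    """
    from .preprocess import detect_feature_points, estimate_normals

    if params is None:
        params = RegistrationParams()
    warnings: list[str] = []

    src_normals = estimate_normals(source, k=params.normals_k)
    tgt_normals = estimate_normals(target, k=params.normals_k)
    src_feat = detect_feature_points(source, src_normals, params.normals_k,
                                     params.feature_angle_thresh)
    tgt_feat = detect_feature_points(target, tgt_normals, params.normals_k,
                                     params.feature_angle_thresh)
    if len(src_feat) < params.min_feature_points or len(tgt_feat) < params.min_feature_points:
        raise InsufficientPointsError(
            f"too few feature points for registration "
            f"(source {len(src_feat)}, target {len(tgt_feat)})"
        )

    src_desc = fpfh_descriptors(source, src_normals, src_feat, params.fpfh_radius)
    tgt_desc = fpfh_descriptors(target, tgt_normals, tgt_feat, params.fpfh_radius)
    coarse = _sac_ia(source.points[src_feat], src_desc,
                     target.points[tgt_feat], tgt_desc, params)
    transform, rms, converged, n_corr = _icp(source.points, target.points, coarse, params)

    if not converged:
        warnings.append("ICP did not converge within the iteration budget")
    if n_corr < 0.25 * min(len(source), len(target)):
        warnings.append("low overlap: under a quarter of points found mutual correspondences")
        converged = False

    merged_pts = np.vstack([source.points, transform.apply(target.points)])
    merged_int = None
    if source.intensity is not None and target.intensity is not None:
        merged_int = np.concatenate([source.intensity, target.intensity])
    merged = PointCloud(merged_pts, merged_int, frame=source.frame)
    return RegistrationResult(transform, merged, rms, converged, n_corr, warnings)
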