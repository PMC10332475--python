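"""Domain types and reusable geometric primitives.

Coordinate convention (camera frame): x is horizontal, y is depth (positive
away from the camera, toward the backdrop curtain), z is height.  All lengths
are in metres; grayscale intensities are in [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel

from .errors import (
    DegenerateHullError,
    EllipseFitError,
    EmptyCloudError,
    InsufficientPointsError,
    InvalidIntrinsicsError,
)

__all__ = [
    "PointCloud",
    "CameraIntrinsics",
    "Plane",
    "Ellipse2D",
    "depth_to_cloud",
    "project_to_plane",
    "plane_basis",
    "convex_hull_2d",
    "fit_ellipse_minor_axis",
    "centroid",
    "read_cloud",
    "write_cloud",
]


@dataclass
class PointCloud:
    """An ordered set of 3D points with optional per-point grayscale intensity.

    ``points`` is an (n, 3) float64 array in metres; ``intensity`` is an (n,)
    float64 array in [0, 255] or None; ``frame`` tags the coordinate
    convention ("camera" for raw acquisitions, "world" for scene-level data —
    the axes are the same, only the origin differs).
    """

    points: np.ndarray
    intensity: np.ndarray | None = None
    frame: str = "camera"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if not np.isfinite(self.points).all():
            raise ValueError("points contain NaN or Inf")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=np.float64).ravel()
            if len(self.intensity) != len(self.points):
                raise ValueError("intensity length does not match point count")
            if len(self.intensity) and (
                self.intensity.min() < 0 or self.intensity.max() > 255
            ):
                raise ValueError("intensity values must lie in [0, 255]")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def select(self, index) -> "PointCloud":
        """Sub-cloud at the given integer/boolean index, preserving order."""
        inten = None if self.intensity is None else self.intensity[index]
        return PointCloud(self.points[index], inten, self.frame)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PointCloud":
        pts = self.points @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return PointCloud(pts, None if self.intensity is None else self.intensity.copy(), self.frame)


@dataclass
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise InvalidIntrinsicsError(
                f"focal lengths must be positive, got fx={self.fx}, fy={self.fy}"
            )
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise InvalidIntrinsicsError(
                "principal point must lie inside the image"
            )


@dataclass
class Plane:
    """A plane given by a centre point and a unit normal."""

    center: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64).ravel()
        self.normal = np.asarray(self.normal, dtype=np.float64).ravel()
        if self.center.shape != (3,) or self.normal.shape != (3,):
            raise ValueError("center and normal must be 3-vectors")
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("plane normal must be nonzero")
            self.normal = self.normal / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return (pts - self.center) @ self.normal


@dataclass
class Ellipse2D:
    """Geometric ellipse parameters: centre, semi-axes (semi_major >= semi_minor)
    and the major-axis angle in radians."""

    center: tuple
    semi_major: float
    semi_minor: float
    angle: float

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")

    @property
    def minor_axis_length(self) -> float:
        return 2.0 * self.semi_minor


def depth_to_cloud(
    depth: np.ndarray,
    intr: CameraIntrinsics,
    intensity_image: np.ndarray | None = None,
) -> PointCloud:
    """Back-project a depth image (metres) into a point cloud.

    Standard pinhole geometry with the depth axis as y:
    X = d (x - cx) / fx, Y = d, Z = -d (y - cy) / fy.  The image row index
    increases downward, hence the sign flip so that z points up.  Pixels with
    zero depth carry no return and are dropped.
    """
    depth = np.asarray(depth, dtype=np.float64)
    if depth.shape != (intr.height, intr.width):
        raise ValueError(
            f"depth shape {depth.shape} does not match intrinsics "
            f"({intr.height}, {intr.width})"
        )
    if (depth < 0).any():
        raise ValueError("depth values must be nonnegative")
    rows, cols = np.nonzero(depth > 0)
    if len(rows) == 0:
        raise EmptyCloudError("depth image has no valid (positive) returns")
    d = depth[rows, cols]
    pts = np.column_stack(
        [
            d * (cols - intr.cx) / intr.fx,
            d,
            -d * (rows - intr.cy) / intr.fy,
        ]
    )
    inten = None
    if intensity_image is not None:
        intensity_image = np.asarray(intensity_image, dtype=np.float64)
        if intensity_image.shape != depth.shape:
            raise ValueError("intensity image shape must match depth image")
        inten = intensity_image[rows, cols]
    return PointCloud(pts, inten, frame="camera")


def plane_basis(plane: Plane) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (u, v) with u x v = normal."""
    n = plane.normal
    # reference axis least aligned with the normal, for numerical stability
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(ref, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def project_to_plane(cloud: PointCloud | np.ndarray, plane: Plane) -> np.ndarray:
    """Orthogonally project points onto the plane, returning (n, 2) in-plane
    coordinates centred at ``plane.center``.  Distances within the plane are
    preserved; an empty input yields an empty output."""
    pts = cloud.points if isinstance(cloud, PointCloud) else np.atleast_2d(np.asarray(cloud, float))
    if pts.size == 0:
        return np.zeros((0, 2))
    u, v = plane_basis(plane)
    rel = pts - plane.center
    return np.column_stack([rel @ u, rel @ v])


def convex_hull_2d(points2d: np.ndarray) -> np.ndarray:
    """Counter-clockwise convex hull vertices of a 2D point set.

    Strictly collinear boundary points are excluded.  Raises
    DegenerateHullError for fewer than 3 points or a collinear set.
    """
    pts = np.atleast_2d(np.asarray(points2d, dtype=np.float64))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array")
    if len(pts) < 3:
        raise DegenerateHullError(f"need >= 3 points, got {len(pts)}")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError("input points are degenerate (collinear)") from exc
    return pts[hull.vertices]


def fit_ellipse_minor_axis(points2d: np.ndarray) -> Ellipse2D:
    """Direct least-squares ellipse fit (ellipse-specific conic constraint),
    returning geometric parameters; the stem-diameter estimator uses
    ``2 * semi_minor``."""
    pts = np.atleast_2d(np.asarray(points2d, dtype=np.float64))
    if len(pts) < 5:
        raise InsufficientPointsError(f"ellipse fit needs >= 5 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-12) < 2:
        raise EllipseFitError("points are collinear; conic fit is degenerate")
    try:  # skimage >= 0.26
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise EllipseFitError("direct ellipse fit failed")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    except AttributeError:  # older skimage
        model = EllipseModel()
        if not model.estimate(pts) or model.params is None:
            raise EllipseFitError("direct ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if not np.isfinite([xc, yc, a, b, theta]).all() or a <= 0 or b <= 0:
        raise EllipseFitError("ellipse fit produced non-finite or non-positive axes")
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    theta = float(np.mod(theta, np.pi))
    return Ellipse2D(center=(float(xc), float(yc)), semi_major=float(a), semi_minor=float(b), angle=theta)


def centroid(points: np.ndarray | PointCloud) -> np.ndarray:
    """Arithmetic mean of a non-empty point set."""
    pts = points.points if isinstance(points, PointCloud) else np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        raise EmptyCloudError("centroid of an empty point set is undefined")
    return pts.mean(axis=0)


# I/O lives in its own module; re-exported here so that the core namespace
# carries the full cloud interface.
from .io import read_cloud, write_cloud  # noqa: E402,F401
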