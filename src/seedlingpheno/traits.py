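"""The five phenotypes: plant height, stem diameter, main stem length,
regional leaf length and distance-density leaf number, plus the accuracy
metrics used to assess them.

Stem diameter is the mean minor-axis length of ellipses fitted to near-soil
stem cross-sections projected on the local tangent plane of the skeleton
(projecting on the horizontal plane instead smears oblique sections of a
leaning stem and is provided only as the ``projection="xoy"`` variant for
comparison).  Leaf number uses the mean nearest-neighbour distance of a
region's points — denser needle packing means more leaves — through a
linearly calibrated count = a * density + b model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings as _warnings

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    Plane,
    PointCloud,
    convex_hull_2d,
    fit_ellipse_minor_axis,
    project_to_plane,
)
from .errors import (
    BelowSoilError,
    DegenerateHullError,
    EllipseFitError,
    EmptyCloudError,
    InsufficientPointsError,
    SingularFitError,
    ZeroVarianceError,
)
from .stem_segmentation import StemPath

__all__ = [
    "Region",
    "DensityModel",
    "TraitReport",
    "plant_height",
    "stem_diameter",
    "main_stem_length",
    "partition_regions",
    "regional_leaf_length",
    "distance_density",
    "fit_density_model",
    "leaf_count",
    "EvaluationResult",
    "evaluate",
]


@dataclass
class Region:
    """A 5 cm window along the main-stem skeleton, measured from the canopy
    base downward, bounded by planes perpendicular to the local skeleton
    direction."""

    index: int
    arc_range: tuple  # (start, end) metres from the canopy base, start < end
    lower_plane: Plane
    upper_plane: Plane
    point_indices: np.ndarray | None = None


@dataclass
class DensityModel:
    """Linear leaf-count model count = slope * density + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_samples: int

    def predict(self, density: float) -> float:
        return self.slope * density + self.intercept


@dataclass
class TraitReport:
    """The five phenotypes with per-region breakdowns (all lengths in metres;
    leaf counts are unitless)."""

    plant_height: float
    stem_diameter: float
    main_stem_length: float
    regional_leaf_lengths: list  # (region index, length in m or None)
    leaf_count: int | None
    region_counts: list | None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "plant_height_m": self.plant_height,
            "stem_diameter_m": self.stem_diameter,
            "main_stem_length_m": self.main_stem_length,
            "regional_leaf_lengths_m": [
                {"region": i, "leaf_length_m": v} for i, v in self.regional_leaf_lengths
            ],
            "leaf_count": self.leaf_count,
            "region_counts": self.region_counts,
            "metadata": self.metadata,
        }


def plant_height(cloud: PointCloud, z_soil: float) -> float:
    """H = z_max - z_soil: highest plant point above the soil plane."""
    if len(cloud) == 0:
        raise EmptyCloudError("plant height of an empty cloud is undefined")
    h = float(cloud.z.max()) - z_soil
    if h <= 0:
        raise BelowSoilError("all points lie at or below the soil plane")
    return h


def _local_tangent(path: StemPath, i: int, window: float = 0.0075) -> np.ndarray:
    """Unit direction of the path at node i, pointing up-path.

    Averaged over +/- ``window`` of arc length around the node so that a
    single noisy skeleton point cannot tilt the tangent plane.
    """
    arc = path.arc_positions
    j_lo = int(np.searchsorted(arc, arc[i] - window, side="left"))
    j_hi = int(np.searchsorted(arc, arc[i] + window, side="right")) - 1
    j_hi = min(max(j_hi, j_lo + 1), len(path) - 1)
    j_lo = max(min(j_lo, j_hi - 1), 0)
    d = path.coords[j_hi] - path.coords[j_lo]
    n = np.linalg.norm(d)
    if n < 1e-12:
        d, n = np.array([0.0, 0.0, 1.0]), 1.0
    return d / n


def stem_diameter(
    cloud: PointCloud,
    path: StemPath,
    band: tuple = (0.02, 0.04),
    layer_height: float = 0.01,
    projection: str = "tangent",
) -> float:
    """Stem (ground) diameter: cross-sections in the ``band`` arc window above
    the lowest skeleton point, in ``layer_height`` slices, each projected and
    fitted with an ellipse; the diameter is the mean minor-axis length.

    ``projection="tangent"`` (default) projects each slice on the plane
    perpendicular to the local skeleton direction; ``projection="xoy"``
    reproduces the naive variant that slices along z and projects on the
    horizontal plane.
    """
    if projection not in ("tangent", "xoy"):
        raise ValueError("projection must be 'tangent' or 'xoy'")
    if len(path) < 2:
        raise InsufficientPointsError("skeleton path too short for a diameter estimate")
    arc = path.arc_positions
    lo, hi = band
    if arc[-1] < lo:
        raise InsufficientPointsError("skeleton does not reach the measurement band")

    i_lo = int(np.searchsorted(arc, lo))
    i_hi = min(int(np.searchsorted(arc, hi)), len(path) - 1)
    c_lo = path.coords[i_lo]

    if projection == "tangent":
        n_lo = _local_tangent(path, i_lo)
        n_hi = _local_tangent(path, i_hi)
        lower = Plane(center=c_lo, normal=n_lo)
        upper = Plane(center=path.coords[i_hi], normal=n_hi)
        h = lower.signed_distance(cloud.points)
        between = (h >= 0) & (upper.signed_distance(cloud.points) <= 0)
        heights = h[between]
        proj = project_to_plane(cloud.points[between], lower)
    else:
        z = cloud.z
        z_lo, z_hi = c_lo[2], c_lo[2] + (hi - lo)
        between = (z >= z_lo) & (z <= z_hi)
        heights = z[between] - z_lo
        proj = cloud.points[between][:, :2]

    diameters = []
    n_slices = max(1, int(round((hi - lo) / layer_height)))
    for s in range(n_slices):
        mask = (heights >= s * layer_height) & (heights < (s + 1) * layer_height)
        if s == n_slices - 1:
            mask = (heights >= s * layer_height) & (heights <= (s + 1) * layer_height + 1e-12)
        if mask.sum() < 5:
            continue
        try:
            ell = fit_ellipse_minor_axis(proj[mask])
        except (EllipseFitError, InsufficientPointsError):
            continue
        diameters.append(ell.minor_axis_length)
    if not diameters:
        raise InsufficientPointsError("no slice layer had enough points for an ellipse fit")
    return float(np.mean(diameters))


def main_stem_length(path: StemPath) -> float:
    """Sum of Euclidean distances between consecutive skeleton points."""
    if len(path) < 2:
        _warnings.warn("main stem path has a single point; length is 0", stacklevel=2)
        return 0.0
    return path.length


def partition_regions(
    path: StemPath, region_len: float = 0.05, min_partial: float = 0.01
) -> list[Region]:
    """Consecutive ``region_len`` arc windows from the canopy base downward.

    A final partial window shorter than ``min_partial`` is merged into the
    previous region; each region carries lower/upper planes perpendicular to
    the local skeleton tangents at its ends.
    """
    total = path.length
    if total <= 0:
        raise InsufficientPointsError("zero-length path cannot be partitioned")
    arc = path.arc_positions

    # window boundaries measured from the top (canopy base)
    bounds = [0.0]
    while bounds[-1] + region_len < total - 1e-12:
        bounds.append(bounds[-1] + region_len)
    bounds.append(total)
    if len(bounds) > 2 and (bounds[-1] - bounds[-2]) < min_partial:
        del bounds[-2]

    def node_at(arc_from_root: float, *, prefer_low: bool) -> int:
        i = int(np.searchsorted(arc, arc_from_root))
        i = min(max(i, 0), len(path) - 1)
        if prefer_low and i > 0 and arc[i] > arc_from_root + 1e-12:
            i -= 1
        return i

    regions = []
    for k in range(len(bounds) - 1):
        start, end = bounds[k], bounds[k + 1]  # from the top
        arc_hi, arc_lo = total - start, total - end
        i_lo = node_at(arc_lo, prefer_low=True)
        i_hi = node_at(arc_hi, prefer_low=False)
        lower = Plane(center=path.coords[i_lo], normal=_local_tangent(path, i_lo))
        upper = Plane(center=path.coords[i_hi], normal=_local_tangent(path, max(i_hi - 1, 0)))
        regions.append(Region(index=k, arc_range=(start, end), lower_plane=lower, upper_plane=upper))
    return regions


def _region_mask(cloud: PointCloud, region: Region) -> np.ndarray:
    lo = region.lower_plane.signed_distance(cloud.points) >= 0
    hi = region.upper_plane.signed_distance(cloud.points) <= 0
    return lo & hi


def regional_leaf_length(
    cloud: PointCloud, region: Region, stem_diam: float
) -> float | None:
    """Mean distance of the region projection's convex-hull vertices to the
    lower-plane centre, reported when it exceeds the stem diameter; ``None``
    means "no leaves in this region"."""
    if stem_diam <= 0:
        raise ValueError("stem_diam must be positive")
    mask = _region_mask(cloud, region)
    region.point_indices = np.nonzero(mask)[0]
    if mask.sum() < 3:
        return None
    proj = project_to_plane(cloud.points[mask], region.lower_plane)
    try:
        hull = convex_hull_2d(proj)
    except DegenerateHullError:
        return None
    mean_dist = float(np.linalg.norm(hull, axis=1).mean())
    return mean_dist if mean_dist > stem_diam else None


def distance_density(points: np.ndarray | PointCloud) -> float:
    """Mean nearest-neighbour distance of the point set."""
    pts = points.points if isinstance(points, PointCloud) else np.atleast_2d(np.asarray(points, float))
    if len(pts) < 2:
        raise InsufficientPointsError("distance density needs >= 2 points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return float(d[:, 1].mean())


def fit_density_model(samples) -> DensityModel:
    """Ordinary least squares count = a * density + b over (density, count)
    samples; at least two distinct density values are required."""
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise SingularFitError("need >= 2 (density, count) samples")
    d, c = arr[:, 0], arr[:, 1]
    if np.ptp(d) <= 0:
        raise SingularFitError("all density values identical; slope is undefined")
    slope, intercept = np.polyfit(d, c, 1)
    resid = c - (slope * d + intercept)
    ss_tot = float(((c - c.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return DensityModel(float(slope), float(intercept), r2, len(arr))


def leaf_count(
    cloud: PointCloud,
    regions: list[Region],
    model: DensityModel,
    stem_diam: float,
) -> tuple[int, list[int]]:
    """Per-region and total leaf counts from the density model.

    A region counts 0 when the leaf test (same as regional_leaf_length)
    reports no leaves; otherwise count = round(max(0, a * density + b)).
    ``cloud`` should be the leaf-side cloud so stem points do not dilute the
    density signal.
    """
    counts = []
    for region in regions:
        leafy = regional_leaf_length(cloud, region, stem_diam)
        if leafy is None:
            counts.append(0)
            continue
        mask = _region_mask(cloud, region)
        if mask.sum() < 2:
            counts.append(0)
            continue
        dbar = distance_density(cloud.points[mask])
        counts.append(int(round(max(0.0, model.predict(dbar)))))
    return int(sum(counts)), counts


@dataclass
class EvaluationResult:
    r: float
    rmse: float
    mae: float
    accuracy: float  # 100 * (1 - MAE / mean(actual)), in percent
    n: int


def evaluate(estimates, actuals) -> EvaluationResult:
    """Pearson R, RMSE, MAE and accuracy = 100 (1 - MAE/mean(actual)) for
    paired estimate/actual vectors."""
    est = np.asarray(estimates, dtype=float).ravel()
    act = np.asarray(actuals, dtype=float).ravel()
    if len(est) != len(act) or len(est) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    if est.std() == 0 or act.std() == 0:
        raise ZeroVarianceError("Pearson R undefined: zero variance input")
    r = float(np.corrcoef(est, act)[0, 1])
    err = est - act
    rmse = float(np.sqrt((err**2).mean()))
    mae = float(np.abs(err).mean())
    accuracy = 100.0 * (1.0 - mae / act.mean())
    return EvaluationResult(r=r, rmse=rmse, mae=mae, accuracy=accuracy, n=len(est))
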