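"""Procedural generator of potted conifer-seedling scenes with ground truth.

The generator emulates the study material: a 15-30 cm seedling in a 0.12 m
flowerpot on a platform in front of a dark curtain, scanned by a ToF depth
camera at ~1 mm point spacing.  The plant has a curved main stem (bright,
bark-like grayscale), needles radiating near-perpendicular from the stem in
5 cm regions (dimmer grayscale), a denser apical needle cluster (the canopy)
sitting on top of the stem, and Gaussian coordinate noise.  All ground-truth
traits — stem spline, height, diameter, arc length, per-region needle counts
and mean lengths, per-point labels — are recorded for use as test oracles.

Scale defaults follow the study material: ~65 needles per 5 cm region
(mean ~259 needles per plant), needle lengths 2.5-5.5 cm, stem diameter
2-6 mm, the lowest ~5 cm of stem bare (the near-soil stem carries no
needles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PointCloud
from .errors import InfeasibleSpecError
from .preprocess import SceneGeometry
from .registration import RigidTransform

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "RegionTruth",
    "TwoViewResult",
    "generate_plant",
    "generate_scene",
    "two_view",
]

SOIL_Z = 0.12  # soil surface height above the platform (= pot height), metres
BARE_STEM_ARC = 0.05  # near-soil stem length carrying no needles, metres

# grayscale levels: the stem is optically brighter than the needles
STEM_INTENSITY = (200.0, 8.0)
NEEDLE_INTENSITY = (110.0, 12.0)


@dataclass
class PlantSpec:
    """Parameters of one synthetic seedling.  Same spec + seed => identical
    output."""

    height: float = 0.225  # soil to canopy top, m
    stem_diameter: float = 0.004  # m
    stem_curvature: float = 0.015  # max lateral spline deviation, m
    needle_length_profile: tuple = (0.043, 0.047, 0.040, 0.025)  # per 5 cm region, top-down
    needles_per_region: tuple = (70, 65, 60, 50)
    canopy_radius: float = 0.03  # m
    noise_sigma: float = 0.001  # per-coordinate Gaussian noise, m
    spacing: float = 0.001  # nominal point spacing, m
    base_tilt: float = 0.0  # lean of the near-soil stem segment, radians
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.stem_diameter <= 0 or self.spacing <= 0:
            raise InfeasibleSpecError("height, stem_diameter and spacing must be positive")
        if self.canopy_radius <= 0 or self.canopy_radius >= self.height:
            raise InfeasibleSpecError("canopy radius must be positive and below the height")
        if any(l <= 0 for l in self.needle_length_profile):
            raise InfeasibleSpecError("needle lengths must be positive")
        if max(self.needle_length_profile) >= self.height:
            raise InfeasibleSpecError("needle length must be below the plant height")
        if any(c < 0 for c in self.needles_per_region):
            raise InfeasibleSpecError("needle counts must be nonnegative")
        if self.noise_sigma < 0 or self.stem_curvature < 0:
            raise InfeasibleSpecError("noise sigma and curvature must be nonnegative")
        if not (0 <= self.base_tilt < np.pi / 3):
            raise InfeasibleSpecError("base tilt must be in [0, 60 degrees)")


@dataclass
class RegionTruth:
    """Ground truth for one 5 cm region below the canopy (top-down index)."""

    index: int
    arc_range: tuple  # (start, end) metres from the canopy base downward
    needle_count: int
    mean_needle_length: float | None


@dataclass
class GroundTruth:
    """Everything the generator knows about the plant it built."""

    spline: np.ndarray  # (m, 3) dense noiseless stem centreline, soil to tip
    height: float  # noiseless z extent above the soil, m
    stem_diameter: float
    main_stem_length: float  # spline arc length, m
    canopy_radius: float
    z_soil: float
    regions: list = field(default_factory=list)  # list[RegionTruth]
    labels: np.ndarray | None = None  # per plant point: stem/needle/canopy
    leaf_count: int = 0  # total needles over the below-canopy regions

    def spline_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance of each query point to the dense stem centreline."""
        from scipy.spatial import cKDTree

        return cKDTree(self.spline).query(np.atleast_2d(points))[0]


def _stem_centerline(spec: PlantSpec, rng: np.random.Generator, n_dense: int = 2000):
    """Dense noiseless centreline from the soil to the canopy centre.

    Lateral deviation is a smooth bump (zero slope at both ends) in a random
    direction with magnitude ``stem_curvature``; a base tilt, when requested,
    adds a straight lean over the lowest 6 cm that then holds constant.
    """
    stem_top = spec.height - spec.canopy_radius
    if stem_top <= BARE_STEM_ARC:
        raise InfeasibleSpecError("plant too short for a stem above the bare zone")
    zs = np.linspace(0.0, stem_top, n_dense)
    phase = rng.uniform(0, 2 * np.pi)
    bump = np.sin(np.pi * zs / stem_top) ** 2
    lat = spec.stem_curvature * bump
    tilt_run = np.minimum(zs, 0.06)
    tilt_mag = np.tan(spec.base_tilt) * tilt_run
    tilt_phase = rng.uniform(0, 2 * np.pi)
    x = lat * np.cos(phase) + tilt_mag * np.cos(tilt_phase)
    y = lat * np.sin(phase) + tilt_mag * np.sin(tilt_phase)
    return np.column_stack([x, y, SOIL_Z + zs])


def _arc_lengths(line: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(line, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _frames(line: np.ndarray):
    """Unit tangents and two perpendicular frame vectors along a polyline."""
    t = np.gradient(line, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    ref = np.array([1.0, 0.0, 0.0])
    n1 = np.cross(t, ref)
    bad = np.linalg.norm(n1, axis=1) < 1e-6
    n1[bad] = np.cross(t[bad], np.array([0.0, 1.0, 0.0]))
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(t, n1)
    return t, n1, n2


def generate_plant(spec: PlantSpec) -> tuple[PointCloud, GroundTruth]:
    """Build one seedling point cloud (plant only, world frame with the soil
    surface at z = 0.12) together with its full ground truth."""
    rng = np.random.default_rng(spec.seed)
    line = _stem_centerline(spec, rng)
    arc = _arc_lengths(line)
    total_arc = float(arc[-1])
    tangents, n1, n2 = _frames(line)
    r_stem = spec.stem_diameter / 2.0

    pts: list[np.ndarray] = []
    labels: list[str] = []
    inten: list[float] = []

    def _interp_at(s: float):
        i = int(np.searchsorted(arc, s))
        i = min(max(i, 1), len(arc) - 1)
        f = (s - arc[i - 1]) / max(arc[i] - arc[i - 1], 1e-12)
        p = line[i - 1] + f * (line[i] - line[i - 1])
        return p, tangents[i], n1[i], n2[i]

    # ----- stem tube: rings of surface points every `spacing` of arc length
    n_around = max(6, int(round(2 * np.pi * r_stem / spec.spacing)))
    ring_arcs = np.arange(0.0, total_arc, spec.spacing)
    for k, s in enumerate(ring_arcs):
        p, _, a, b = _interp_at(s)
        offset = 2 * np.pi * ((k * 0.381966) % 1.0)  # de-alias successive rings
        ang = offset + np.linspace(0, 2 * np.pi, n_around, endpoint=False)
        ring = p + r_stem * (np.cos(ang)[:, None] * a + np.sin(ang)[:, None] * b)
        pts.append(ring)
        labels.extend(["stem"] * n_around)
        inten.extend(rng.normal(*STEM_INTENSITY, n_around))

    # ----- needles in 5 cm regions measured from the canopy base downward
    regions: list[RegionTruth] = []
    n_regions = int(np.ceil((total_arc - BARE_STEM_ARC) / 0.05 - 1e-9))
    for k in range(max(n_regions, 0)):
        hi = total_arc - k * 0.05
        lo = max(hi - 0.05, BARE_STEM_ARC)
        frac = (hi - lo) / 0.05
        mean_len = spec.needle_length_profile[min(k, len(spec.needle_length_profile) - 1)]
        nominal = spec.needles_per_region[min(k, len(spec.needles_per_region) - 1)]
        count = int(round(nominal * frac))
        lengths = []
        # conifer needles follow a phyllotactic spiral: regular spacing along
        # the stem with azimuths advancing by the golden angle (plus jitter)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        phi0 = rng.uniform(0, 2 * np.pi)
        for j in range(count):
            s = lo + (j + rng.uniform(0.2, 0.8)) * (hi - lo) / max(count, 1)
            p, t, a, b = _interp_at(s)
            phi = phi0 + j * golden + rng.normal(0.0, 0.15)
            psi = rng.uniform(np.deg2rad(70), np.deg2rad(110))  # from the stem axis
            radial = np.cos(phi) * a + np.sin(phi) * b
            direction = np.cos(psi) * t + np.sin(psi) * radial
            length = max(mean_len * (1.0 + 0.1 * rng.standard_normal()), 0.3 * mean_len)
            lengths.append(length)
            # pinhole foreshortening: the views look along +/-y, so a needle
            # pointing near the view axis covers few pixels and is sampled
            # sparsely along its length
            fshort = max(float(np.hypot(direction[0], direction[2])), 0.15)
            eff_spacing = spec.spacing / fshort
            n_pts = max(2, int(np.floor(length / eff_spacing)))
            ts = np.linspace(eff_spacing, length, n_pts)
            chain = p + r_stem * radial + ts[:, None] * direction
            pts.append(chain)
            labels.extend(["needle"] * n_pts)
            inten.extend(rng.normal(*NEEDLE_INTENSITY, n_pts))
        regions.append(
            RegionTruth(
                index=k,
                arc_range=(k * 0.05, k * 0.05 + (hi - lo)),
                needle_count=count,
                mean_needle_length=float(np.mean(lengths)) if lengths else None,
            )
        )

    # ----- apical canopy: a dense whorl of short needles attached along the
    # top of the stem and a short bark-bright terminal shoot; the bud tip
    # caps the plant at stem top + canopy_radius
    tip = line[-1]
    r_c = spec.canopy_radius
    z_cap = tip[2] + r_c
    shoot_len = 0.5 * r_c
    shoot_r = 0.7 * r_stem
    n_shoot_around = max(5, int(round(2 * np.pi * shoot_r / spec.spacing)))
    for k, h in enumerate(np.arange(spec.spacing, shoot_len, spec.spacing)):
        ang = 2 * np.pi * ((k * 0.381966) % 1.0) + np.linspace(
            0, 2 * np.pi, n_shoot_around, endpoint=False)
        ring = tip + np.array([0.0, 0.0, h]) + shoot_r * np.column_stack(
            [np.cos(ang), np.sin(ang), np.zeros(n_shoot_around)])
        pts.append(ring)
        labels.extend(["canopy"] * n_shoot_around)
        inten.extend(rng.normal(*STEM_INTENSITY, n_shoot_around))
    # the terminal bud: a dense bark-bright knob atop the shoot
    bud_center = tip + np.array([0.0, 0.0, shoot_len])
    bud_r = max(0.004, 1.5 * r_stem)
    n_bud = 120
    u = rng.normal(size=(n_bud, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    bud = bud_center + bud_r * u * rng.uniform(0.3, 1.0, (n_bud, 1)) ** (1 / 3)
    bud = bud[bud[:, 2] <= z_cap]
    pts.append(bud)
    labels.extend(["canopy"] * len(bud))
    inten.extend(rng.normal(*STEM_INTENSITY, len(bud)))

    n_canopy = max(30, int(round(150 * (r_c / 0.03) ** 2)))
    attach_lo = max(total_arc - 0.6 * r_c, BARE_STEM_ARC)
    for _ in range(n_canopy):
        u = rng.uniform(0, 1)
        if u < 0.8:  # attached on the top stem segment
            base, _, _, _ = _interp_at(rng.uniform(attach_lo, total_arc))
        else:  # attached on the terminal shoot
            base = tip + np.array([0.0, 0.0, rng.uniform(0.0, shoot_len)])
        theta = rng.uniform(np.deg2rad(20), np.deg2rad(80))  # from vertical, up-out
        phi = rng.uniform(0, 2 * np.pi)
        d = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                      np.cos(theta)])
        length = r_c * rng.uniform(0.4, 1.0)
        fshort = max(float(np.hypot(d[0], d[2])), 0.15)
        eff_spacing = 0.8 * spec.spacing / fshort
        n_pts = max(2, int(np.floor(length / eff_spacing)))
        ts = np.linspace(0.5 * spec.spacing, length, n_pts)
        chain = base + ts[:, None] * d
        chain = chain[chain[:, 2] <= z_cap]  # the bud tip caps the crown
        if len(chain) < 2:
            continue
        pts.append(chain)
        labels.extend(["canopy"] * len(chain))
        inten.extend(rng.normal(*NEEDLE_INTENSITY, len(chain)))

    points = np.vstack(pts)
    height_true = float(points[:, 2].max() - SOIL_Z)  # noiseless realized height
    if spec.noise_sigma > 0:
        points = points + rng.normal(0.0, spec.noise_sigma, points.shape)
    intensity = np.clip(np.array(inten), 0, 255)

    truth = GroundTruth(
        spline=line,
        height=height_true,
        stem_diameter=spec.stem_diameter,
        main_stem_length=total_arc,
        canopy_radius=spec.canopy_radius,
        z_soil=SOIL_Z,
        regions=regions,
        labels=np.array(labels),
        leaf_count=int(sum(r.needle_count for r in regions)),
    )
    return PointCloud(points, intensity, frame="world"), truth


def generate_scene(
    plant: PointCloud,
    geom: SceneGeometry,
    seed: int = 0,
    plant_labels: np.ndarray | None = None,
    outlier_count: int = 60,
    noise_sigma: float = 0.001,
) -> tuple[PointCloud, np.ndarray]:
    """Embed a plant cloud into a full acquisition scene.

    Adds the platform plane at z = 0, the flowerpot cylinder (0 to pot
    height), a soil disc, a sparse curtain plane at depth ``dcc`` and uniform
    speckle outliers; the plant is shifted to the camera-to-plant distance
    ``dcp``.  Returns (scene cloud, per-point labels).
    """
    rng = np.random.default_rng(seed)
    parts, labels, inten = [], [], []

    def add(points, label, level, sigma=noise_sigma):
        points = np.asarray(points, float)
        if sigma > 0:
            points = points + rng.normal(0, sigma, points.shape)
        parts.append(points)
        labels.append(np.full(len(points), label))
        inten.append(np.clip(rng.normal(level, 10.0, len(points)), 0, 255))

    # plant, shifted to its working distance
    plant_pts = plant.points + np.array([0.0, geom.dcp, 0.0])
    parts.append(plant_pts)
    labels.append(plant_labels if plant_labels is not None else np.full(len(plant_pts), "plant"))
    inten.append(plant.intensity if plant.intensity is not None
                 else np.full(len(plant_pts), 128.0))

    # platform plane at z = 0 (near the camera, hence densely sampled)
    gx, gy = np.meshgrid(np.arange(-0.2, 0.2, 0.004), geom.dcp + np.arange(-0.2, 0.2, 0.004))
    platform = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    add(platform, "platform", 160.0)

    # flowerpot cylinder and soil disc
    zs = np.arange(0.0, geom.pot_height, 0.008)
    ang = np.linspace(0, 2 * np.pi, 40, endpoint=False)
    pot = np.array([[0.05 * np.cos(a), geom.dcp + 0.05 * np.sin(a), z] for z in zs for a in ang])
    add(pot, "pot", 130.0)
    rr = np.arange(0.004, 0.048, 0.004)
    soil = np.array([[r * np.cos(a), geom.dcp + r * np.sin(a), geom.pot_height]
                     for r in rr for a in np.linspace(0, 2 * np.pi, int(10 + 140 * r), endpoint=False)])
    add(soil, "soil", 90.0)

    # curtain plane at the camera-to-curtain distance
    cx, cz = np.meshgrid(np.arange(-0.4, 0.4, 0.02), np.arange(0.0, 0.6, 0.02))
    curtain = np.column_stack([cx.ravel(), np.full(cx.size, geom.dcc), cz.ravel()])
    add(curtain, "curtain", 60.0)

    # sparse speckle outliers
    if outlier_count > 0:
        out = np.column_stack([
            rng.uniform(-0.3, 0.3, outlier_count),
            rng.uniform(0.1, geom.dcc, outlier_count),
            rng.uniform(0.0, 0.5, outlier_count),
        ])
        add(out, "outlier", 100.0, sigma=0.0)

    cloud = PointCloud(np.vstack(parts), np.concatenate(inten), frame="camera")
    return cloud, np.concatenate(labels)


@dataclass
class TwoViewResult:
    view0: PointCloud
    view180: PointCloud
    transform: RigidTransform  # maps view180 coordinates into view0's frame
    indices0: np.ndarray  # scene indices retained in view 0
    indices180: np.ndarray  # scene indices retained in view 180


def two_view(
    scene: PointCloud,
    angle: float = np.pi,
    occlusion_frac: float = 0.3,
    seed: int = 0,
    center: np.ndarray | None = None,
) -> TwoViewResult:
    """Simulate the turntable acquisition: two views ``angle`` apart, each
    with the far surface occluded.

    Occlusion keeps, within every 1 cm (x, z) pixel bin, the fraction
    (1 - occlusion_frac) of points nearest the camera (smallest y).  The
    returned transform maps the second view back into the first view's frame
    (rotation by -angle about the vertical axis through ``center``).
    """
    if not (0 <= occlusion_frac < 1):
        raise ValueError("occlusion_frac must be in [0, 1)")
    if center is None:
        center = scene.points[:, :2].mean(axis=0)
    center3 = np.array([center[0], center[1], 0.0])

    def rot_z(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def cull(points):
        if occlusion_frac == 0:
            return np.arange(len(points))
        keep = []
        bins: dict[tuple, list] = {}
        for i, p in enumerate(points):
            bins.setdefault((int(np.floor(p[0] / 0.01)), int(np.floor(p[2] / 0.01))), []).append(i)
        for members in bins.values():
            members = sorted(members, key=lambda i: points[i][1])
            n_keep = max(1, int(np.ceil((1 - occlusion_frac) * len(members))))
            keep.extend(members[:n_keep])
        return np.array(sorted(keep), dtype=int)

    idx0 = cull(scene.points)
    view0 = scene.select(idx0)

    r_fwd = rot_z(angle)
    rotated = (scene.points - center3) @ r_fwd.T + center3
    idx180 = cull(rotated)
    inten180 = None if scene.intensity is None else scene.intensity[idx180]
    view180 = PointCloud(rotated[idx180], inten180, frame=scene.frame)

    r_back = rot_z(-angle)
    transform = RigidTransform(r_back, center3 - r_back @ center3)
    return TwoViewResult(view0, view180, transform, idx0, idx180)
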