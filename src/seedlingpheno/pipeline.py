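"""End-to-end driver: preprocessing -> segmentation -> traits, plus the
synthetic-cohort evaluation harness.

``run_on_cloud`` processes a single (already merged) scene cloud;
``run_two_view`` first registers the 0/180 degree views.  ``cohort_eval``
simulates a cohort of seedlings with known ground truth, runs the pipeline on
each, and scores every trait with Pearson R, RMSE, MAE and accuracy
(100 * (1 - MAE/mean)).  A single seed fans out deterministically to the
per-plant and per-stage random streams via numpy SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import stem_segmentation as seg
from . import synthetic, traits
from .config import PipelineConfig
from .core import PointCloud
from .errors import StageError

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "CohortRanges",
    "CohortResult",
    "preprocess_scene",
    "run_on_cloud",
    "run_two_view",
    "draw_spec",
    "calibrate_density_model",
    "cohort_eval",
]


@dataclass
class PipelineResult:
    report: traits.TraitReport
    plant_cloud: PointCloud
    segmentation: seg.SegmentationResult
    regions: list
    z_soil: float
    diagnostics: dict = field(default_factory=dict)


def preprocess_scene(
    cloud: PointCloud, geom: pp.SceneGeometry, config: PipelineConfig | None = None
) -> tuple[PointCloud, float, dict]:
    """Raw scene -> clean plant cloud: pass-through background removal,
    RANSAC platform removal, radius outlier filtering, soil/pot removal.
    Returns (plant cloud, z_soil, per-stage diagnostics)."""
    config = config or PipelineConfig()
    diag = {"n_input": len(cloud)}

    _, pt_ub = pp.passthrough_bounds(geom, cloud)
    near = pp.passthrough_filter(cloud, "y", float(cloud.y.min()) - 1e-9, pt_ub)
    diag["n_after_background"] = len(near)

    plane, inliers = pp.ransac_plane(near, config.ransac_thresh,
                                     config.ransac_iterations, seed=config.seed)
    platform_z = float(near.points[inliers, 2].mean())
    mask = np.ones(len(near), dtype=bool)
    mask[inliers] = False
    no_platform = near.select(mask)
    diag["n_after_platform"] = len(no_platform)
    diag["platform_z"] = platform_z

    filtered = pp.radius_outlier_filter(no_platform, config.radius_r, config.radius_k)
    diag["n_after_radius"] = len(filtered)

    geom_eff = pp.SceneGeometry(geom.dcc, geom.dcp, config.pot_height,
                                (config.soil_band_low, config.pot_height))
    plant, z_soil = pp.remove_soil_and_pot(filtered, platform_z, geom_eff)
    diag["n_plant"] = len(plant)
    diag["z_soil"] = z_soil
    return plant, z_soil, diag


def run_on_cloud(
    cloud: PointCloud,
    geom: pp.SceneGeometry,
    config: PipelineConfig | None = None,
    density_model: traits.DensityModel | None = None,
) -> PipelineResult:
    """Full pipeline on a single merged scene cloud."""
    config = config or PipelineConfig()
    plant, z_soil, diag = preprocess_scene(cloud, geom, config)

    segmentation = seg.segment(
        plant,
        n_layers=config.n_layers,
        n_x=config.n_x,
        x_thresh=config.x_thresh,
        cluster_tol=config.cluster_tol,
        cluster_min_size=config.cluster_min_size,
        k_top=config.k_top,
    )
    diag.update(segmentation.diagnostics)

    path = segmentation.skeleton
    height = traits.plant_height(plant, z_soil)
    # traits are read off the separated clouds: the diameter from the restored
    # stem (needles would corrupt the cross-section fit), leaf traits from the
    # leaf side
    stem_cloud = plant.select(segmentation.stem_indices)
    diameter = traits.stem_diameter(stem_cloud, path, (config.band_low, config.band_high),
                                    config.layer_height)
    length = traits.main_stem_length(path)
    regions = traits.partition_regions(path, config.region_len)
    leaf_lengths = [
        (r.index, traits.regional_leaf_length(plant, r, diameter)) for r in regions
    ]
    leaf_cloud = plant.select(segmentation.leaf_indices)
    total = counts = None
    if density_model is not None:
        total, counts = traits.leaf_count(leaf_cloud, regions, density_model, diameter)

    report = traits.TraitReport(
        plant_height=height,
        stem_diameter=diameter,
        main_stem_length=length,
        regional_leaf_lengths=leaf_lengths,
        leaf_count=total,
        region_counts=counts,
        metadata={"z_soil": z_soil, "n_regions": len(regions)},
    )
    return PipelineResult(report, plant, segmentation, regions, z_soil, diag)


def run_two_view(
    view0: PointCloud,
    view180: PointCloud,
    geom: pp.SceneGeometry,
    config: PipelineConfig | None = None,
    density_model: traits.DensityModel | None = None,
) -> PipelineResult:
    """Preprocess both views, register the 180-degree view onto the 0-degree
    view, and run the pipeline on the merged cloud."""
    config = config or PipelineConfig()
    plant0, z_soil0, diag0 = preprocess_scene(view0, geom, config)
    plant180, _, _ = preprocess_scene(view180, geom, config)
    reg = pp.register(plant0, plant180, config.registration_params())

    segmentation = seg.segment(
        reg.merged,
        n_layers=config.n_layers,
        n_x=config.n_x,
        x_thresh=config.x_thresh,
        cluster_tol=config.cluster_tol,
        cluster_min_size=config.cluster_min_size,
        k_top=config.k_top,
    )
    path = segmentation.skeleton
    height = traits.plant_height(reg.merged, z_soil0)
    stem_cloud = reg.merged.select(segmentation.stem_indices)
    diameter = traits.stem_diameter(stem_cloud, path, (config.band_low, config.band_high),
                                    config.layer_height)
    regions = traits.partition_regions(path, config.region_len)
    leaf_lengths = [(r.index, traits.regional_leaf_length(reg.merged, r, diameter))
                    for r in regions]
    leaf_cloud = reg.merged.select(segmentation.leaf_indices)
    total = counts = None
    if density_model is not None:
        total, counts = traits.leaf_count(leaf_cloud, regions, density_model, diameter)
    report = traits.TraitReport(
        plant_height=height,
        stem_diameter=diameter,
        main_stem_length=traits.main_stem_length(path),
        regional_leaf_lengths=leaf_lengths,
        leaf_count=total,
        region_counts=counts,
        metadata={"z_soil": z_soil0, "registration_rms": reg.rms,
                  "registration_converged": reg.converged},
    )
    diag0["registration_rms"] = reg.rms
    return PipelineResult(report, reg.merged, segmentation, regions, z_soil0, diag0)


# ------------------------------------------------------------------ cohorts

@dataclass
class CohortRanges:
    """Sampling ranges for synthetic cohorts (uniform draws)."""

    height: tuple = (0.15, 0.30)
    stem_diameter: tuple = (0.002, 0.006)
    stem_curvature: tuple = (0.005, 0.02)
    needle_count: tuple = (35, 85)  # per 5 cm region
    needle_length: tuple = (0.025, 0.055)  # per-region mean, m
    canopy_radius: tuple = (0.025, 0.035)
    base_tilt_deg: tuple = (0.0, 0.0)
    noise_sigma: float = 0.001


def draw_spec(rng: np.random.Generator, ranges: CohortRanges, seed: int) -> synthetic.PlantSpec:
    """One random plant specification within the cohort ranges."""
    n_regions = 5  # profiles longer than needed are truncated by the generator
    return synthetic.PlantSpec(
        height=rng.uniform(*ranges.height),
        stem_diameter=rng.uniform(*ranges.stem_diameter),
        stem_curvature=rng.uniform(*ranges.stem_curvature),
        needle_length_profile=tuple(rng.uniform(*ranges.needle_length, n_regions)),
        needles_per_region=tuple(int(c) for c in rng.integers(ranges.needle_count[0],
                                                              ranges.needle_count[1] + 1,
                                                              n_regions)),
        canopy_radius=rng.uniform(*ranges.canopy_radius),
        noise_sigma=ranges.noise_sigma,
        base_tilt=np.deg2rad(rng.uniform(*ranges.base_tilt_deg)),
        seed=seed,
    )


def _plant_seeds(seed: int, n: int, stream: int) -> list[int]:
    """Deterministic fan-out of one master seed into per-plant seeds."""
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def _simulate_and_run(spec, geom, config, density_model=None):
    plant, truth = synthetic.generate_plant(spec)
    scene, _ = synthetic.generate_scene(plant, geom, seed=spec.seed,
                                        plant_labels=truth.labels)
    result = run_on_cloud(scene, geom, config, density_model)
    return result, truth


def calibrate_density_model(
    n_plants: int = 10,
    seed: int = 100,
    config: PipelineConfig | None = None,
    ranges: CohortRanges | None = None,
    geom: pp.SceneGeometry | None = None,
) -> traits.DensityModel:
    """Fit the count = a * density + b model on regions of freshly simulated
    calibration plants: the pipeline's own density measurement paired with
    the generator's true per-region needle count."""
    config = config or PipelineConfig()
    ranges = ranges or CohortRanges()
    geom = geom or pp.SceneGeometry(dcc=1.35, dcp=0.45)
    rng = np.random.default_rng(seed)
    samples = []
    for plant_seed in _plant_seeds(seed, n_plants, stream=1):
        spec = draw_spec(rng, ranges, plant_seed)
        result, truth = _simulate_and_run(spec, geom, config)
        leaf_cloud = result.plant_cloud.select(result.segmentation.leaf_indices)
        diameter = result.report.stem_diameter
        # pair every region the pipeline found with the true attachment count
        # for that window (0 beyond the needle zone): the model must cover the
        # same region population it will score at prediction time, including
        # bare-stem windows that pass the leaf test by catching drooping tips
        truth_counts = {rt.index: rt.needle_count for rt in truth.regions}
        for k, region in enumerate(result.regions):
            if traits.regional_leaf_length(leaf_cloud, region, diameter) is None:
                continue
            mask = traits._region_mask(leaf_cloud, region)
            if mask.sum() < 2:
                continue
            dbar = traits.distance_density(leaf_cloud.points[mask])
            samples.append((dbar, truth_counts.get(k, 0)))
    return traits.fit_density_model(samples)


@dataclass
class CohortResult:
    table: pd.DataFrame  # one row per plant: estimated and actual traits
    regional: pd.DataFrame  # one row per (plant, region) leaf-length pair
    summary: dict  # trait -> EvaluationResult plus relative-MAE entries


def cohort_eval(
    n_plants: int = 20,
    seed: int = 0,
    config: PipelineConfig | None = None,
    ranges: CohortRanges | None = None,
    density_model: traits.DensityModel | None = None,
    geom: pp.SceneGeometry | None = None,
) -> CohortResult:
    """Simulate ``n_plants`` seedlings, run the full pipeline on each, and
    score the five traits against the generator's ground truth."""
    if n_plants < 2:
        raise ValueError("cohort evaluation needs n >= 2 plants")
    config = config or PipelineConfig()
    ranges = ranges or CohortRanges()
    geom = geom or pp.SceneGeometry(dcc=1.35, dcp=0.45)
    rng = np.random.default_rng(seed)

    rows, region_rows = [], []
    for i, plant_seed in enumerate(_plant_seeds(seed, n_plants, stream=0)):
        spec = draw_spec(rng, ranges, plant_seed)
        result, truth = _simulate_and_run(spec, geom, config, density_model)
        rep = result.report
        row = {
            "plant": i,
            "est_height": rep.plant_height, "act_height": truth.height,
            "est_diameter": rep.stem_diameter, "act_diameter": truth.stem_diameter,
            "est_stem_length": rep.main_stem_length, "act_stem_length": truth.main_stem_length,
        }
        if rep.leaf_count is not None:
            row["est_leaf_count"] = rep.leaf_count
            row["act_leaf_count"] = truth.leaf_count
        rows.append(row)
        est_by_region = dict(rep.regional_leaf_lengths)
        for rt in truth.regions:
            est = est_by_region.get(rt.index)
            if rt.mean_needle_length is not None and est is not None:
                region_rows.append({
                    "plant": i, "region": rt.index,
                    "est_leaf_length": est, "act_leaf_length": rt.mean_needle_length,
                })

    table = pd.DataFrame(rows)
    regional = pd.DataFrame(region_rows)
    summary: dict = {}
    for trait in ("height", "diameter", "stem_length"):
        summary[trait] = traits.evaluate(table[f"est_{trait}"], table[f"act_{trait}"])
    if not regional.empty:
        summary["regional_leaf_length"] = traits.evaluate(
            regional["est_leaf_length"], regional["act_leaf_length"]
        )
    if "est_leaf_count" in table:
        ev = traits.evaluate(table["est_leaf_count"], table["act_leaf_count"])
        summary["leaf_count"] = ev
        summary["leaf_count_relative_mae_pct"] = 100.0 * ev.mae / table["act_leaf_count"].mean()
    for trait in ("height", "diameter", "stem_length"):
        summary[f"{trait}_relative_mae_pct"] = (
            100.0 * summary[trait].mae / table[f"act_{trait}"].mean()
        )
    return CohortResult(table=table, regional=regional, summary=summary)
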