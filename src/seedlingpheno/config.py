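"""Pipeline configuration: every tunable in one schema-validated record.

Defaults follow the study protocol where it states values (30 z slices, 5 x
sub-slices, radius filter r = 0.01 m with k = 10, pot height 0.12 m, soil
band 0.07-0.12 m, canopy anchor at the 5th point from the top, 5 cm regions,
2-4 cm diameter band in 1 cm layers); the remaining knobs are this package's
own defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # skeletonization
    n_layers: int = 30
    n_x: int = 5
    x_thresh: float = 0.02  # m; cluster wider than this gets x-subdivided
    cluster_tol: float = 0.01  # m
    cluster_min_size: int = 30
    # preprocessing
    radius_r: float = 0.01  # m
    radius_k: int = 10
    ransac_thresh: float = 0.005  # m
    ransac_iterations: int = 1000
    pot_height: float = 0.12  # m
    soil_band_low: float = 0.07  # m above the platform
    # segmentation
    k_top: int = 5
    capture_radius: float = 0.015  # m, preliminary-diameter capture cylinder
    # traits
    region_len: float = 0.05  # m
    band_low: float = 0.02  # m, stem-diameter band above lowest skeleton point
    band_high: float = 0.04
    layer_height: float = 0.01  # m
    # registration
    normals_k: int = 10
    feature_angle_thresh_deg: float = 15.0
    fpfh_radius: float = 0.025  # m
    sacia_iterations: int = 500
    icp_max_iterations: int = 50
    icp_correspondence_cap: float = 0.02  # m
    icp_tolerance: float = 1e-7  # m, RMS change convergence threshold
    # determinism: a single seed fans out to per-stage streams
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1 or self.n_x < 2:
            raise ConfigError("require n_layers >= 1 and n_x >= 2")
        if min(self.x_thresh, self.cluster_tol, self.radius_r, self.ransac_thresh,
               self.region_len, self.layer_height, self.capture_radius) <= 0:
            raise ConfigError("length parameters must be positive")
        if self.radius_k < 1 or self.cluster_min_size < 1 or self.k_top < 1:
            raise ConfigError("count parameters must be >= 1")
        if not self.band_low < self.band_high:
            raise ConfigError("require band_low < band_high")
        if not 0 < self.soil_band_low < self.pot_height:
            raise ConfigError("require 0 < soil_band_low < pot_height")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in d:
            if key not in known:
                raise ConfigError(f"unknown configuration key: {key!r}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def registration_params(self):
        from .registration import RegistrationParams

        return RegistrationParams(
            normals_k=self.normals_k,
            feature_angle_thresh=np.deg2rad(self.feature_angle_thresh_deg),
            fpfh_radius=self.fpfh_radius,
            sacia_iterations=self.sacia_iterations,
            icp_max_iterations=self.icp_max_iterations,
            icp_correspondence_cap=self.icp_correspondence_cap,
            icp_tolerance=self.icp_tolerance,
            seed=self.seed,
        )
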