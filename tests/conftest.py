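"""Shared fixtures: simple geometric clouds and one synthetic scene."""

import numpy as np
import pytest

from seedlingpheno import PlantSpec, PointCloud, SceneGeometry, generate_plant, generate_scene


def make_cylinder(radius=0.002, height=0.25, spacing=0.001, z0=0.12, tilt=0.0,
                  intensity=200.0, noise=0.0, seed=0):
    """Point shell of a (possibly tilted) cylinder with uniform intensity.

    Tilt is applied in the x-z plane; the axis starts at (0, 0, z0).
    """
    rng = np.random.default_rng(seed)
    axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
    a = np.array([0.0, 1.0, 0.0])
    b = np.cross(axis, a)
    n_around = max(6, int(round(2 * np.pi * radius / spacing)))
    pts = []
    for k, s in enumerate(np.arange(0.0, height, spacing)):
        c = axis * s + np.array([0.0, 0.0, z0])
        ang = np.linspace(0, 2 * np.pi, n_around, endpoint=False) + 0.7 * k
        pts.append(c + radius * (np.cos(ang)[:, None] * a + np.sin(ang)[:, None] * b))
    pts = np.vstack(pts)
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    return PointCloud(pts, np.full(len(pts), float(intensity)))


@pytest.fixture(scope="session")
def geom():
    return SceneGeometry(dcc=1.35, dcp=0.45)


@pytest.fixture(scope="session")
def seedling():
    """One default noisy seedling with ground truth."""
    return generate_plant(PlantSpec(seed=0))


@pytest.fixture(scope="session")
def scene(seedling, geom):
    plant, truth = seedling
    cloud, labels = generate_scene(plant, geom, seed=0, plant_labels=truth.labels)
    return cloud, labels, truth


@pytest.fixture(scope="session")
def noiseless_seedling():
    return generate_plant(PlantSpec(seed=2, noise_sigma=0.0))
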