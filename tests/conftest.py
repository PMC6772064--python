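"""Shared fixtures: small sphere geometries and the standard simulation."""

import numpy as np
import pytest
import trimesh

from opmarray.forward import HeadModel, SourceSpace, fit_sphere
from opmarray.geometry import Sensor, SensorArray


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def sphere_mesh():
    return trimesh.creation.icosphere(subdivisions=3, radius=0.08)


@pytest.fixture(scope="session")
def sphere_head(sphere_mesh):
    return fit_sphere(sphere_mesh)


@pytest.fixture(scope="session")
def cap_array():
    """13 point magnetometers on a spherical cap around +z-ish."""
    rng = np.random.default_rng(7)
    dirs = rng.normal(size=(13, 3))
    dirs[:, 2] = np.abs(dirs[:, 2]) + 2.0
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    sensors = tuple(
        Sensor(d * 0.0965, d, 1.0, f"ch{i:02d}") for i, d in enumerate(dirs))
    return SensorArray(sensors)


@pytest.fixture(scope="session")
def tangential_sources():
    """50 interior dipoles with tangential orientations (never silent)."""
    rng = np.random.default_rng(11)
    u = rng.normal(size=(50, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pos = u * 0.055
    ori = np.cross(u, rng.normal(size=(50, 3)))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    return SourceSpace(pos, ori)


@pytest.fixture(scope="session")
def standard():
    """The default simulated protocol at full resolution (shared, costly)."""
    from opmarray.synthetic import standard_setup

    return standard_setup(seed=0)


@pytest.fixture(scope="session")
def small_setup():
    """Cheap variant of the protocol for fast functional tests."""
    from opmarray.synthetic import SimulationSpec, standard_setup

    spec = SimulationSpec(sample_rate_hz=500.0, seed=99)
    return standard_setup(seed=5, spec=spec, n_vertices=642)
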