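"""Shared fixtures: a compact MEG geometry with a sphere conductor and a
coarse source grid, sized so the whole suite runs quickly on one CPU."""

import numpy as np
import pytest

from megbeam import forward as fwd
from megbeam.session import SensorArray, SessionData


def make_mag_array(n=24, seed=1, radius=0.12, min_z=0.25) -> SensorArray:
    """Point magnetometers scattered over the upper part of a helmet
    sphere, radially oriented."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        if v[2] > min_z:
            pts.append(v)
    pts = np.array(pts)
    return SensorArray(
        names=[f"MEG{i:03d}" for i in range(n)],
        positions=radius * pts,
        orientations=pts,
        kinds=["meg_mag"] * n,
    )


def tangential(position, axis=(0.0, 0.0, 1.0)):
    """A unit vector tangential to the sphere (origin-centred) at ``position``."""
    r_hat = np.asarray(position, float)
    r_hat = r_hat / np.linalg.norm(r_hat)
    t = np.cross(r_hat, np.asarray(axis, float))
    n = np.linalg.norm(t)
    if n < 1e-9:
        t = np.cross(r_hat, [1.0, 0.0, 0.0])
        n = np.linalg.norm(t)
    return t / n


@pytest.fixture(scope="session")
def sensors() -> SensorArray:
    return make_mag_array()


@pytest.fixture(scope="session")
def sphere() -> fwd.SphereModel:
    return fwd.SphereModel(centre=np.zeros(3), radius=0.09)


@pytest.fixture(scope="session")
def grid() -> fwd.VoxelGrid:
    # 5 x 5 x 4 lattice, 1 cm spacing, upper half of the conductor
    return fwd.VoxelGrid.from_box(
        [(-0.02, 0.02), (-0.02, 0.02), (0.03, 0.06)], 0.01
    )


@pytest.fixture(scope="session")
def leadfield(sphere, grid, sensors) -> fwd.LeadField:
    return fwd.leadfield_meg_sphere(sphere, grid, sensors)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_session(data, fs=250.0, t0=-0.2, sensors_=None) -> SessionData:
    data = np.asarray(data, dtype=np.float64)
    nt, nc, ns = data.shape
    if sensors_ is None:
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((nc, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        sensors_ = SensorArray(
            names=[f"CH{i}" for i in range(nc)],
            positions=0.1 * pts,
            orientations=pts,
            kinds=["meg_mag"] * nc,
        )
    time = t0 + np.arange(ns) / fs
    return SessionData(data=data, fs=fs, time=time, sensors=sensors_)
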