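"""Shared fixtures: small, fast phantom geometries for unit tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from octquant.synthetic import PhantomSpec, generate_phantom
from octquant.volio import OctVolume


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale cylindrical phantom spec (128 x 96 x 16)."""
    return PhantomSpec(
        grid_dims=(128, 96, 16),
        lateral_extent_mm=2.4,
        apex_depth_px=20,
        jitter_amplitude_px=0,
        seed=7,
    )


@pytest.fixture(scope="session")
def sphere_spec() -> PhantomSpec:
    """Spherical-cap phantom with enough valid A-scans for surface work."""
    return PhantomSpec(
        grid_dims=(128, 96, 32),
        lateral_extent_mm=2.0,
        apex_depth_px=20,
        jitter_amplitude_px=0,
        specular=None,
        spherical=True,
        seed=9,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def jittered_spec(small_spec) -> PhantomSpec:
    return dataclasses.replace(small_spec, jitter_amplitude_px=5, seed=13)


def make_slab_volume(
    depth: int = 64,
    nx: int = 32,
    ny: int = 8,
    top: int = 20,
    thickness: int = 24,
    level: int = 200,
    background: int = 0,
) -> OctVolume:
    """Flat uniform slab: analytic surface at ``top``, bottom at top+thickness."""
    arr = np.full((depth, nx, ny), background, dtype=np.uint8)
    arr[top : top + thickness] = level
    return OctVolume(intensities=arr)


@pytest.fixture()
def slab_volume() -> OctVolume:
    return make_slab_volume()
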