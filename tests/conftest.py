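"""Shared fixtures: reference phantoms built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import coccomorph as cm


@pytest.fixture(scope="session")
def goceanica_spec():
    """Largest-coccolith reference geometry: grid perimeter 6.92 µm, 61 segments."""
    return cm.default_coccolith_spec(6.92, n=61, label="G. oceanica-like")


@pytest.fixture(scope="session")
def goceanica_volume(goceanica_spec):
    """Voxelized reference coccolith at 32.5 nm with its analytic ground truth."""
    return cm.build_coccolith(goceanica_spec, 32.5)


@pytest.fixture(scope="session")
def goceanica_record(goceanica_volume):
    vol, _ = goceanica_volume
    return cm.measure_coccolith(vol)


@pytest.fixture(scope="session")
def small_spec():
    """Smallest-coccolith reference: grid perimeter 3.32 µm, 29 segments."""
    return cm.default_coccolith_spec(3.32, n=29, label="R. parvula-like")


@pytest.fixture(scope="session")
def sphere14():
    """A 14-coccolith coccosphere phantom (non-touching placement)."""
    specs = [cm.default_coccolith_spec(3.3, n=29) for _ in range(14)]
    cs = cm.CoccosphereSpec(phi_cs=6.5, coccoliths=specs, placement_seed=1)
    density, labels, truths = cm.build_coccosphere(cs, 32.5)
    return density, labels, truths


@pytest.fixture(scope="session")
def sphere14_segmented(sphere14):
    density, _, _ = sphere14
    return cm.segment_coccosphere(density)


@pytest.fixture(scope="session")
def ellipsoid64():
    """Asymmetric ellipsoid test object on a 64³ grid (oversampled ~3x)."""
    N = 64
    x = np.arange(N) - N // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    grid = (((X + 3) ** 2 / 100 + (Y - 2) ** 2 / 64 + Z ** 2 / 36) < 1)
    return cm.VoxelVolume(grid.astype(np.float32), 32.5)


@pytest.fixture(scope="session")
def ball64():
    N = 64
    x = np.arange(N) - N // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    grid = ((X ** 2 + Y ** 2 + Z ** 2) < 10 ** 2)
    return cm.VoxelVolume(grid.astype(np.float32), 32.5)


@pytest.fixture(scope="session")
def ellipsoid64_retrieval(ellipsoid64):
    """Noiseless, fully measured phase retrieval of the ellipsoid."""
    dv = cm.diffraction_from_volume(ellipsoid64)
    res = cm.phase_retrieval(dv, seed=3)
    return dv, res
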