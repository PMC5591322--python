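"""Shared fixtures: small phantoms reused across test modules."""

import numpy as np
import pytest

from fusionwmh.core_io import LabelMap, Volume3D
from fusionwmh.phantom import (
    MriPhantomSpec,
    SpectPhantomSpec,
    make_mri_phantom,
    make_spect_phantom,
)


@pytest.fixture(scope="session")
def small_mri_phantom():
    """64^3 @ 2 mm MRI phantom with the default brain/lesion geometry."""
    spec = MriPhantomSpec(shape=(64, 64, 64), voxel_mm=2.0, seed=11)
    t1, flair, truth = make_mri_phantom(spec)
    return spec, t1, flair, truth


@pytest.fixture(scope="session")
def mri_phantom_fine():
    """80^3 @ 1.6 mm phantom: finer grid for volumetric accuracy checks."""
    spec = MriPhantomSpec(shape=(80, 80, 80), voxel_mm=1.6, seed=5)
    t1, flair, truth = make_mri_phantom(spec)
    return spec, t1, flair, truth


@pytest.fixture(scope="session")
def spect_phantom_clean():
    spec = SpectPhantomSpec(noise_level=0.0, matrix=32, seed=3)
    return (spec, *make_spect_phantom(spec))


def uniform_volume(value=0.0, shape=(10, 10, 10), voxel=1.0, units="intensity"):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel
    return Volume3D(np.full(shape, float(value)), aff, units)


def full_mask(vol: Volume3D, name="mask") -> LabelMap:
    return LabelMap.from_mask(np.ones(vol.shape, bool), vol.affine, name)
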