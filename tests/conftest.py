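import numpy as np
import pytest

from edfrim import (
    GridGeometry,
    compute_edf_psf,
    compute_psf3d,
    make_pupil,
)

WAVELENGTH = 530.0 / 1.3  # in-medium, nm
NA = 0.8


@pytest.fixture(scope="session")
def grid64():
    """Desk-scale reconstruction grid at the reference voxel pitches."""
    return GridGeometry(nx=64, ny=64, nz=32, dx=38.5, dy=38.5, dz=87.5)


@pytest.fixture(scope="session")
def grid32():
    return GridGeometry(nx=32, ny=32, nz=8, dx=38.5, dy=38.5, dz=87.5)


@pytest.fixture(scope="session")
def pupil64(grid64):
    return make_pupil(NA, WAVELENGTH, grid64)


@pytest.fixture(scope="session")
def psf64(pupil64, grid64):
    return compute_psf3d(pupil64, grid64)


@pytest.fixture(scope="session")
def edf64(psf64):
    return compute_edf_psf(psf64)
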