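import numpy as np
import pytest

from qcfmri.dataio import VolumeGrid, EpiSeries
from qcfmri.synthgen import PhantomSpec, make_anat_phantom, make_epi


@pytest.fixture
def small_grid():
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    aff[:3, 3] = -np.array([7, 7, 4.5]) * 3.0
    return VolumeGrid.from_affine((8, 8, 4), aff, qform_code=1, sform_code=1)


@pytest.fixture
def quiet_phantom():
    """Clean phantom: no motion, no artifacts, mild noise."""
    spec = PhantomSpec(n_vols=60, noise_sd=1.0)
    epi, truth = make_epi(spec, seed=11)
    return spec, epi, truth


@pytest.fixture
def anat_phantom():
    return make_anat_phantom(PhantomSpec(), seed=11)


def make_series(data, tr_s=2.0, affine=None):
    """Wrap a raw 4D array as an EpiSeries on a simple centered grid."""
    data = np.asarray(data, float)
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = -(np.asarray(data.shape[:3]) - 1) / 2.0 * 3.0
    grid = VolumeGrid.from_affine(data.shape[:3], affine, 1, 1)
    return EpiSeries(grid=grid, data=data, tr_s=tr_s, n_vols=data.shape[3])
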