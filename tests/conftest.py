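import warnings

import numpy as np
import pytest

import dtialps as da

# statsmodels MixedLM emits benign convergence chatter on small simulations
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def scheme():
    return da.default_gradient_scheme()


@pytest.fixture(scope="session")
def roi_grid():
    return da.minimal_roi_grid()


@pytest.fixture(scope="session")
def default_cohort():
    return da.simulate_cohort(da.CohortSimParams(), seed=42)


@pytest.fixture()
def tiny_grid():
    aff = np.eye(4)
    aff[:3, :3] = np.diag([2.0, 2.0, 2.0])
    return da.VolumeGrid(shape=(6, 6, 6), voxel_size=(2.0, 2.0, 2.0), affine=aff)


def uniform_field(grid, dxx, dyy, dzz, off=(0.0, 0.0, 0.0)):
    comps = np.zeros(grid.shape + (6,))
    comps[..., 0] = dxx
    comps[..., 1] = dyy
    comps[..., 2] = dzz
    comps[..., 3:] = np.asarray(off)
    return da.DiffusionTensorField(
        components=comps, grid=grid, mask=np.ones(grid.shape, dtype=bool)
    )
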