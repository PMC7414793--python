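import numpy as np
import pytest

from flimglia import AcquisitionGrid, IRFProfile


@pytest.fixture(scope="session")
def grid():
    """Default acquisition grid: 256 channels over 12.5 ns, 128x128."""
    return AcquisitionGrid()


@pytest.fixture(scope="session")
def irf(grid):
    """Default Gaussian IRF (FWHM 300 ps, peak at channel 10)."""
    return IRFProfile.gaussian(grid)


@pytest.fixture(scope="session")
def delta_irf(grid):
    return IRFProfile.delta(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
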