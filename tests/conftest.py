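import numpy as np
import pytest

from panev.core import Grid2D, ProbeGeometry
from panev.forward import AcousticConfig


@pytest.fixture(scope="session")
def probe():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def grid():
    return Grid2D()


@pytest.fixture(scope="session")
def acfg(probe):
    return AcousticConfig(output_fs_mhz=probe.fs_mhz)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def point_source(grid, depth_mm, x_mm, amplitude=1.0):
    """Initial pressure map with a single non-zero cell near (depth, x)."""
    p0 = np.zeros((grid.nz, grid.nx))
    iz = int(round(depth_mm / grid.dx_mm - 0.5))
    ix = int(round((x_mm + grid.extent_x_mm / 2) / grid.dx_mm - 0.5))
    p0[iz, ix] = amplitude
    return p0, (grid.z_mm[iz], grid.x_mm[ix])
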