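import numpy as np
import pytest

from vfdrive import binocular, geometry
from vfdrive.geometry import Eye, Pattern


@pytest.fixture(scope="session")
def grid_24_od():
    return geometry.build_pattern(Pattern.P24_2, Eye.OD)


@pytest.fixture(scope="session")
def grid_24_os():
    return geometry.build_pattern(Pattern.P24_2, Eye.OS)


@pytest.fixture(scope="session")
def grid_30_od():
    return geometry.build_pattern(Pattern.P30_2, Eye.OD)


def make_flat_field(grid, tv=30.0, td=0.0):
    """Constant monocular field (used as the all-normal baseline)."""
    return binocular.MonocularField(
        eye=grid.eye,
        grid=grid,
        tv=np.full(grid.n_locations, float(tv)),
        td=np.full(grid.n_locations, float(td)),
    )


@pytest.fixture
def normal_pair(grid_24_os, grid_24_od):
    return make_flat_field(grid_24_os), make_flat_field(grid_24_od)
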