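import numpy as np
import pytest

from gccafmri.grids import GridSpec
from gccafmri.synthetic import make_block_design


@pytest.fixture
def full_grid():
    """Small fully-masked grid for geometry-light tests."""
    dims = (10, 10, 5)
    return GridSpec(dims=dims, voxel_size_mm=(3.0, 3.0, 3.0),
                    mask=np.ones(dims, dtype=bool))


@pytest.fixture
def paper_design():
    """The package's default paradigm: 4+4 x 35 s blocks, TR 3.5 s, drop 5."""
    return make_block_design(4, 4, 35.0, 3.5, drop_initial=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
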