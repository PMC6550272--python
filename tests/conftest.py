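import numpy as np
import pytest

from affectkit.features import HogConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_hog():
    """16x16 patch config: fast enough for brute-force oracles."""
    return HogConfig(patch_size=16, cell_size=4, block_size=2, n_orientations=9)
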