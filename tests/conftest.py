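import numpy as np
import pytest

from fcstates.atlas import default_atlas
from fcstates.simulate import default_ground_truth


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def ground_truth(atlas):
    return default_ground_truth(atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
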