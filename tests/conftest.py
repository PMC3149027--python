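import numpy as np
import pytest

from ire1_rnase.synthetic_data import AssayDesign, NoiseModel


@pytest.fixture
def noiseless():
    return NoiseModel(sd_fraction=0.0, seed=0)


@pytest.fixture
def design():
    return AssayDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)
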