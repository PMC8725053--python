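import numpy as np
import pytest
from hypothesis import settings

from carescreen import ScaleDesign, make_generator_spec

settings.register_profile("repro", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def design():
    return ScaleDesign.hexaco_like()


@pytest.fixture(scope="session")
def gen_spec(design):
    """Calibrated default copula generator (shared; calibration is pure)."""
    return make_generator_spec(design, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
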