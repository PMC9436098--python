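import numpy as np
import pytest
from hypothesis import settings

from rdnasim.core import ModelParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def default_params() -> ModelParams:
    """The cln3 evolution-experiment parameterization (125 -> 220, Delta 1.3)."""
    return ModelParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
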