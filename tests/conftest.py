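import numpy as np
import pytest

from fretscape import FretSetup


@pytest.fixture
def neutral_setup() -> FretSetup:
    """Default instrument: R0 = 5.4 nm, all corrections neutral."""
    return FretSetup()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
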