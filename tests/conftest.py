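import numpy as np
import pytest

from seats import ModelParameters, get_preset


@pytest.fixture(scope="session")
def p_super() -> ModelParameters:
    """High-transmission parameter set (R0 = 11.11)."""
    return get_preset("p2").params


@pytest.fixture(scope="session")
def p_sub() -> ModelParameters:
    """Parameter set with R0 just above 1 (the low-transmission preset)."""
    return get_preset("p1").params


@pytest.fixture(scope="session")
def p_control() -> ModelParameters:
    """Control-scenario parameters on a population of 100."""
    return get_preset("fig7").params


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
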