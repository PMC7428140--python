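import numpy as np
import pytest

from sorensen import model_core, params


@pytest.fixture(scope="session")
def p_a1():
    return params.appendix_a1()


@pytest.fixture(scope="session")
def p_t3():
    return params.table3_after()


@pytest.fixture(scope="session")
def simo_after():
    return params.simo_after()


@pytest.fixture(scope="session")
def basal_a1(p_a1):
    return model_core.basal_initialization(p_a1, mode="exact")


@pytest.fixture(scope="session")
def basal_a1_paper(p_a1):
    return model_core.basal_initialization(p_a1, mode="paper")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
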