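import numpy as np
import pytest

from uaeopt import data as dio


@pytest.fixture(scope="session")
def paper_design():
    return dio.load_design("paper")


@pytest.fixture(scope="session")
def paper_responses():
    return dio.load_responses("paper")


@pytest.fixture(scope="session")
def paper_X(paper_design):
    return dio.design_matrix(paper_design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
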