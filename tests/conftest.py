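import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sandilite.acquisition import connectom_like_protocol, prisma_protocol
from sandilite.dictionary_fit import build_dictionary


@pytest.fixture(scope="session")
def prisma():
    return prisma_protocol()


@pytest.fixture(scope="session")
def connectom():
    return connectom_like_protocol()


@pytest.fixture(scope="session")
def dict_connectom(connectom):
    return build_dictionary(connectom)


@pytest.fixture(scope="session")
def dict_prisma(prisma):
    return build_dictionary(prisma)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
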