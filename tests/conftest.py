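import pytest

from chimeraprot import ModelingConfig
from chimeraprot.fixtures import make_embedded_pair


@pytest.fixture(scope="session")
def cfg():
    return ModelingConfig()


@pytest.fixture(scope="session")
def embedded_pair():
    """One certified embedded fixture: 30-aa guest in a 100-aa host."""
    return make_embedded_pair(1, host_len_aa=100, guest_len_aa=30, frames=(3, 1))
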