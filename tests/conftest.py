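import numpy as np
import pytest

from cbrd_iid.network import NetworkConfig


@pytest.fixture
def default_config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass
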