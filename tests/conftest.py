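import pytest
from hypothesis import HealthCheck, settings

from ontoquant.encoder import Encoder, small_config

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_cfg():
    """A very small encoder config for fast unit tests."""
    return small_config(seed=3, embed_dim=32, hidden_dim=32,
                        vocab_size=256, max_len=12)


@pytest.fixture(scope="session")
def tiny_encoder(tiny_cfg):
    return Encoder(tiny_cfg)


@pytest.fixture(scope="session")
def default_encoder():
    """Encoder at the desk-scale default dimensions."""
    return Encoder(small_config(seed=101))
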