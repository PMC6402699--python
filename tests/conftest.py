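import dataclasses

import pytest

from cosmodyn import LYSINE_RELEASE_VS_GROWTH, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def lys_consumer(registry):
    """Lysine-requiring, hypoxanthine-releasing strain (1335)."""
    return registry["1335"]


@pytest.fixture(scope="session")
def hyp_consumer(registry):
    """Hypoxanthine-requiring, lysine-releasing strain (1340); piecewise
    lysine release law in local hypoxanthine."""
    return registry["1340"]


@pytest.fixture(scope="session")
def hyp_consumer_linear(hyp_consumer):
    """Same strain with the growth-rate-based linear lysine release law."""
    return dataclasses.replace(hyp_consumer, release=LYSINE_RELEASE_VS_GROWTH)
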