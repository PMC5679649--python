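import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from maxentseq.fixtures import build_exact_xor_network
from maxentseq.network import ALPHABET

ALL_DINUCLEOTIDES = [a + b for a in ALPHABET for b in ALPHABET]


@pytest.fixture(scope="session")
def route_net():
    """Exact XOR network whose two XOR routes occupy distinct penultimate units."""
    return build_exact_xor_network("route_separating")


@pytest.fixture(scope="session")
def merged_net():
    return build_exact_xor_network("merged")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
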