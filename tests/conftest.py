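import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polynet import TripartiteNetwork, two_drug_toy

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy2() -> TripartiteNetwork:
    """The packaged two-drug toy network (13 nodes, 13 edges)."""
    return two_drug_toy()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
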