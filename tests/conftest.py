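import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi 0/1 adjacency, symmetric, no self-loops."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1).astype(np.int8)
    return adj + adj.T
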