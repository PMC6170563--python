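import numpy as np
import pytest

from econetres import IncidenceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_by_three():
    """The worked 2x3 web: plants p1, p2; animals a1..a3."""
    return IncidenceMatrix(
        ("p1", "p2"), ("a1", "a2", "a3"), np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
    )


def random_binary_incidence(rng, max_dim=8):
    """Random pruned binary web with n, m in [1, max_dim]."""
    for _ in range(100):
        n = int(rng.integers(1, max_dim + 1))
        m = int(rng.integers(1, max_dim + 1))
        M = (rng.random((n, m)) < rng.uniform(0.2, 0.9)).astype(float)
        if M.sum(axis=1).min() > 0 and M.sum(axis=0).min() > 0:
            return IncidenceMatrix(
                tuple(f"p{i}" for i in range(n)), tuple(f"a{j}" for j in range(m)), M
            )
    raise RuntimeError("could not draw a pruned web")
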