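import numpy as np
import pytest

from qgopt.replicator import Population


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def population_factory():
    """Random finite populations with uniform base frequencies."""

    def make(seed: int = 0, K: int = 12, D: int = 3) -> Population:
        r = np.random.default_rng(seed)
        X = r.standard_normal((K, D))
        f = r.standard_normal(K)
        return Population.uniform(X, f)

    return make
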