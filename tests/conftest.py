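import numpy as np
import pytest
from hypothesis import settings

from signmf import AbundanceMatrix, synthetic_dense

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def small_matrix() -> AbundanceMatrix:
    values = np.array(
        [
            [1.0, 2.0, 0.5],
            [3.0, 0.0, 1.5],
            [0.0, 4.0, 2.0],
            [2.0, 1.0, 1.0],
            [1.0, 1.0, 0.0],
        ]
    )
    return AbundanceMatrix(values, ("g1", "g2", "?", "g4", "g5"), ("s1", "s2", "s3"))


@pytest.fixture
def rank1_exact():
    """An exactly rank-1 positive matrix with its generating vectors."""
    rng = np.random.default_rng(42)
    w = rng.uniform(0.5, 2.0, size=8)
    h = rng.uniform(0.5, 2.0, size=6)
    return np.outer(w, h), w, h


@pytest.fixture
def noiseless_rank3():
    """Noiseless exactly factorizable synthetic dataset, true rank 3."""
    return synthetic_dense(k=3, n=10, p=0.25, s=0.25, noise_var=0.0, seed=33)
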