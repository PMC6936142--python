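import numpy as np
import pandas as pd
import pytest

from manialign import make_paired_manifold


@pytest.fixture
def tiny_expression():
    """3 genes x 2 samples with easily checked values."""
    return pd.DataFrame(
        [[1.0, 3.0], [0.0, 4.0], [7.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )


@pytest.fixture
def small_scenario():
    """Default paired-manifold scenario at a fixed seed."""
    return make_paired_manifold(seed=7)


def random_partition(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """A random k-label partition guaranteed to use at least one label."""
    return rng.integers(0, k, size=n)
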