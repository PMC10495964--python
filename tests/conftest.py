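import numpy as np
import pytest

from jscore import LabelPair, worked_example_pair


@pytest.fixture(scope="session")
def stray_pair() -> LabelPair:
    """Four clusters over classes 10/30/60; the 20-point cluster is stray."""
    return worked_example_pair("stray")


@pytest.fixture(scope="session")
def stray_split_pair() -> LabelPair:
    """The stray cluster of ``stray_pair`` split into two clusters of 10."""
    return worked_example_pair("stray-split")


@pytest.fixture(scope="session")
def merged_pair() -> LabelPair:
    """Two clusters mixing 70%/30% of each class; the 30% cluster is stray."""
    return worked_example_pair("merged")


@pytest.fixture(scope="session")
def merged_split_pair() -> LabelPair:
    """The 30% cluster of ``merged_pair`` dealt into two equal halves."""
    return worked_example_pair("merged-split")


def random_pair(rng: np.random.Generator, n_max: int = 40) -> LabelPair:
    """A random label pair with modest N and block counts, for property sweeps."""
    n = int(rng.integers(1, n_max + 1))
    t = rng.integers(0, int(rng.integers(1, min(n, 6) + 1)), size=n)
    k = rng.integers(0, int(rng.integers(1, min(n, 6) + 1)), size=n)
    return LabelPair(t, k)
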