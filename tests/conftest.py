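import numpy as np
import pytest

from dipd.counts_io import CountMatrix, filter_counts
from dipd.synthetic import SyntheticSpec, generate


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """2x2 matrix [[1,3],[2,4]] used in the closed-form worked example."""
    return CountMatrix(np.array([[1, 3], [2, 4]]), ["gA", "gB"], ["c1", "c2"])


@pytest.fixture(scope="session")
def homogeneous_counts() -> CountMatrix:
    """Droplet-like homogeneous matrix, filtered, no planted structure."""
    m, _, _ = generate(SyntheticSpec(G=200, C=80, seed=314))
    return filter_counts(m)


@pytest.fixture(scope="session")
def homogeneous_with_rates():
    """Unfiltered homogeneous matrix together with its true rate surface."""
    m, labels, rates = generate(SyntheticSpec(G=200, C=120, seed=2718))
    return m, labels, rates
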