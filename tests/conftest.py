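import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def triangle_network():
    from netnorm import WeightedNetwork

    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = a[0, 2] = a[2, 0] = a[1, 2] = a[2, 1] = 0.7
    return WeightedNetwork(a)


@pytest.fixture
def two_triangles_network():
    """Two disconnected unit-weight triangles: known max modularity 0.5."""
    from netnorm import WeightedNetwork

    a = np.zeros((6, 6))
    for (i, j) in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1.0
    return WeightedNetwork(a)
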