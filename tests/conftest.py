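import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from psnet import PlantedSpec, SimilarityMatrix, ThresholdNetwork, planted_similarity


@pytest.fixture(scope="session")
def planted():
    """Default planted-partition fixture: 3 blocks of 10, 75/25, sd 3."""
    return planted_similarity(PlantedSpec(seed=0))


@pytest.fixture
def two_cliques_bridge():
    """Two 4-cliques joined by a single bridge edge."""
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    edges = [(x, y) for i, x in enumerate(a) for y in a[i + 1 :]]
    edges += [(x, y) for i, x in enumerate(b) for y in b[i + 1 :]]
    edges.append(("a0", "b0"))
    return ThresholdNetwork.from_edges(a + b, edges)


@pytest.fixture
def path3():
    """The 3-node path a-b-c."""
    return ThresholdNetwork.from_edges(["a", "b", "c"], [("a", "b"), ("b", "c")])


def make_symmetric_matrix(values, labels=None) -> SimilarityMatrix:
    v = np.asarray(values, dtype=float)
    labels = labels or [f"s{i}" for i in range(v.shape[0])]
    return SimilarityMatrix(labels, v, symmetric=True)


@pytest.fixture
def constant50():
    """All off-diagonal similarities equal to 50."""
    n = 6
    v = np.full((n, n), 50.0)
    np.fill_diagonal(v, 100.0)
    return make_symmetric_matrix(v)
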