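import numpy as np
import pandas as pd
import pytest

from mapperplus import DataMatrix, RawTable, WeightedGraph
from mapperplus.synthetic import gaussian_blobs


def clique_pair_graph(size: int = 20) -> WeightedGraph:
    """Two unit-weight cliques joined by a single bridge edge."""
    n = 2 * size
    a = np.zeros((n, n))
    for base in (0, size):
        block = slice(base, base + size)
        a[block, block] = 1.0
    np.fill_diagonal(a, 0.0)
    a[0, size] = a[size, 0] = 1.0
    return WeightedGraph(adjacency=a)


@pytest.fixture(scope="session")
def three_blobs():
    """The canonical well-separated fixture: 3 Gaussian blobs, 20-sigma apart."""
    return gaussian_blobs(
        n_per_blob=100, centers=[[0.0, 0.0], [20.0, 0.0], [0.0, 20.0]],
        sigma=1.0, seed=0,
    )


@pytest.fixture(scope="session")
def three_blob_matrix(three_blobs) -> DataMatrix:
    return three_blobs.to_data_matrix()


@pytest.fixture()
def mixed_table() -> RawTable:
    frame = pd.DataFrame(
        {
            "age": [1.0, 2.0, 3.0, 4.0],
            "grp": ["A", "A", "B", "A"],
            "sex": ["M", "F", "M", "F"],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="row_id"),
    )
    return RawTable(frame=frame)


def random_partition(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Random disjoint labels with every community non-empty."""
    labels = rng.integers(0, m, size=n)
    for c in range(m):
        if not (labels == c).any():
            labels[rng.integers(0, n)] = c
    present = np.unique(labels)
    remap = {v: i for i, v in enumerate(present)}
    return np.array([remap[v] for v in labels])
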