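import numpy as np
import pytest

from scresolve import Embedding, Partition


def random_instance(rng: np.random.Generator, n_max: int = 200, d_max: int = 10):
    """A random embedding + partition with 2-6 clusters, each non-empty."""
    n = int(rng.integers(10, n_max + 1))
    d = int(rng.integers(1, d_max + 1))
    k = int(rng.integers(2, 7))
    X = rng.normal(size=(n, d)) * rng.uniform(0.5, 3.0)
    labels = rng.integers(0, k, size=n)
    labels[:k] = np.arange(k)  # guarantee every cluster occupied
    # contiguous relabel
    uniq = np.unique(labels)
    remap = {int(u): i for i, u in enumerate(uniq)}
    labels = np.array([remap[int(x)] for x in labels])
    ids = [f"c{i}" for i in range(n)]
    emb = Embedding(coords=X, cell_ids=ids)
    part = Partition(labels=labels, resolution=1.0, seed=0, algorithm="leiden", cell_ids=ids)
    return emb, part


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_embedding(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"c{i}" for i in range(len(points))]
    return Embedding(coords=points, cell_ids=ids)


def make_partition(labels, ids=None, resolution=1.0, seed=0):
    labels = np.asarray(labels)
    ids = ids or [f"c{i}" for i in range(len(labels))]
    return Partition(labels=labels, resolution=resolution, seed=seed, algorithm="leiden", cell_ids=ids)
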