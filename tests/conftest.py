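import numpy as np
import pytest

from fuseclust.preprocess import preprocess
from fuseclust.synthetic import SimSpec, simulate_counts


def numerical_grad(f, x, eps=1e-6):
    """Central finite differences of scalar f with respect to array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


@pytest.fixture(scope="session")
def tiny_dataset():
    """120 cells x 60 genes, 4 groups; enough signal to cluster."""
    raw, labels = simulate_counts(
        SimSpec(n_cells=120, n_genes=60, n_clusters=4, seed=11))
    return raw, labels


@pytest.fixture(scope="session")
def tiny_processed(tiny_dataset):
    raw, labels = tiny_dataset
    data, graph = preprocess(raw, n_hvg=50, k=10)
    return data, graph, labels
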