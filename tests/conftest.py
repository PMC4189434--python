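import numpy as np
import pytest

from bacon import Hyperparameters, forward_simulate, sample_graph_from_prior


@pytest.fixture
def rng():
    return np.random.default_rng(20140126)


@pytest.fixture
def default_hyper():
    return Hyperparameters()


@pytest.fixture
def flat_hyper():
    """Uniform graph prior and graph-independent likelihood."""
    return Hyperparameters(alpha=1.0, beta=1.0, d0=1.0, d1=1.0)


@pytest.fixture
def tiny_problem(default_hyper):
    """Enumerable K=4 instance: truth graph, counts, hyperparameters."""
    rng = np.random.default_rng(7)
    truth, _, counts = forward_simulate(4, default_hyper, 20, rng)
    return truth, counts, default_hyper


def random_graph(K, rng, p=0.3):
    """Plain Erdos-Renyi helper for tests."""
    iu = np.triu_indices(K, 1)
    A = np.zeros((K, K), dtype=np.int8)
    A[iu] = rng.random(len(iu[0])) < p
    return A + A.T


def batch_se(x, n_batches=20):
    """Batch-means standard error of the mean of a correlated trace."""
    x = np.asarray(x, dtype=float)
    n = (len(x) // n_batches) * n_batches
    means = x[:n].reshape(n_batches, -1).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)
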