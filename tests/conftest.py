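"""Shared fixtures: small synthetic maps reused across test modules."""

import numpy as np
import pytest

from tidmap.contact_map import ContactMap


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_symmetric_map(n=50, seed=0, bin_size=1000, circular=True):
    """Dense positive symmetric raw-count map for balancing/correlation tests."""
    r = np.random.default_rng(seed)
    m = r.integers(1, 100, size=(n, n)).astype(float)
    m = np.triu(m) + np.triu(m, 1).T
    return ContactMap(matrix=m, bin_size=bin_size, genome_length=n * bin_size,
                      circular=circular)


def toeplitz_map(n=100, alpha=0.8, bin_size=1000, circular=True):
    """Noise-free map whose entries depend only on genomic separation."""
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    if circular:
        d = np.minimum(d, n - d)
    m = (d + 1.0) ** (-alpha)
    return ContactMap(matrix=m, bin_size=bin_size, genome_length=n * bin_size,
                      circular=circular, balanced=True)


@pytest.fixture(scope="session")
def small_map():
    return random_symmetric_map()


@pytest.fixture(scope="session")
def decay_map():
    return toeplitz_map()
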