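import numpy as np
import pytest

from mosaic_hic import (
    ContactMatrix,
    GenomicBinning,
    SyntheticParams,
    generate_matrix,
    generate_tracks,
    generate_truth,
    modularity_matrix,
)


@pytest.fixture
def dyad_model():
    """Two disconnected unit-weight dyads: edges 1-2 and 3-4."""
    adj = np.zeros((4, 4))
    adj[0, 1] = adj[1, 0] = 1.0
    adj[2, 3] = adj[3, 2] = 1.0
    cm = ContactMatrix(GenomicBinning("chrT", 1, 4), adj, kind="oe")
    return adj, modularity_matrix(cm)


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(200, seed=11)


@pytest.fixture(scope="session")
def small_matrix(small_truth):
    return generate_matrix(small_truth)


@pytest.fixture(scope="session")
def small_tracks(small_truth):
    active, h3, expr = generate_tracks(small_truth)
    return {"active": active, "h3k27me3": h3, "expression": expr}


def random_symmetric_graph(rng, n):
    """Random non-negative weighted graph with a guaranteed positive m."""
    adj = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
    adj = (adj + adj.T) / 2.0
    np.fill_diagonal(adj, rng.random(n) * (rng.random(n) < 0.3))
    if adj.sum() == 0:
        adj[0, 1] = adj[1, 0] = 1.0
    return adj


def as_contact(adj, kind="oe"):
    return ContactMatrix(GenomicBinning("chrT", 1, adj.shape[0]), adj, kind=kind)


def two_block_matrix(n=60, within=2.0, between=1.0, seed=0, noise=0.0):
    """Planted two-block O/E-like matrix (blocks split at n//2)."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    labels[n // 2 :] = 1
    base = np.where(np.equal.outer(labels, labels), within, between).astype(float)
    if noise > 0:
        mult = rng.lognormal(0.0, noise, (n, n))
        base *= np.sqrt(mult * mult.T)
        base = (base + base.T) / 2
    return as_contact(base), labels
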