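import itertools

import numpy as np
import pytest

import eegconn as ec


@pytest.fixture(scope="session")
def montage():
    return ec.load_montage()


@pytest.fixture(scope="session")
def two_block_spec():
    """Two blocks of four channels, strong intra- and weak inter-coupling."""
    return ec.CouplingSpec(n_channels=8, fs=200.0, duration=30.0, seed=7,
                           rho_hi=0.8, rho_lo=0.1)


@pytest.fixture(scope="session")
def two_block_rec(two_block_spec):
    return ec.gen_structured_recording(two_block_spec)


@pytest.fixture(scope="session")
def two_block_pairs(two_block_spec):
    """(intra, inter) unordered index-pair lists of the two-block layout."""
    blocks = two_block_spec.block_assignment()
    intra, inter = [], []
    for a, b in itertools.combinations(range(two_block_spec.n_channels), 2):
        same = any(a in blk and b in blk for blk in blocks)
        (intra if same else inter).append((a, b))
    return intra, inter


def random_symmetric_cm(n, seed, metric="plv", low=0.0, high=1.0):
    """Random symmetric ConnectivityMatrix with the metric's self-diagonal."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(low, high, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return ec.ConnectivityMatrix(weights=w, metric=metric,
                                 labels=tuple(f"ch{i}" for i in range(n)))
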