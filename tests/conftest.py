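import numpy as np
import pytest

import vplotvae as vv


@pytest.fixture(scope="session")
def small_truth():
    """A compact chromatin map shared by fast tests."""
    return vv.simulate_chromatin_map(contig_length=60_000, n_nfr=30,
                                     nfr_len_bp=300, seed=7)


@pytest.fixture(scope="session")
def small_fragments(small_truth):
    return vv.simulate_fragments(small_truth, vv.BatchProfile(), 30_000, seed=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def _nor_nfr_stack(n_per_class=100, seed=0, w=128, h=64):
    """Synthetic density stack of idealized NOR-like and NFR-like V-plots."""
    rng = np.random.default_rng(seed)
    x = np.zeros((2 * n_per_class, 1, w, h))
    for i in range(2 * n_per_class):
        counts = np.zeros((w, h))
        if i < n_per_class:  # NOR: mono-nucleosome sizes near the center
            pos = rng.integers(w // 2 - 6, w // 2 + 6, size=40)
            size = rng.integers(18, 25, size=40)
        else:  # NFR: short fragments near the center
            pos = rng.integers(w // 2 - 10, w // 2 + 10, size=40)
            size = rng.integers(0, 10, size=40)
        np.add.at(counts, (pos, size), 1.0)
        x[i, 0] = vv.normalize_vplot(counts)
    labels = np.r_[np.ones(n_per_class), np.zeros(n_per_class)]
    return x, labels


@pytest.fixture(scope="session")
def nor_nfr_stack():
    return _nor_nfr_stack()
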