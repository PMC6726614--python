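import numpy as np
import pytest

from spatialmhg import LabeledCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_cloud(seed, n=None, d=2, b_frac=0.4, n_range=(6, 11)):
    """Uniform random labelled cloud; guarantees 0 < B < N."""
    r = np.random.default_rng(seed)
    if n is None:
        n = int(r.integers(*n_range))
    coords = r.uniform(0, 10, (n, d))
    labels = (r.random(n) < b_frac).astype(int)
    if labels.sum() == 0:
        labels[0] = 1
    elif labels.sum() == n:
        labels[0] = 0
    return LabeledCloud(coords, labels)


@pytest.fixture
def two_row_construct():
    """Two parallel rows of bins with the positives clustered at one end of
    each row; the interesting pivot sits midway between the two clusters,
    away from every bin."""
    xs = np.arange(8.0)
    coords = np.vstack([np.c_[xs, np.zeros(8)], np.c_[xs, np.full(8, 3.0)]])
    labels = np.zeros(16, dtype=int)
    labels[[0, 1, 8, 9]] = 1
    chrom = np.array(["chr1"] * 8 + ["chr2"] * 8, dtype=object)
    bin_index = np.tile(np.arange(8), 2)
    return LabeledCloud(coords, labels, chrom, bin_index)
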