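import numpy as np
import pytest

from loopshift.contactio import ContactMatrix, GenomeLayout


@pytest.fixture
def layout50():
    """50 bins of 10 kb on one toy chromosome."""
    return GenomeLayout.from_dict({"chrT": 500_000}, 10_000)


@pytest.fixture
def layout_2chr():
    return GenomeLayout.from_dict({"chrA": 500_000, "chrB": 300_000}, 10_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_matrix(layout, chrom, rng, density=0.3, max_count=20,
                  norm_state="raw"):
    """Random symmetric sparse matrix with integer counts."""
    n = layout.n_bins(chrom)
    dense = np.zeros((n, n))
    iu = np.triu_indices(n)
    k = len(iu[0])
    pick = rng.random(k) < density
    dense[iu[0][pick], iu[1][pick]] = rng.integers(1, max_count + 1, pick.sum())
    dense = np.triu(dense) + np.triu(dense, 1).T
    return ContactMatrix.from_dense(layout, chrom, np.triu(dense), norm_state)


@pytest.fixture
def random_matrix_factory():
    return random_matrix
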