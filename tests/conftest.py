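import warnings

import numpy as np
import pytest

import poolfreq as pf

# trust-constr warns about singular constraint Jacobians (the simplex rows are
# linearly dependent with the data rows on exactly representable instances);
# harmless for the oracle comparisons
warnings.filterwarnings(
    "ignore", message="Singular Jacobian matrix", category=UserWarning
)


@pytest.fixture(scope="session")
def dict4():
    """Full dictionary over 4 loci (M=16)."""
    return pf.build_full_dictionary(4)


@pytest.fixture(scope="session")
def dict10():
    """Full dictionary over 10 loci (M=1024)."""
    return pf.build_full_dictionary(10)


@pytest.fixture(scope="session")
def agt():
    return pf.agt_distribution()


def make_row_sparse_instance(dictionary, O, k, rng, noise_sd=0.0):
    """A pool set whose columns share a k-row support in the dictionary."""
    M = dictionary.M
    support = rng.choice(M, size=k, replace=False)
    X = np.zeros((M, O))
    for i in range(O):
        X[support, i] = rng.dirichlet(np.ones(k))
    A = dictionary.H @ X
    if noise_sd:
        A = np.clip(A + rng.normal(0.0, noise_sd, A.shape), 0.0, 1.0)
    return pf.PoolSet(A=A, sizes=np.full(O, 2)), X
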