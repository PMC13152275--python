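import numpy as np
import pytest

from ovoflux.phylo import parse_newick, vcv_matrix
from ovoflux.synthetic import simulate_tree


@pytest.fixture(scope="session")
def cherry():
    """Two tips of height 1 with no shared path."""
    return parse_newick("(A:1,B:1);")


@pytest.fixture(scope="session")
def three_tip():
    """((A:1,B:1):1,C:2); height 2, MRCA(A,B) at depth 1."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree20():
    return simulate_tree(20, seed=101)


@pytest.fixture(scope="session")
def tree100():
    return simulate_tree(100, seed=100)


@pytest.fixture(scope="session")
def chol100(tree100):
    C = vcv_matrix(tree100)
    L = np.linalg.cholesky(C.matrix + 1e-12 * np.eye(C.n))
    return C, L
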