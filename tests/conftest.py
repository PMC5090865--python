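import numpy as np
import pytest
import scipy.sparse as sp

from inpadr.network import HeteroNetwork, LabelIndex, assemble
from inpadr.synthetic import SyntheticConfig, generate, network_from_truth


def make_random_net(rng, n, m, density=0.2, isolated=0):
    """Random heterogeneous network; optionally force some isolated proteins."""
    A = np.triu((rng.random((n, n)) < density) * rng.uniform(0.1, 1.0, (n, n)), 1)
    A = A + A.T
    B = (rng.random((n, m)) < density).astype(float)
    C = np.triu((rng.random((m, m)) < density) * rng.uniform(0.1, 1.0, (m, m)), 1)
    C = C + C.T
    for i in range(isolated):
        A[i, :] = A[:, i] = 0
        B[i, :] = 0
    pidx = LabelIndex([f"p{i}" for i in range(n)])
    aidx = LabelIndex([f"a{j}" for j in range(m)])
    return assemble(sp.csr_matrix(A), sp.csr_matrix(B), sp.csr_matrix(C),
                    pidx, aidx)


def dense_stable(model, p0, r):
    """Closed-form stable vector: r (I - (1-r) M_eff^T)^-1 p0.

    Dangling-row mass redistribution to p0 is folded into the effective
    transition matrix, matching the iterative walk's update exactly.
    """
    MT = model.M.T.toarray()
    MT_eff = MT + np.outer(np.asarray(p0, float), model.dangling.astype(float))
    n = MT.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1.0 - r) * MT_eff, np.asarray(p0, float))


@pytest.fixture(scope="session")
def default_truth():
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def planted_net(default_truth) -> HeteroNetwork:
    return network_from_truth(default_truth)


@pytest.fixture()
def tiny_net() -> HeteroNetwork:
    """Two proteins joined by one edge, one ADR linked to the first protein."""
    A = sp.csr_matrix(np.array([[0.0, 0.8], [0.8, 0.0]]))
    B = sp.csr_matrix(np.array([[1.0], [0.0]]))
    C = sp.csr_matrix((1, 1))
    return assemble(A, B, C, LabelIndex(["p1", "p2"]), LabelIndex(["a1"]))
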