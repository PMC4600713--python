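import numpy as np
import pytest

from netctrl import Connectome, StabilizedSystem


def make_system(A: np.ndarray) -> StabilizedSystem:
    """Wrap an explicit (already stable) matrix as a StabilizedSystem."""
    A = np.asarray(A, dtype=float)
    evals = np.linalg.eigvalsh(A) if A.any() else np.zeros(A.shape[0])
    rho = float(max(abs(evals[0]), abs(evals[-1]))) if A.any() else 0.0
    ids = [f"n{i}" for i in range(1, A.shape[0] + 1)]
    return StabilizedSystem(adjacency=A, scheme="manual", c=1.0, rho=rho, region_ids=ids)


def random_stable_system(rng: np.random.Generator, n: int) -> StabilizedSystem:
    """Random symmetric zero-diagonal matrix scaled inside the unit disc."""
    A = rng.random((n, n))
    A = np.triu(A, 1)
    A = A + A.T
    lam = np.linalg.eigvalsh(A)[-1]
    A = A / (1.0 + lam)
    return make_system(A)


@pytest.fixture
def two_node_half():
    """The 2-node stabilized system with off-diagonal weight 0.5."""
    return make_system([[0.0, 0.5], [0.5, 0.0]])


@pytest.fixture
def two_triangles():
    """Two unit-weight triangles {1,2,3}, {4,5,6} joined by bridge 3-4."""
    A = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
        A[i, j] = A[j, i] = 1.0
    return Connectome(region_ids=[f"n{i}" for i in range(1, 7)], adjacency=A)


@pytest.fixture
def path3():
    """3-node path with weights 2 and 4."""
    A = np.array([[0.0, 2.0, 0.0], [2.0, 0.0, 4.0], [0.0, 4.0, 0.0]])
    return Connectome(region_ids=["a", "b", "c"], adjacency=A)
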