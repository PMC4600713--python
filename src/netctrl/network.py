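"""Connectome data model, node strength, stabilization and linear dynamics.

The structural network is a symmetric, nonnegative, zero-diagonal weighted
adjacency matrix A (streamline counts between parcellated brain regions).
Neural activity is modelled as the noise-free discrete-time linear system

    x(t+1) = A_s x(t) + B_K u(t)

where ``A_s`` is a stabilized version of A and ``B_K`` selects the control
regions.  All controllability diagnostics downstream operate on ``A_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la

__all__ = [
    "Connectome",
    "StabilizedSystem",
    "ControlSet",
    "Trajectory",
    "weighted_degree",
    "stabilize",
    "simulate_dynamics",
]

_SYM_TOL = 1e-9


@dataclass
class Connectome:
    """A weighted, undirected, zero-diagonal brain network.

    Parameters
    ----------
    region_ids
        Ordered region identifiers (strings), one per node.
    adjacency
        Square symmetric matrix of nonnegative edge weights
        (streamline counts); the diagonal must be zero.
    subject, scan
        Optional cohort tags.
    """

    region_ids: list[str]
    adjacency: np.ndarray
    subject: str | None = None
    scan: str | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {A.shape}")
        if len(self.region_ids) != A.shape[0]:
            raise ValueError(
                f"{len(self.region_ids)} region ids for {A.shape[0]}x{A.shape[1]} matrix"
            )
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region ids must be unique")
        if not np.all(np.isfinite(A)):
            raise ValueError("adjacency contains non-finite entries")
        if np.any(A < 0):
            raise ValueError("adjacency contains negative weights")
        if not np.allclose(A, A.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("adjacency is not symmetric")
        if np.any(np.abs(np.diag(A)) > 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = A

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def index_of(self, region_id: str) -> int:
        return self.region_ids.index(region_id)


@dataclass
class StabilizedSystem:
    """Normalized adjacency A_s driving the linear dynamics.

    ``rho`` is the spectral radius of A_s; infinite-horizon Gramian
    operations require ``rho < 1`` and call :meth:`require_stable`.
    """

    adjacency: np.ndarray
    scheme: str
    c: float
    rho: float
    region_ids: list[str] = field(default_factory=list)
    subject: str | None = None
    scan: str | None = None

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def require_stable(self) -> None:
        if not self.rho < 1.0:
            raise ValueError(
                f"spectral radius {self.rho:.6g} >= 1 under scheme "
                f"'{self.scheme}': infinite-horizon Gramian diverges "
                "(use the spectral stabilization scheme)"
            )


@dataclass
class ControlSet:
    """Ordered control node indices K and the input matrix B_K.

    Columns of B_K are the canonical vectors e_i for i in K.
    """

    nodes: list[int]
    B: np.ndarray

    @classmethod
    def from_nodes(cls, nodes, n: int) -> "ControlSet":
        nodes = [int(i) for i in nodes]
        if len(nodes) < 1:
            raise ValueError("control set must contain at least one node")
        if len(set(nodes)) != len(nodes):
            raise ValueError("control nodes must be distinct")
        if any(i < 0 or i >= n for i in nodes):
            raise ValueError(f"control node out of range for n={n}")
        B = np.zeros((n, len(nodes)))
        for col, i in enumerate(nodes):
            B[i, col] = 1.0
        return cls(nodes=nodes, B=B)


@dataclass
class Trajectory:
    states: np.ndarray  # (T+1, N)
    inputs: np.ndarray  # (T, |K|)
    horizon: int


def weighted_degree(conn: Connectome, mode: str = "sum") -> np.ndarray:
    """Node strength k_i = sum_j a_ij, or the mean weight of existing edges.

    ``mode='sum'`` (default) is conventional node strength; ``mode='mean'``
    divides by the number of nonzero edges at each node (0 for isolated
    nodes).  Rank-based analyses are unaffected by the choice.
    """
    A = conn.adjacency
    k = A.sum(axis=1)
    if mode == "sum":
        return k
    if mode == "mean":
        counts = (A > 0).sum(axis=1)
        out = np.zeros_like(k)
        nz = counts > 0
        out[nz] = k[nz] / counts[nz]
        return out
    raise ValueError(f"unknown degree mode {mode!r}")


def stabilize(conn: Connectome, scheme: str = "spectral", c: float = 1.0) -> StabilizedSystem:
    """Normalize the adjacency so the linear dynamics can be analysed.

    schemes
    -------
    ``spectral`` (default): A_s = A / (c * (1 + lambda_max(A))).  For any
    nonnegative symmetric A and c >= 1 this guarantees spectral radius < 1.

    ``mean_edge_weight``: A_s = A / mean(nonzero off-diagonal weights),
    the normalization described with the model; it does **not** guarantee
    stability (a single-edge graph maps to weight 1 exactly), so the
    resulting ``rho`` is recorded and checked by Gramian operations.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    A = conn.adjacency
    if scheme == "spectral":
        lam_max = la.eigvalsh(A)[-1] if A.any() else 0.0
        A_s = A / (c * (1.0 + lam_max))
    elif scheme == "mean_edge_weight":
        nz = A[A > 0]
        if nz.size == 0:
            raise ValueError("mean_edge_weight scheme undefined for an all-zero matrix")
        A_s = A / nz.mean()
    else:
        raise ValueError(f"unknown stabilization scheme {scheme!r}")
    if A_s.any():
        evals = la.eigvalsh(A_s)
        rho = float(max(abs(evals[0]), abs(evals[-1])))
    else:
        rho = 0.0
    return StabilizedSystem(
        adjacency=A_s,
        scheme=scheme,
        c=float(c),
        rho=rho,
        region_ids=list(conn.region_ids),
        subject=conn.subject,
        scan=conn.scan,
    )


def simulate_dynamics(
    sys: StabilizedSystem,
    ctrl: ControlSet,
    x0: np.ndarray,
    u: np.ndarray,
    horizon: int | None = None,
) -> Trajectory:
    """Iterate x(t+1) = A_s x(t) + B_K u(t) for ``horizon`` steps."""
    A = sys.adjacency
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != sys.n:
        raise ValueError(f"x0 has length {x0.size}, expected {sys.n}")
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if u.shape[1] != len(ctrl.nodes):
        raise ValueError(
            f"inputs have {u.shape[1]} channels, control set has {len(ctrl.nodes)}"
        )
    T = u.shape[0] if horizon is None else int(horizon)
    if u.shape[0] < T:
        raise ValueError(f"need {T} input vectors, got {u.shape[0]}")
    states = np.empty((T + 1, sys.n))
    states[0] = x0
    for t in range(T):
        states[t + 1] = A @ states[t] + ctrl.B @ u[t]
    return Trajectory(states=states, inputs=u[:T].copy(), horizon=T)
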