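"""Boundary controllability: consensus partition + iterative Fiedler splits.

Boundary controllability marks regions that sit at the interfaces between
network communities and can therefore couple or decouple cognitive systems.
The assignment is hierarchical:

1. a robust consensus partition of the whole network is computed; every
   node with at least one positive-weight edge into another community is a
   first-level boundary node and receives the value 1 (N_1 nodes);
2. each community is bipartitioned by the sign pattern of the Fiedler
   eigenvector of its weighted graph Laplacian; nodes newly exposed on the
   bipartition boundary at depth d receive (N - assigned_before_d) / N;
3. the recursion continues into each half until all nodes carry a value
   (subnetworks of <= 2 nodes absorb their unassigned nodes at the current
   depth's value).

Values therefore lie in (0, 1] and weakly decrease with assignment depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import scipy.linalg as la
from scipy.sparse.csgraph import connected_components

from .network import Connectome

__all__ = [
    "BoundaryParams",
    "Partition",
    "BoundaryValues",
    "robust_partition",
    "boundary_nodes",
    "fiedler_bipartition",
    "boundary_controllability",
]


@dataclass(frozen=True)
class BoundaryParams:
    """Tunables of the consensus partition and the recursion.

    n_runs seeded modularity-maximization runs feed a co-assignment
    matrix, thresholded at the ``consensus_threshold`` quantile of a
    label-permutation null and reclustered.  ``order`` controls the
    recursion: 'breadth_first' (default) processes every community at each
    depth so values depend only on depth; 'least_controllable_first'
    processes one subnetwork at a time, smallest mean average
    controllability first (requires ``avg_ctrl`` passed to
    :func:`boundary_controllability`).
    """

    n_runs: int = 100
    resolution: float = 1.0
    consensus_threshold: float = 0.95
    seed: int = 0
    order: str = "breadth_first"


@dataclass
class Partition:
    membership: dict[str, int]
    n_communities: int
    consensus: dict[str, float] = field(default_factory=dict)


@dataclass
class BoundaryValues:
    """Per-region boundary value in (0, 1] and the depth it was assigned at."""

    values: dict[str, float]
    depth: dict[str, int]
    n1: int


def _to_igraph(A: np.ndarray) -> ig.Graph:
    iu, ju = np.nonzero(np.triu(A, 1))
    g = ig.Graph(n=A.shape[0], edges=list(zip(iu.tolist(), ju.tolist())))
    g.es["weight"] = A[iu, ju].tolist()
    return g


def _leiden_membership(g: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    if resolution == 1.0:
        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, weights="weight", seed=seed
        )
    else:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
        )
    return np.asarray(part.membership)


def robust_partition(
    conn: Connectome,
    n_runs: int = 100,
    resolution: float = 1.0,
    consensus_threshold: float = 0.95,
    seed: int = 0,
) -> Partition:
    """Consensus community structure over many seeded modularity runs.

    The pairwise co-assignment (association) matrix over ``n_runs`` runs is
    thresholded against a label-permutation null (per-run memberships
    shuffled across nodes) at the ``consensus_threshold`` quantile and the
    surviving association graph is reclustered once.  Deterministic given
    the seed.  An edgeless network yields singleton communities.
    """
    n = conn.n
    if n == 0:
        raise ValueError("cannot partition an empty network")
    A = conn.adjacency
    if not A.any():
        membership = {r: i for i, r in enumerate(conn.region_ids)}
        return Partition(membership=membership, n_communities=n,
                         consensus={r: 1.0 for r in conn.region_ids})

    g = _to_igraph(A)
    rng = np.random.default_rng(seed)
    runs = np.empty((n_runs, n), dtype=int)
    for r in range(n_runs):
        runs[r] = _leiden_membership(g, resolution, seed=int(seed + r))

    assoc = np.zeros((n, n))
    null = np.zeros((n, n))
    for r in range(n_runs):
        m = runs[r]
        assoc += m[:, None] == m[None, :]
        p = m[rng.permutation(n)]
        null += p[:, None] == p[None, :]
    assoc /= n_runs
    null /= n_runs
    iu = np.triu_indices(n, 1)
    thresh = float(np.quantile(null[iu], consensus_threshold))
    pruned = np.where(assoc > thresh, assoc, 0.0)
    np.fill_diagonal(pruned, 0.0)

    if pruned.any():
        final = _leiden_membership(_to_igraph(pruned), 1.0, seed=int(seed))
    else:  # no pair survived the null: fall back to the modal run
        final = runs[0]

    consensus = {}
    for i, rid in enumerate(conn.region_ids):
        same = final == final[i]
        same[i] = False
        consensus[rid] = float(assoc[i, same].mean()) if same.any() else 1.0
    membership = {r: int(final[i]) for i, r in enumerate(conn.region_ids)}
    return Partition(
        membership=membership,
        n_communities=int(len(set(final))),
        consensus=consensus,
    )


def boundary_nodes(conn: Connectome, partition: Partition) -> set[str]:
    """Regions with >= 1 positive-weight edge into a different community."""
    A = conn.adjacency
    m = np.array([partition.membership[r] for r in conn.region_ids])
    cross = (A > 0) & (m[:, None] != m[None, :])
    return {conn.region_ids[i] for i in np.nonzero(cross.any(axis=1))[0]}


def fiedler_bipartition(
    A_sub: np.ndarray, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Split a subnetwork by the sign of its Laplacian Fiedler eigenvector.

    Zero entries go to the positive side.  A disconnected subnetwork is
    split into its first connected component versus the rest.  Near-
    degenerate Fiedler pairs (e.g. symmetric triangles) are resolved by a
    deterministic seeded symmetric perturbation of magnitude 1e-9.
    Returns local index lists; raises on fewer than 2 nodes.
    """
    n = A_sub.shape[0]
    if n < 2:
        raise ValueError("cannot bipartition fewer than 2 nodes")
    ncomp, labels = connected_components(A_sub > 0, directed=False)
    if ncomp > 1:
        first = labels == labels[0]
        return list(np.nonzero(first)[0]), list(np.nonzero(~first)[0])

    L = np.diag(A_sub.sum(axis=1)) - A_sub
    evals, V = la.eigh(L)
    scale = max(evals[-1], 1.0)
    if n > 2 and (evals[2] - evals[1]) < 1e-8 * scale:
        rng = np.random.default_rng(seed)
        P = rng.standard_normal((n, n)) * 1e-9
        P = (P + P.T) / 2.0
        np.fill_diagonal(P, 0.0)
        evals, V = la.eigh(L + P)
    v = V[:, 1]
    # orient deterministically: largest-magnitude entry positive
    if v[int(np.argmax(np.abs(v)))] < 0:
        v = -v
    pos = v >= 0.0
    if pos.all() or not pos.any():  # numerically one-sided: split at median
        pos = v >= np.median(v)
    if pos.all() or not pos.any():  # constant vector: split by index
        pos = np.arange(n) < n // 2
    return list(np.nonzero(pos)[0]), list(np.nonzero(~pos)[0])


def _crossing_nodes(A_sub: np.ndarray, g1: list[int], g2: list[int]) -> set[int]:
    if not g1 or not g2:
        return set()
    block = A_sub[np.ix_(g1, g2)] > 0
    out = {g1[i] for i in np.nonzero(block.any(axis=1))[0]}
    out |= {g2[j] for j in np.nonzero(block.any(axis=0))[0]}
    return out


def boundary_controllability(
    conn: Connectome,
    params: BoundaryParams | None = None,
    avg_ctrl: np.ndarray | None = None,
) -> BoundaryValues:
    """Assign every region a boundary controllability value in (0, 1]."""
    if params is None:
        params = BoundaryParams()
    n = conn.n
    if n == 0:
        raise ValueError("empty network")
    A = conn.adjacency
    ids = conn.region_ids

    part = robust_partition(
        conn,
        n_runs=params.n_runs,
        resolution=params.resolution,
        consensus_threshold=params.consensus_threshold,
        seed=params.seed,
    )
    first = boundary_nodes(conn, part)
    values: dict[str, float] = {r: 1.0 for r in first}
    depth: dict[str, int] = {r: 1 for r in first}
    n1 = len(first)

    comms: dict[int, list[int]] = {}
    for i, r in enumerate(ids):
        comms.setdefault(part.membership[r], []).append(i)
    subnets = [sorted(v) for _, v in sorted(comms.items())]

    if params.order == "breadth_first":
        _recurse_breadth_first(A, ids, subnets, values, depth, params.seed)
    elif params.order == "least_controllable_first":
        if avg_ctrl is None:
            raise ValueError("least_controllable_first ordering needs avg_ctrl values")
        _recurse_least_controllable(A, ids, subnets, values, depth, params.seed, avg_ctrl)
    else:
        raise ValueError(f"unknown recursion order {params.order!r}")
    return BoundaryValues(values=values, depth=depth, n1=n1)


def _recurse_breadth_first(A, ids, subnets, values, depth, seed) -> None:
    n = A.shape[0]
    d = 2
    current = subnets
    while any(ids[i] not in values for sub in current for i in sub):
        value_d = (n - len(values)) / n
        newly: set[int] = set()
        nxt: list[list[int]] = []
        for sub in current:
            unassigned = [i for i in sub if ids[i] not in values]
            if not unassigned:
                continue
            if len(sub) <= 2:
                newly.update(unassigned)
                continue
            A_sub = A[np.ix_(sub, sub)]
            g1, g2 = fiedler_bipartition(A_sub, seed=seed + d)
            cross = _crossing_nodes(A_sub, g1, g2)
            newly.update(sub[i] for i in cross if ids[sub[i]] not in values)
            nxt.append([sub[i] for i in g1])
            nxt.append([sub[i] for i in g2])
        for i in newly:
            values[ids[i]] = value_d
            depth[ids[i]] = d
        current = [s for s in nxt if any(ids[i] not in values for i in s)]
        d += 1


def _recurse_least_controllable(A, ids, subnets, values, depth, seed, avg_ctrl) -> None:
    n = A.shape[0]
    d = 2
    pending = list(subnets)
    while pending:
        # least controllable subnetwork first: smallest mean avg. controllability
        pending.sort(key=lambda sub: (float(np.mean(avg_ctrl[sub])), sub))
        sub = pending.pop(0)
        unassigned = [i for i in sub if ids[i] not in values]
        if not unassigned:
            continue
        value_d = (n - len(values)) / n
        if len(sub) <= 2:
            newly = set(unassigned)
        else:
            A_sub = A[np.ix_(sub, sub)]
            g1, g2 = fiedler_bipartition(A_sub, seed=seed + d)
            cross = _crossing_nodes(A_sub, g1, g2)
            newly = {sub[i] for i in cross if ids[sub[i]] not in values}
            for half in (g1, g2):
                part_nodes = [sub[i] for i in half]
                if any(ids[i] not in values for i in part_nodes if i not in newly):
                    pending.append(part_nodes)
        for i in newly:
            values[ids[i]] = value_d
            depth[ids[i]] = d
        d += 1
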