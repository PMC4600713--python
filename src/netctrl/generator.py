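"""Seeded synthetic structural connectomes for cohort-scale experiments.

Real streamline networks are sparse, symmetric, integer-weighted with a
heavy-tailed weight distribution, strongly modular, and contain a minority
of high-strength hub regions that also bridge communities.  The generator
emulates exactly those statistical features with a weighted stochastic
block model:

* regions are split into ``n_communities`` balanced blocks; edges appear
  with probability ``p_within`` inside and ``p_between`` across blocks;
* existing edges carry rounded log-normal weights (>= 1), emulating
  streamline counts;
* ``n_hubs`` designated regions receive extra cross-community edges (at
  the within-community rate) and a multiplicative ``hub_boost`` on all
  incident weights, so hubs are simultaneously high-strength and
  boundary-adjacent;
* repeated scans of one subject are multiplicative log-normal
  perturbations of the subject's base network (plus a small Bernoulli
  edge flip), calibrated so the mean relative weight difference between
  two scans is approximately ``scan_noise``.

Geometry, tractography biases and imaging physics are deliberately not
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .network import Connectome

__all__ = [
    "COGNITIVE_SYSTEMS",
    "GeneratorParams",
    "SystemLabels",
    "generate_connectome",
    "generate_cohort",
    "generate_system_labels",
    "hub_nodes",
    "community_blocks",
]

#: The eight resting-state cognitive systems regions are assigned to.
COGNITIVE_SYSTEMS = (
    "auditory",
    "visual",
    "sensorimotor",
    "ventral attention",
    "dorsal attention",
    "default mode",
    "frontoparietal",
    "cingulo-opercular",
)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort; defaults mirror the study design.

    234 regions (the parcellation scale of the main analysis), 8
    communities, dense within-community and sparse between-community
    connectivity (~5% overall density, so community interiors exist and
    boundary nodes are a genuine minority), log-normal weights with median
    e^3 ~ 20 streamlines, 16 hubs boosted 3x, and 10% scan-to-scan weight
    jitter.
    """

    n_regions: int = 234
    n_communities: int = 8
    p_within: float = 0.35
    p_between: float = 0.005
    weight_mu: float = 3.0
    weight_sigma: float = 1.0
    n_hubs: int = 16
    hub_boost: float = 3.0
    hub_cross_degree: float = 8.0
    scan_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be positive")
        if self.n_communities < 1 or self.n_communities > self.n_regions:
            raise ValueError("need 1 <= n_communities <= n_regions")
        for name in ("p_within", "p_between"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.p_between > self.p_within:
            raise ValueError("modular structure requires p_between <= p_within")
        if self.n_hubs < 0 or self.n_hubs > self.n_regions:
            raise ValueError("need 0 <= n_hubs <= n_regions")
        if self.hub_boost < 1.0:
            raise ValueError("hub_boost must be >= 1")
        if self.hub_cross_degree < 0:
            raise ValueError("hub_cross_degree must be >= 0")
        if not 0.0 <= self.scan_noise < 1.0:
            raise ValueError("scan_noise must lie in [0, 1)")


@dataclass
class SystemLabels:
    """region id -> cognitive system, with per-system sizes."""

    labels: dict[str, str]

    @property
    def systems(self) -> list[str]:
        return sorted(set(self.labels.values()))

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.labels.values():
            out[s] = out.get(s, 0) + 1
        return out


def region_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"R{i:0{width}d}" for i in range(1, n + 1)]


def community_blocks(params: GeneratorParams) -> np.ndarray:
    """Balanced contiguous community assignment, deterministic in params."""
    return np.sort(np.arange(params.n_regions) % params.n_communities)


def hub_nodes(params: GeneratorParams) -> list[int]:
    """Designated hubs: the leading regions of each community, round-robin."""
    comm = community_blocks(params)
    starts = [int(np.searchsorted(comm, c)) for c in range(params.n_communities)]
    hubs: list[int] = []
    offset = 0
    while len(hubs) < params.n_hubs:
        for c in range(params.n_communities):
            if len(hubs) >= params.n_hubs:
                break
            end = starts[c + 1] if c + 1 < params.n_communities else params.n_regions
            cand = starts[c] + offset
            if cand < end:
                hubs.append(cand)
        offset += 1
    return sorted(hubs)


def _lognormal_weights(rng: np.random.Generator, mu: float, sigma: float, size) -> np.ndarray:
    return np.maximum(1.0, np.round(rng.lognormal(mu, sigma, size)))


def generate_connectome(
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
    subject: str | None = None,
    scan: str | None = None,
) -> Connectome:
    """One symmetric, zero-diagonal, integer-weighted modular network."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_regions
    comm = community_blocks(params)
    within = comm[:, None] == comm[None, :]
    P = np.where(within, params.p_within, params.p_between)

    upper = np.triu(np.ones((n, n), dtype=bool), 1)
    edges = upper & (rng.random((n, n)) < P)

    hubs = hub_nodes(params)
    if hubs and params.hub_cross_degree > 0:
        hub_mask = np.zeros(n, dtype=bool)
        hub_mask[hubs] = True
        # extra cross-community edges so each hub bridges modules with an
        # expected hub_cross_degree extra partners (bounded, so community
        # interiors survive)
        n_outside = np.maximum((~within).sum(axis=1), 1)
        p_hub = np.minimum(1.0, params.hub_cross_degree / n_outside)
        extra_p = np.where(
            (hub_mask[:, None] | hub_mask[None, :]) & ~within,
            np.maximum(p_hub[:, None], p_hub[None, :]),
            0.0,
        )
        edges |= upper & (rng.random((n, n)) < extra_p)

    A = np.zeros((n, n))
    ne = int(edges.sum())
    if ne:
        A[edges] = _lognormal_weights(rng, params.weight_mu, params.weight_sigma, ne)
    if hubs and params.hub_boost > 1.0:
        boost = np.ones((n, n))
        boost[hubs, :] *= params.hub_boost
        boost[:, hubs] *= params.hub_boost
        A = np.where(A > 0, np.maximum(1.0, np.round(A * boost)), 0.0)
    A = A + A.T
    return Connectome(
        region_ids=region_names(n), adjacency=A, subject=subject, scan=scan
    )


def perturb_scan(
    A: np.ndarray, scan_noise: float, rng: np.random.Generator,
    weight_mu: float, weight_sigma: float,
) -> np.ndarray:
    """Scan-to-scan perturbation: log-normal jitter + rare edge flips.

    Jitter sigma = scan_noise * sqrt(pi)/2 makes the expected relative
    weight difference between two independently perturbed scans equal
    scan_noise to first order.  A fraction 0.02*scan_noise of edges is
    deleted and an equal expected number of new edges appears.
    """
    if scan_noise == 0.0:
        return A.copy()
    n = A.shape[0]
    upper = np.triu(np.ones((n, n), dtype=bool), 1)
    sigma = scan_noise * math.sqrt(math.pi) / 2.0
    jitter = np.exp(rng.normal(0.0, sigma, (n, n)))
    out = np.where(A > 0, np.maximum(1.0, np.round(A * jitter)), 0.0)

    flip = 0.02 * scan_noise
    present = upper & (A > 0)
    absent = upper & (A == 0)
    n_present, n_absent = int(present.sum()), int(absent.sum())
    drop = present & (rng.random((n, n)) < flip)
    out[drop] = 0.0
    if n_absent:
        p_add = flip * n_present / n_absent
        add = absent & (rng.random((n, n)) < p_add)
        k = int(add.sum())
        if k:
            out[add] = _lognormal_weights(rng, weight_mu, weight_sigma, k)
    out = np.triu(out, 1)
    return out + out.T


def generate_cohort(
    params: GeneratorParams, n_subjects: int, n_scans: int
) -> list[Connectome]:
    """n_subjects x n_scans networks; scans of one subject differ only by
    the scan_noise perturbation of that subject's base network."""
    if n_subjects < 1 or n_scans < 1:
        raise ValueError("need n_subjects >= 1 and n_scans >= 1")
    root = np.random.SeedSequence(params.seed)
    subject_seeds = root.spawn(n_subjects)
    cohort: list[Connectome] = []
    for s, sseq in enumerate(subject_seeds, start=1):
        base_rng = np.random.default_rng(sseq.spawn(1)[0])
        base = generate_connectome(params, rng=base_rng)
        scan_seeds = sseq.spawn(n_scans)
        for t, tseq in enumerate(scan_seeds, start=1):
            A = perturb_scan(
                base.adjacency,
                params.scan_noise,
                np.random.default_rng(tseq),
                params.weight_mu,
                params.weight_sigma,
            )
            cohort.append(
                Connectome(
                    region_ids=list(base.region_ids),
                    adjacency=A,
                    subject=f"sub-{s:02d}",
                    scan=f"scan-{t:02d}",
                )
            )
    return cohort


def generate_system_labels(n_regions: int, seed: int = 0) -> SystemLabels:
    """Random assignment of every region to one of the eight systems.

    All eight systems are guaranteed non-empty (requires n_regions >= 8).
    """
    k = len(COGNITIVE_SYSTEMS)
    if n_regions < k:
        raise ValueError(f"need at least {k} regions to cover all systems")
    rng = np.random.default_rng(seed)
    assign = rng.integers(0, k, size=n_regions)
    # guarantee coverage: seed one region per system at random positions
    pos = rng.permutation(n_regions)[:k]
    assign[pos] = np.arange(k)
    names = region_names(n_regions)
    return SystemLabels(
        labels={names[i]: COGNITIVE_SYSTEMS[assign[i]] for i in range(n_regions)}
    )


def with_seed(params: GeneratorParams, seed: int) -> GeneratorParams:
    return replace(params, seed=seed)
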