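# Methods

## Model and assumptions

The package analyses weighted, undirected, zero-diagonal adjacency
matrices A whose entries count white-matter streamlines between
parcellated brain regions. Dynamics are the simplest construct that links
structure to controllability: a noise-free, discrete-time, linear
time-invariant system x(t+1) = A_s x(t) + B_K u(t). The linearization is a
deliberate modelling choice — linear models predict a substantial share of
slow, fMRI-scale covariance — and every conclusion the diagnostics support
is conditional on it. Control sets are evaluated one region at a time
(B = e_i); multi-node control sets are accepted by the Gramian solver but
no minimum-energy input design is provided.

## Stabilization

Two schemes are implemented.

* `spectral` (default): A_s = A / (c·(1 + λ_max(A))), c = 1. For
  nonnegative symmetric A this always yields spectral radius ρ < 1, which
  the infinite-horizon Gramian requires.
* `mean_edge_weight`: A_s = A / mean(nonzero off-diagonal weights). This
  is the normalization stated with the model, kept for fidelity, but it
  does not bound ρ: the single-edge graph maps to weight exactly 1
  (ρ = 1), and denser matrices can land on either side. Operations that
  need stability call `require_stable()` and hard-error when ρ ≥ 1.

The "mean edge weight" is taken over nonzero off-diagonal entries, not
over all N(N−1) cells; the alternative would only rescale by a constant
factor. Note that the spectral scheme is *not* exactly invariant to
rescaling A (the +1 in the denominator): stabilize(αA) is proportional,
not equal, to stabilize(A). Rank-based downstream analyses are unaffected
by the proportionality constant.

## Gramian computation

The primary path solves the discrete Lyapunov fixed point
W = A_s W A_sᵀ + B Bᵀ with `scipy.linalg.solve_discrete_lyapunov`; the
truncated defining series (terms accumulated until the term norm falls
below 1e-14, horizon bounded by log(tol)/2·log(ρ)) is retained as an
independent cross-check, and diag((I − A_s²)⁻¹) and 1 − Σ_j a_ij² serve
as closed-form oracles for Trace(W_i) and φ_i respectively on symmetric
systems. W is symmetrized as (W + Wᵀ)/2 before any eigenvalue is taken.

Average controllability is Trace(W_i), not Trace(W_i⁻¹): W_i is extremely
ill-conditioned on realistic networks, so the inverse is numerically
meaningless while the trace is well-defined (it is the squared H₂ norm of
the impulse response).

Numerical tolerances: eigenvalues of W below −1e-10·max(1, λ_max(W)) raise
(the Gramian must be PSD); small negative values inside that band clamp to
0. λ_min below 1e-15 is reported as effectively singular — at study scale
*every* region-scan is in this regime, i.e. the system is theoretically
controllable from any single region but the energy bound is astronomically
poor, and the specific λ_min digits carry no information. A cautionary
exact fact: strict λ_min > 0 is not even a theorem for every connected
weighted graph (a 3-path controlled from its midpoint is exactly
uncontrollable for any weights, because an eigenvector vanishes there);
it holds generically for the dense-ish random structures analysed here.

Modal controllability φ_i = Σ_j (1 − λ_j²) v_ij² is computed from the
eigendecomposition of the *stabilized* matrix. Eigenvector sign and
ordering ambiguities are irrelevant because only squares enter.

## Boundary controllability

The recursion needs a community partition that is robust to the
stochasticity of modularity maximization. `robust_partition` runs
`n_runs = 100` seeded Leiden optimizations (modularity at resolution 1 by
default), forms the pairwise co-assignment matrix, thresholds it at the
95th percentile of a label-permutation null (each run's membership vector
permuted across nodes), and reclusters the surviving association graph
once. All three knobs (runs, resolution, consensus quantile) are exposed.

First-level boundary nodes — any node with a positive-weight edge into
another community; this is the minimal reading of "lying at the boundary",
chosen over participation-coefficient thresholds — receive the value 1.
Each community is then recursively split by the sign pattern of the
Fiedler eigenvector of its weighted Laplacian L = D − A (zero entries to
the positive side; disconnected subnetworks split into first component vs
rest; near-degenerate Fiedler pairs resolved by a seeded symmetric 1e-9
perturbation). Nodes newly exposed on a split at depth d receive
(N − cumulative previously assigned)/N, which reduces to the stated
(N − N₁)/N at depth 2; subnetworks of ≤ 2 nodes absorb their unassigned
members at the current depth's value. Processing is breadth-first, so the
value depends only on depth; ordering communities by mean average
controllability ("least controllable first") is available behind a flag
and changes only the sequencing of assignments. Values therefore lie in
(0, 1] and weakly decrease with depth; an edgeless network has no
first-level boundary nodes and every node receives the terminal value at
depth 2.

Determinism: all stochastic components (Leiden runs, permutation null,
degeneracy perturbation) derive from one seed. Relabelling regions
permutes outputs identically whenever the consensus partition itself is
stable under the relabelling (seeded community detection interacts with
node order, so exact equivariance on arbitrary graphs is not guaranteed;
it is exercised on the two-triangle fixture).

## Cohort aggregation

Within each scan the diagnostic values are ranked ascending (ties receive
mean ranks); ranks are averaged over all scans and subjects. Hubs are the
top-k = 30 regions of the aggregated ranking, ties at the boundary broken
lexicographically by region id. System enrichment divides each system's
raw hub fraction by its size n_c and rescales the scores to sum to 100
(both the raw percentage and the rescaled share are emitted, since either
normalization may be wanted). Degree correlations are Pearson r of mean
controllability rank vs mean weighted-degree rank; raw-value correlations
are emitted alongside. Weighted degree defaults to node strength Σ_j a_ij;
the mean-of-existing-edges variant is available and identical in rank
terms up to per-node edge counts.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes and
nothing else — no geometry, tractography bias, or imaging physics. It is a
weighted stochastic block model: balanced communities, within/between edge
probabilities, rounded log-normal weights (minimum 1 on existing edges,
emulating integer streamline counts), designated hub regions given extra
cross-community edges and a multiplicative weight boost, and per-scan
perturbation of a per-subject base network.

Defaults (the study conditions): 234 regions, 8 communities, 8 subjects ×
3 scans. `p_within = 0.35`, `p_between = 0.005` give ~5% edge density with
genuine community interiors — if between-community connectivity is much
denser, every node touches another community and boundary controllability
degenerates to a constant, which is both unrealistic (structural
connectomes are strongly modular) and uninformative. `weight_mu = 3`,
`weight_sigma = 1` give a heavy-tailed weight distribution with median
~20 streamlines. 16 hubs with `hub_boost = 3` and ~8 extra cross-community
partners each make hubs simultaneously high-strength and
boundary-adjacent, as empirically observed. No density or weight summary
was published for the original matrices, so these are conventions, not
calibrations.

Scan-to-scan noise multiplies each weight by exp(σZ), Z ~ N(0,1), with
σ = scan_noise·√π/2 so that the expected relative difference between two
independently perturbed scans, E|e^{σZ₁} − e^{σZ₂}|/mean ≈ (2/√π)·σ,
equals `scan_noise` (default 0.1) to first order; a fraction 0.02·scan_noise
of edges is deleted and an equal expected number appears, keeping matrices
symmetric and integer after rounding.

What passing tests on this generator do and do not show: the sign
structure of the degree-controllability correlations (positive for
average, strongly negative for modal, weak for boundary) is a property of
modular hub-rich topology and is reproduced; the *numerical* correlation
values, hub identities and system percentages of any real cohort depend on
data the generator does not model and are not claimed.

## Problem sizes and cost

One scan at N = 234 costs 234 discrete Lyapunov solves plus one
eigendecomposition and one consensus partition (~10 s single-threaded);
the full 24-scan cohort runs in a few minutes. The acceptance script uses
20-network ensembles at N = 60, where the same analytic bounds hold and
each ensemble completes in seconds. The end-to-end determinism check runs
at N = 60 with 2 subjects × 2 scans; determinism is scale-independent.

## Known limitations

* Undirected networks only; directed extensions change both the Gramian
  and the community structure.
* Single-node control diagnostics; no input design or trajectory planning.
* λ_min at realistic scales is below double precision; treat global
  controllability as a flag ("theoretically controllable, practically
  not"), never as a comparable magnitude.
* The consensus partition concretizes an under-specified "robust
  partition" procedure; with very weak community structure its output (and
  hence boundary values) is sensitive to the resolution and threshold
  choices.
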