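# netctrl — network controllability of structural brain networks

`netctrl` asks, of a weighted structural connectome, *which brain regions
are best placed to steer large-scale neural dynamics* — and answers with
the standard diagnostics of linear network control theory. It is written
for network neuroscientists who have a region-by-region streamline-count
matrix (or want a realistic synthetic one) and need per-region
controllability values, cohort-level control hubs, and their distribution
over cognitive systems.

## The model

Activity is modelled as a noise-free, discrete-time, linear time-invariant
system on the stabilized connectome A_s:

```
x(t+1) = A_s x(t) + B_K u(t)
```

where x(t) is the vector of regional activity magnitudes, B_K = [e_i : i ∈ K]
selects the control regions, and A_s = A / (c·(1 + λ_max(A))) with c = 1 by
default, which guarantees spectral radius ρ < 1 for any nonnegative
symmetric A (normalization by the mean edge weight is also available, but
does not guarantee stability and is rejected by Gramian operations when
ρ ≥ 1).

For a single control region i, the infinite-horizon controllability Gramian

```
W_i = Σ_{τ≥0} A_s^τ e_i e_iᵀ (A_sᵀ)^τ ,   i.e.   W_i = A_s W_i A_sᵀ + e_i e_iᵀ
```

is solved as a discrete Lyapunov equation. The per-region diagnostics are

| diagnostic | definition | reading |
|---|---|---|
| global | λ_min(W_i) | > 0 ⇔ theoretically controllable from i; near-zero ⇒ practically hard |
| average | Trace(W_i) | energy of the impulse response; ease of reaching many nearby states |
| modal | φ_i = Σ_j (1 − λ_j²(A_s)) v_ij² | ability to excite all modes, i.e. to reach difficult states |
| boundary | hierarchical value in (0, 1] | position at interfaces between network communities |

Boundary controllability assigns 1 to every node of a robust consensus
partition that has a cross-community edge (N₁ nodes), then recursively
bipartitions each community by its Laplacian Fiedler eigenvector, giving
newly exposed interface nodes the value (N − previously assigned)/N at each
depth until all nodes carry a value.

Cohort aggregation ranks each diagnostic within every scan, averages the
ranks across scans and subjects, takes the top-30 regions per diagnostic as
control hubs, and reports each cognitive system's hub share normalized by
system size.

## Worked example

```python
import numpy as np, netctrl as nc

conn = nc.Connectome(["a", "b"], np.array([[0.0, 6.0], [6.0, 0.0]]))
sys = nc.stabilize(conn)              # A_s = A/7, rho = 6/7
print(nc.average_controllability(sys))  # [3.76923077 3.76923077]
print(nc.modal_controllability(sys))    # [0.26530612 0.26530612]
print(nc.global_controllability(sys, 0))  # 1.5963800904977368
```

At study scale, the numbered drivers under `analysis/` reproduce the full
cohort workflow on synthetic data (8 subjects × 3 scans, 234 regions,
seeded). Running them in order prints, among other things:

```
$ python analysis/01_generate_cohort.py
cohort: 24 scans of 234 regions (seed 1)
edge density: 0.051 (range 0.047-0.053)

$ python analysis/02_control_profiles.py      # ~4-6 min
profiled 24 scans in 371 s
global controllability below 1e-15 (machine-precision floor): 5616/5616 region-scans

$ python analysis/03_cohort_analysis.py
   diagnostic       r         p
     avg_ctrl  0.8761  1.89e-75
   modal_ctrl -0.9773 2.62e-158
boundary_ctrl  0.3147 8.908e-07
```

The correlations are of mean controllability rank against mean weighted-
degree rank over the 24 scans: average controllability concentrates on
high-strength hubs (r = 0.88), modal controllability on weakly connected
regions (r = −0.98), and boundary controllability is only weakly tied to
strength (r = 0.31) — the characteristic sign structure of these
diagnostics on modular, hub-rich networks. The global-controllability
line reports that every smallest Gramian eigenvalue lies below the
double-precision floor: single-region control is theoretically possible
but practically negligible, and the numerical value of λ_min is not
meaningful beyond "tiny".

A thin CLI wraps the same stages
(`netctrl gen-data | controllability | boundary | cohort | run-all`).

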