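"""Generate the synthetic study cohort: 8 subjects x 3 scans, 234 regions.

Draws the default modular, hub-rich, integer-weighted networks plus the
region -> cognitive-system label table, writes the connectomes as edge-list
TSVs under scratch/cohort/ (inputs for 02) and the labels under results/,
and prints the basic structural statistics of what was generated.

Run from the repository root:  python analysis/01_generate_cohort.py
"""

from pathlib import Path

import numpy as np

import netctrl as nc

SEED = 1
ROOT = Path(__file__).resolve().parents[1]

params = nc.GeneratorParams(seed=SEED)
cohort = nc.generate_cohort(params, n_subjects=8, n_scans=3)
labels = nc.generate_system_labels(params.n_regions, seed=SEED)

outdir = ROOT / "scratch" / "cohort"
outdir.mkdir(parents=True, exist_ok=True)
for conn in cohort:
    nc.write_connectome(conn, outdir / f"{conn.subject}_{conn.scan}.tsv", seed=SEED)
nc.write_labels(labels, ROOT / "results" / "labels.tsv", seed=SEED)

dens = [float((c.adjacency > 0).mean()) for c in cohort]
strength = np.concatenate([c.adjacency.sum(axis=1) for c in cohort])
print(f"cohort: {len(cohort)} scans of {params.n_regions} regions (seed {SEED})")
print(f"edge density: {np.mean(dens):.3f} (range {min(dens):.3f}-{max(dens):.3f})")
print(f"node strength: median {np.median(strength):.0f}, max {strength.max():.0f}")
print(f"system sizes: {dict(sorted(labels.sizes.items()))}")
print(f"wrote {len(cohort)} edge lists to {outdir}")
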