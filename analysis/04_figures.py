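"""Scatter and bar figures for the cohort results.

Renders (a) degree-rank vs controllability-rank scatters for the three
diagnostics and (b) the size-normalized system enrichment bars, from the
tables produced by 03.  PNGs are written under scratch/figures/.

Run after 03:  python analysis/04_figures.py
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"
FIG = ROOT / "scratch" / "figures"
FIG.mkdir(parents=True, exist_ok=True)

mean_ranks = pd.read_csv(RES / "mean_ranks.tsv", sep="\t", comment="#")
corr = pd.read_csv(RES / "correlations.tsv", sep="\t", comment="#").set_index(
    "diagnostic"
)
enrich = pd.read_csv(RES / "enrichment.tsv", sep="\t", comment="#")

fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharex=True)
titles = {
    "avg_ctrl": "average controllability",
    "modal_ctrl": "modal controllability",
    "boundary_ctrl": "boundary controllability",
}
for ax, diag in zip(axes, titles):
    ax.scatter(mean_ranks["degree"], mean_ranks[diag], s=8, alpha=0.6)
    ax.set_xlabel("weighted degree (mean rank)")
    ax.set_ylabel(f"{titles[diag]} (mean rank)")
    ax.set_title(f"r = {corr.loc[diag, 'r']:.2f}")
fig.tight_layout()
fig.savefig(FIG / "degree_vs_controllability.png", dpi=150)

fig, axes = plt.subplots(1, 3, figsize=(13, 3.8), sharey=True)
for ax, diag in zip(axes, titles):
    sub = enrich[enrich["diagnostic"] == diag].sort_values("system")
    ax.bar(range(len(sub)), sub["normalized_percent"])
    ax.set_xticks(range(len(sub)))
    ax.set_xticklabels(sub["system"], rotation=60, ha="right", fontsize=7)
    ax.set_title(titles[diag])
axes[0].set_ylabel("size-normalized hub share (%)")
fig.tight_layout()
fig.savefig(FIG / "system_enrichment.png", dpi=150)
print(f"figures written to {FIG}")
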