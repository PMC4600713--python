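"""Aggregate profiles across the cohort: hubs, enrichment, correlations.

Ranks each diagnostic within every scan, averages ranks over the 24 scans,
extracts the top-30 control hubs per diagnostic, computes size-normalized
cognitive-system enrichment, per-group hub means, and the rank correlation
of each diagnostic with weighted degree.  Tables land in results/.

Run after 02:  python analysis/03_cohort_analysis.py
"""

from pathlib import Path

import netctrl as nc

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"

profiles = nc.read_profiles(ROOT / "scratch" / "profiles.tsv")
labels = nc.read_labels(RES / "labels.tsv")
res = nc.analyze_cohort(profiles, labels, k=30)

res.mean_ranks.to_csv(RES / "mean_ranks.tsv", sep="\t", float_format="%.10g")
res.enrichment.to_csv(RES / "enrichment.tsv", sep="\t", index=False,
                      float_format="%.10g")
res.hub_means.to_csv(RES / "hub_means.tsv", sep="\t", index=False,
                     float_format="%.10g")
res.correlations.to_csv(RES / "correlations.tsv", sep="\t", index=False,
                        float_format="%.10g")
import pandas as pd

hub_df = pd.DataFrame(
    [{"diagnostic": d, "rank": i + 1, "region_id": r}
     for d, regions in res.hubs.items() for i, r in enumerate(regions)]
)
hub_df.to_csv(RES / "hubs.tsv", sep="\t", index=False)

print("rank correlation with weighted degree (mean ranks over 24 scans):")
print(res.correlations.to_string(index=False, float_format="%.4g"))
print("\ntop-3 size-normalized system shares per diagnostic:")
for diag, grp in res.enrichment.groupby("diagnostic"):
    top = grp.nlargest(3, "normalized_percent")
    row = ", ".join(
        f"{r.system} {r.normalized_percent:.1f}%" for r in top.itertuples()
    )
    print(f"  {diag}: {row}")
print(f"\ntables written to {RES}")
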