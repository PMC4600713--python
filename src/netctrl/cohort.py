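"""Cross-subject aggregation: mean ranks, control hubs, system enrichment.

Controllability values are compared across subjects on the rank scale:
within each scan the per-region values are ranked (ascending, ties
averaged) and the ranks are averaged over all scans and subjects.  Control
hubs are the top-k regions (default k=30) of the aggregated ranking; their
distribution over the eight cognitive systems is size-normalized so large
systems have no mechanical advantage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .generator import SystemLabels

__all__ = [
    "DIAGNOSTICS",
    "SYSTEM_GROUPS",
    "CohortResult",
    "rank_regions",
    "aggregate_ranks",
    "select_control_hubs",
    "system_enrichment",
    "system_hub_means",
    "degree_correlation",
    "analyze_cohort",
]

#: the three regional controllability diagnostics used for hub analysis
DIAGNOSTICS = ("avg_ctrl", "modal_ctrl", "boundary_ctrl")

#: hypothesis-driven groupings of the eight cognitive systems
SYSTEM_GROUPS = {
    "default mode": ("default mode",),
    "cognitive control": ("frontoparietal", "cingulo-opercular"),
    "attention": ("ventral attention", "dorsal attention"),
}


@dataclass
class CohortResult:
    mean_ranks: pd.DataFrame  # region_id x diagnostic mean rank
    hubs: dict[str, list[str]]  # diagnostic -> top-k region ids
    enrichment: pd.DataFrame  # diagnostic, system, counts + percentages
    hub_means: pd.DataFrame  # group, diagnostic, mean, sd over subjects
    correlations: pd.DataFrame  # diagnostic, r, p (ranked), r_raw, p_raw
    k: int = 30


def rank_regions(values) -> np.ndarray:
    """Ascending ranks 1..N; ties get the mean of their rank range."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot rank non-finite values")
    return stats.rankdata(values, method="average")


def aggregate_ranks(per_scan_ranks) -> np.ndarray:
    """Elementwise mean rank over all scans and subjects."""
    mats = [np.asarray(r, dtype=float) for r in per_scan_ranks]
    if not mats:
        raise ValueError("no rank vectors to aggregate")
    lengths = {m.shape for m in mats}
    if len(lengths) != 1:
        raise ValueError(f"rank vectors have differing shapes: {lengths}")
    return np.mean(mats, axis=0)


def select_control_hubs(agg_values: pd.Series, k: int = 30) -> list[str]:
    """Top-k regions by aggregated value, descending.

    Ties at the boundary are broken by region-id lexicographic order so
    the hub set is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(agg_values)
    if k > n:
        warnings.warn(f"k={k} exceeds {n} regions; returning all regions")
        k = n
    order = sorted(agg_values.items(), key=lambda kv: (-kv[1], kv[0]))
    return [rid for rid, _ in order[:k]]


def system_enrichment(hubs: list[str], labels: SystemLabels) -> pd.DataFrame:
    """Size-normalized share of hubs per cognitive system.

    raw percentage = 100 * (hubs in system) / k; the size-normalized score
    divides the raw fraction by the system size n_c and is rescaled to sum
    to 100 across systems so diagnostics are directly comparable.
    """
    k = len(hubs)
    if k == 0:
        raise ValueError("empty hub set")
    sizes = labels.sizes
    missing = [h for h in hubs if h not in labels.labels]
    if missing:
        raise KeyError(f"hub regions without system label: {missing[:5]}")
    counts = {s: 0 for s in sizes}
    for h in hubs:
        counts[labels.labels[h]] += 1
    rows = []
    scores = {s: (counts[s] / k) / sizes[s] for s in sizes}
    total = sum(scores.values())
    for s in sorted(sizes):
        rows.append(
            {
                "system": s,
                "n_regions": sizes[s],
                "n_hubs": counts[s],
                "raw_percent": 100.0 * counts[s] / k,
                "size_normalized_score": scores[s],
                "normalized_percent": 100.0 * scores[s] / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def system_hub_means(
    profiles: pd.DataFrame,
    hubs_per_diagnostic: dict[str, list[str]],
    labels: SystemLabels,
    groups: dict[str, tuple] = SYSTEM_GROUPS,
) -> pd.DataFrame:
    """Mean aggregated rank of each group's hubs, per diagnostic.

    Per-subject means (ranks averaged over that subject's scans, then over
    the group's hub members) provide the dispersion: ``sd`` is the s.d. of
    the subject means.  Empty groups are omitted with a warning.
    """
    ranked = _per_scan_ranks(profiles)
    rows = []
    for gname, members in groups.items():
        for diag in DIAGNOSTICS:
            hub_set = [
                h for h in hubs_per_diagnostic.get(diag, ())
                if labels.labels.get(h) in members
            ]
            if not hub_set:
                warnings.warn(f"no {diag} hubs in group '{gname}'")
                continue
            per_subj = (
                ranked[ranked["region_id"].isin(hub_set)]
                .groupby("subject")[f"rank_{diag}"]
                .mean()
            )
            rows.append(
                {
                    "group": gname,
                    "diagnostic": diag,
                    "n_hubs": len(hub_set),
                    "mean_rank": float(per_subj.mean()),
                    "sd_over_subjects": float(per_subj.std(ddof=1))
                    if len(per_subj) > 1
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)


def degree_correlation(
    ctrl_values, degree_values, ranked: bool = True
) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) of controllability vs strength.

    By default both vectors are ranked first, matching how the scatter
    relationships are reported; pass ``ranked=False`` for raw values.
    """
    x = np.asarray(ctrl_values, dtype=float)
    y = np.asarray(degree_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if ranked:
        x, y = rank_regions(x), rank_regions(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _per_scan_ranks(profiles: pd.DataFrame) -> pd.DataFrame:
    """Rank each diagnostic (and degree) within every subject x scan."""
    cols = list(DIAGNOSTICS) + ["degree"]
    out = profiles.copy()
    for col in cols:
        out[f"rank_{col}"] = out.groupby(["subject", "scan"])[col].transform(
            rank_regions
        )
    return out


def analyze_cohort(
    profiles: pd.DataFrame, labels: SystemLabels, k: int = 30
) -> CohortResult:
    """Full cross-subject analysis from a tidy per-scan profile table.

    ``profiles`` has one row per region x subject x scan with columns
    region_id, subject, scan, avg_ctrl, modal_ctrl, boundary_ctrl,
    global_ctrl, degree.
    """
    ranked = _per_scan_ranks(profiles)
    mean_ranks = (
        ranked.groupby("region_id")[
            [f"rank_{c}" for c in DIAGNOSTICS] + ["rank_degree"]
        ]
        .mean()
        .rename(columns=lambda c: c.removeprefix("rank_"))
        .sort_index()
    )

    hubs = {
        diag: select_control_hubs(mean_ranks[diag], k=k) for diag in DIAGNOSTICS
    }
    enrich = pd.concat(
        [
            system_enrichment(hubs[diag], labels).assign(diagnostic=diag)
            for diag in DIAGNOSTICS
        ],
        ignore_index=True,
    )
    hub_means = system_hub_means(profiles, hubs, labels)

    rows = []
    for diag in DIAGNOSTICS:
        r, p = degree_correlation(mean_ranks[diag], mean_ranks["degree"], ranked=False)
        raw = profiles.groupby("region_id")[[diag, "degree"]].mean().sort_index()
        r_raw, p_raw = degree_correlation(raw[diag], raw["degree"], ranked=False)
        rows.append(
            {"diagnostic": diag, "r": r, "p": p, "r_raw": r_raw, "p_raw": p_raw}
        )
    correlations = pd.DataFrame(rows)
    return CohortResult(
        mean_ranks=mean_ranks,
        hubs=hubs,
        enrichment=enrich,
        hub_means=hub_means,
        correlations=correlations,
        k=k,
    )
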