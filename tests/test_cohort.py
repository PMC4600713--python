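"""Rank aggregation, hub selection, system enrichment, degree correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netctrl import (
    SystemLabels,
    aggregate_ranks,
    analyze_cohort,
    degree_correlation,
    rank_regions,
    select_control_hubs,
    system_enrichment,
    system_hub_means,
)


class TestRankRegions:
    def test_simple_ordering(self):
        assert np.allclose(rank_regions([0.2, 0.5, 0.4]), [1, 3, 2])

    def test_ties_get_mean_rank(self):
        assert np.allclose(rank_regions([0.3, 0.3]), [1.5, 1.5])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_matches_sort_based_oracle_on_distinct_values(self, values):
        ranks = rank_regions(values)
        order = np.argsort(values)
        oracle = np.empty(len(values))
        oracle[order] = np.arange(1, len(values) + 1)
        assert np.allclose(ranks, oracle)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            rank_regions([1.0, np.nan])


class TestAggregateRanks:
    def test_single_scan_identity(self):
        assert np.allclose(aggregate_ranks([[1, 3, 2]]), [1, 3, 2])

    def test_two_scans_elementwise_mean(self):
        assert np.allclose(aggregate_ranks([[1, 3, 2], [2, 3, 1]]), [1.5, 3, 1.5])

    def test_idempotent_on_identical_scans(self):
        v = np.array([4.0, 1.0, 2.0])
        assert np.allclose(aggregate_ranks([v] * 24), v)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_ranks([])


class TestSelectControlHubs:
    def test_top_k_descending(self):
        s = pd.Series({"r1": 0.9, "r2": 0.1, "r3": 0.8})
        assert select_control_hubs(s, k=2) == ["r1", "r3"]

    def test_k_equals_n_returns_all(self):
        s = pd.Series({"a": 1.0, "b": 2.0})
        assert set(select_control_hubs(s, k=2)) == {"a", "b"}

    def test_k_too_large_warns_and_returns_all(self):
        s = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.warns(UserWarning):
            hubs = select_control_hubs(s, k=5)
        assert set(hubs) == {"a", "b"}

    def test_boundary_ties_broken_lexicographically(self):
        s = pd.Series({"z": 1.0, "a": 1.0, "m": 2.0})
        assert select_control_hubs(s, k=2) == ["m", "a"]


class TestSystemEnrichment:
    @pytest.fixture
    def labels_2sys(self):
        lab = {"a": "S1", "b": "S1", "c": "S2"}
        lab.update({f"x{i}": "S2" for i in range(3)})  # S1 size 2, S2 size 4
        return SystemLabels(labels=lab)

    def test_hand_computed_example(self, labels_2sys):
        """hubs {a,b,c}: S1 score (2/3)/2 = 1/3, S2 score (1/3)/4 = 1/12,
        renormalized 80% / 20%."""
        df = system_enrichment(["a", "b", "c"], labels_2sys).set_index("system")
        assert df.loc["S1", "normalized_percent"] == pytest.approx(80.0)
        assert df.loc["S2", "normalized_percent"] == pytest.approx(20.0)

    def test_single_system_takes_all(self, labels_2sys):
        df = system_enrichment(["a", "b"], labels_2sys).set_index("system")
        assert df.loc["S1", "normalized_percent"] == pytest.approx(100.0)
        assert df.loc["S2", "normalized_percent"] == 0.0

    def test_percentages_sum_to_100(self, labels_2sys):
        df = system_enrichment(["a", "c", "x0"], labels_2sys)
        assert df["normalized_percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_hubs_proportional_to_sizes_give_equal_shares(self):
        lab = {f"a{i}": "S1" for i in range(2)}
        lab.update({f"b{i}": "S2" for i in range(4)})
        labels = SystemLabels(labels=lab)
        df = system_enrichment(["a0", "b0", "b1"], labels)  # 1:2 like sizes 2:4
        assert df["normalized_percent"].nunique() == 1

    def test_unlabelled_hub_rejected(self, labels_2sys):
        with pytest.raises(KeyError):
            system_enrichment(["a", "nope"], labels_2sys)


def _toy_profiles():
    rng = np.random.default_rng(0)
    rows = []
    regions = [f"r{i}" for i in range(6)]
    for subj in ("s1", "s2"):
        for scan in ("t1", "t2"):
            for i, r in enumerate(regions):
                rows.append(
                    {
                        "region_id": r,
                        "subject": subj,
                        "scan": scan,
                        "avg_ctrl": i + rng.normal(0, 0.1),
                        "modal_ctrl": -i + rng.normal(0, 0.1),
                        "boundary_ctrl": rng.random(),
                        "global_ctrl": 0.0,
                        "degree": i + rng.normal(0, 0.1),
                    }
                )
    return pd.DataFrame(rows), regions


class TestSystemHubMeans:
    def test_group_means_match_brute_force(self):
        prof, regions = _toy_profiles()
        labels = SystemLabels(
            labels={r: ("default mode" if i < 3 else "frontoparietal")
                    for i, r in enumerate(regions)}
        )
        hubs = {"avg_ctrl": regions[:4], "modal_ctrl": regions[2:],
                "boundary_ctrl": regions}
        table = system_hub_means(prof, hubs, labels)
        row = table[(table["group"] == "default mode")
                    & (table["diagnostic"] == "avg_ctrl")].iloc[0]
        # brute force: rank within each scan, subject means over hub members
        from netctrl.cohort import _per_scan_ranks

        ranked = _per_scan_ranks(prof)
        members = [r for r in hubs["avg_ctrl"] if labels.labels[r] == "default mode"]
        per_subj = (
            ranked[ranked.region_id.isin(members)].groupby("subject")["rank_avg_ctrl"].mean()
        )
        assert row["mean_rank"] == pytest.approx(per_subj.mean())
        assert row["sd_over_subjects"] == pytest.approx(per_subj.std(ddof=1))

    def test_single_hub_mean_is_its_value(self):
        prof, regions = _toy_profiles()
        labels = SystemLabels(labels={r: "default mode" for r in regions})
        hubs = {"avg_ctrl": [regions[0]], "modal_ctrl": [regions[0]],
                "boundary_ctrl": [regions[0]]}
        with pytest.warns(UserWarning):  # other groups are empty
            table = system_hub_means(prof, hubs, labels)
        from netctrl.cohort import _per_scan_ranks

        ranked = _per_scan_ranks(prof)
        expect = (
            ranked[ranked.region_id == regions[0]]
            .groupby("subject")["rank_avg_ctrl"].mean().mean()
        )
        row = table[(table["group"] == "default mode")
                    & (table["diagnostic"] == "avg_ctrl")].iloc[0]
        assert row["mean_rank"] == pytest.approx(expect)


class TestDegreeCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = degree_correlation(2 * x + 1, x, ranked=False)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, _ = degree_correlation(-x, x, ranked=False)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.2, 3.4, 2.2, 5.1, 4.4, 0.3, 2.9, 3.3, 1.1, 4.0])
        y = np.array([0.5, 2.1, 1.9, 4.2, 5.0, 0.1, 3.3, 2.2, 0.9, 3.8])
        r, _ = degree_correlation(x, y, ranked=False)
        xm, ym = x - x.mean(), y - y.mean()
        manual = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert r == pytest.approx(manual, abs=1e-12)

    def test_ranked_mode_is_spearman(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        x, y = rng.random(20), rng.random(20)
        r, _ = degree_correlation(x, y, ranked=True)
        assert r == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            degree_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], ranked=False)


class TestAnalyzeCohort:
    def test_end_to_end_structure(self):
        prof, regions = _toy_profiles()
        labels = SystemLabels(
            labels={
                r: ("default mode" if i % 2 else "dorsal attention")
                for i, r in enumerate(regions)
            }
        )
        res = analyze_cohort(prof, labels, k=3)
        assert len(res.mean_ranks) == 6
        assert all(len(h) == 3 for h in res.hubs.values())
        sums = res.enrichment.groupby("diagnostic")["normalized_percent"].sum()
        assert np.allclose(sums, 100.0)
        # avg_ctrl increases with degree by construction
        r_avg = res.correlations.set_index("diagnostic").loc["avg_ctrl", "r"]
        assert r_avg > 0.9
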