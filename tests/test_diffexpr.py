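"""Expression-change statistics, restoration ordering, distance groups."""

import numpy as np
import pandas as pd
import pytest

from prcmap import (
    SimulationConfig,
    distance_stratification,
    expression_changes,
    mann_whitney,
    nearest_positive_distance,
    restoration_histograms,
    simulate_chip_arrays,
    subset_statistics,
)
from oracles import brute_force_nearest, mann_whitney_exact_p

# hand-derived half-width of the 95% t-interval for {1,2,3}:
# t_{0.975, df=2} = sqrt(1.805/0.0975) from the closed-form df=2 t CDF,
# divided by sqrt(3) for the standard error with sd = 1
CI_HALF_123 = np.sqrt(1.805 / 0.0975 / 3.0)


def _expr(changes: dict, n_samples=1):
    genes = pd.Index(sorted(changes), name="gene_id")
    cols, data = [], []
    for i in range(n_samples):
        cols.append(f"before_{i}")
        data.append(np.zeros(len(genes)))
    for i in range(n_samples):
        cols.append(f"after_{i}")
        data.append(np.array([changes[g] for g in genes]))
    expr = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    groups = pd.Series(
        {c: ("before" if c.startswith("before") else "after") for c in cols}
    )
    return expr, groups


class TestExpressionChanges:
    def test_identical_groups_zero_change(self):
        expr, groups = _expr({"a": 0.0, "b": 0.0}, n_samples=3)
        out = expression_changes(expr, groups, "before", "after")
        assert (out["change"] == 0.0).all()

    def test_single_sample_groups_simple_difference(self):
        expr, groups = _expr({"a": 1.25, "b": -0.5})
        out = expression_changes(expr, groups, "before", "after")
        assert out.loc["a", "change"] == 1.25
        assert out.loc["b", "change"] == -0.5

    def test_empty_group_rejected(self):
        expr, groups = _expr({"a": 1.0})
        with pytest.raises(ValueError, match="non-empty"):
            expression_changes(expr, groups, "before", "missing")


class TestSubsetStatistics:
    def test_closed_form_t_interval(self):
        """Changes {1,2,3}: mean 2, SD 1, 95% CI 2 ± t_{0.975,2}/√3, against
        the hand-computed closed form, to 1e-9."""
        changes = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        classes = pd.Series({"a": "TP", "b": "TP", "c": "TP"})
        per_class, _ = subset_statistics(changes, classes)
        row = per_class.set_index("class").loc["TP"]
        assert row["mean_change"] == pytest.approx(2.0, abs=1e-12)
        assert row["sd"] == pytest.approx(1.0, abs=1e-12)
        assert row["ci_low"] == pytest.approx(2.0 - CI_HALF_123, abs=1e-9)
        assert row["ci_high"] == pytest.approx(2.0 + CI_HALF_123, abs=1e-9)

    def test_all_zero_changes_degenerate_not_significant(self):
        changes = pd.Series({"a": 0.0, "b": 0.0, "c": 0.0})
        classes = pd.Series({"a": "SP", "b": "SP", "c": "SP"})
        per_class, _ = subset_statistics(changes, classes)
        row = per_class.set_index("class").loc["SP"]
        assert row["mean_change"] == 0.0
        assert row["band_vs_zero"] != "significant"

    def test_identical_subsets_pairwise_p_one(self):
        changes = pd.Series(
            {"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0, "e": 2.0, "f": 3.0}
        )
        classes = pd.Series(
            {"a": "TP", "b": "TP", "c": "TP", "d": "DP", "e": "DP", "f": "DP"}
        )
        _, pairwise = subset_statistics(changes, classes)
        assert pairwise.iloc[0]["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_small_class_reports_without_pvalue(self):
        changes = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        classes = pd.Series({"a": "TP", "b": "TP", "c": "DP"})
        per_class, _ = subset_statistics(changes, classes)
        row = per_class.set_index("class").loc["DP"]
        assert row["n"] == 1
        assert np.isnan(row["p_vs_zero"])

    def test_reference_class_comparison_emitted(self):
        rng = np.random.default_rng(0)
        changes = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
        changes.iloc[:20] += 2.0
        classes = pd.Series(
            ["TP"] * 20 + ["none"] * 20, index=changes.index
        )
        per_class, _ = subset_statistics(changes, classes, reference_class="none")
        row = per_class.set_index("class").loc["TP"]
        assert row["p_vs_reference"] < 0.001


class TestRestoration:
    def test_histogram_counts_conserve_subset_sizes(self, rng):
        changes = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        positives = [f"g{i}" for i in range(30)]
        hist, means = restoration_histograms({"mock": changes}, positives, bins=10)
        sums = hist.groupby("status")["count"].sum()
        assert sums["positive"] == 30
        assert sums["negative"] == 70

    def test_planted_genotype_ordering_recovered(self, rng):
        """Planted effects mock +1.0, wild-type rescue +0.1, mutant rescue
        +0.6 on positive genes come back in the order WT < mutant < mock."""
        genes = [f"g{i}" for i in range(500)]
        positives = genes[:200]
        effects = {"mock": 1.0, "rescue_wt": 0.1, "rescue_mut": 0.6}
        changes = {}
        for genotype, eff in effects.items():
            vals = rng.normal(0, 0.3, size=500)
            vals[:200] += eff
            changes[genotype] = pd.Series(vals, index=genes)
        _, means = restoration_histograms(changes, positives)
        pos = means[means["status"] == "positive"].set_index("genotype")["mean_change"]
        assert pos["rescue_wt"] < pos["rescue_mut"] < pos["mock"]

    def test_negative_genes_centred_on_zero(self, rng):
        genes = [f"g{i}" for i in range(400)]
        changes = {"mock": pd.Series(rng.normal(0, 0.3, size=400), index=genes)}
        _, means = restoration_histograms(changes, genes[:100])
        neg = means[means["status"] == "negative"].iloc[0]
        assert abs(neg["mean_change"]) < 3 * neg["se"]


class TestMannWhitney:
    def test_textbook_separated_groups(self):
        """{1,2,3} vs {4,5,6}: U = 0, exact two-sided p = 0.1 — the value
        full enumeration of all C(6,3) assignments gives."""
        u, p, method = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert method == "exact"
        assert p == pytest.approx(0.1, abs=1e-12)
        u_o, p_o = mann_whitney_exact_p([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(p_o, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_path_agrees_with_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_x = int(rng.integers(2, 6))
        n_y = int(rng.integers(2, 11 - n_x))
        x = rng.permutation(np.arange(1.0, 11.0))[:n_x]
        y = rng.permutation(np.arange(11.0, 21.0))[:n_y]
        u, p, method = mann_whitney(x, y)
        assert method == "exact"
        _, p_o = mann_whitney_exact_p(x, y)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_tied_large_samples_use_corrected_normal(self, rng):
        x = rng.integers(0, 4, size=30).astype(float)
        y = rng.integers(1, 5, size=30).astype(float)
        _, p, method = mann_whitney(x, y)
        assert method == "asymptotic"
        assert 0.0 <= p <= 1.0


class TestDistances:
    def test_two_close_positives_share_distance_and_group(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "chrom": ["chr1", "chr1"],
                "tss": [10_000, 40_000],
                "strand": ["+", "+"],
            }
        )
        changes = pd.Series({"a": 0.5, "b": 0.7})
        per_gene, _ = distance_stratification(["a", "b"], genes, changes)
        per_gene = per_gene.set_index("gene_id")
        assert (per_gene["distance"] == 30_000).all()
        assert (per_gene["group"] == "<50000").all()

    def test_singleton_chromosome_missing_distance(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "chrom": ["chr1", "chr2", "chr2"],
                "tss": [5_000, 10_000, 400_000],
                "strand": ["+"] * 3,
            }
        )
        d = nearest_positive_distance(["a", "b", "c"], genes)
        assert np.isnan(d["a"])
        assert d["b"] == d["c"] == 390_000

    def test_matches_brute_force_on_simulated_chromosomes(self):
        cfg = SimulationConfig(n_genes=300, n_chromosomes=4, seed=21)
        _, genes, truth = simulate_chip_arrays(cfg)
        positives = truth.members["H2AK119u1"]
        d = nearest_positive_distance(positives, genes)
        sub = genes[genes["gene_id"].isin(positives)]
        for _, grp in sub.groupby("chrom"):
            expected = brute_force_nearest(list(grp["tss"]))
            for gid, exp in zip(grp["gene_id"], expected):
                if exp is None:
                    assert np.isnan(d[gid])
                else:
                    assert d[gid] == exp

    def test_exclusion_list_removes_genes(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "chrom": ["chr1"] * 3,
                "tss": [10_000, 40_000, 500_000],
                "strand": ["+"] * 3,
            }
        )
        changes = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3})
        per_gene, _ = distance_stratification(
            ["a", "b", "c"], genes, changes, exclude=["b"]
        )
        assert set(per_gene["gene_id"]) == {"a", "c"}
        assert (per_gene.set_index("gene_id")["distance"] == 490_000).all()

    def test_group_comparisons_use_mann_whitney(self, rng):
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(40)],
                "chrom": ["chr1"] * 40,
                # 20 genes packed at 30 kb spacing, then 20 at 300 kb spacing
                "tss": [30_000 * i for i in range(20)]
                + [1_000_000 + 300_000 * i for i in range(20)],
                "strand": ["+"] * 40,
            }
        )
        vals = np.concatenate([rng.normal(1.0, 0.1, 20), rng.normal(0.0, 0.1, 20)])
        changes = pd.Series(vals, index=genes["gene_id"].to_numpy())
        per_gene, comparisons = distance_stratification(
            list(genes["gene_id"]), genes, changes
        )
        assert len(comparisons) == 1
        row = comparisons.iloc[0]
        assert {row["group_a"], row["group_b"]} == {"<50000", ">=200000"}
        assert row["p_value"] < 0.001
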