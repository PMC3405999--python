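"""Chromatin classification, set-overlap probability, correlation, terms."""

import itertools

import numpy as np
import pandas as pd
import pytest

from prcmap import (
    classify_genes,
    occupancy_correlation,
    overlap_probability,
    term_enrichment,
)
from oracles import hypergeom_overlap_p, pearson_by_hand, term_two_sided_p

MARKS = ("H2AK119u1", "Ring1B", "H3K27me3")


class TestClassify:
    def test_layer_aliases(self):
        """A gene with all three marks is TP; H3K27me3 alone is SP; the marks
        two outer layers (Ring1B+H3K27me3) give DP."""
        universe = ["g1", "g2", "g3", "g4"]
        calls = {
            "H2AK119u1": {"g1"},
            "Ring1B": {"g1", "g2"},
            "H3K27me3": {"g1", "g2", "g3"},
        }
        table = classify_genes(calls, universe, marks=MARKS).set_index("gene_id")
        assert table.loc["g1", "alias"] == "TP"
        assert table.loc["g2", "alias"] == "DP"
        assert table.loc["g3", "alias"] == "SP"
        assert table.loc["g4", "class"] == "none"

    def test_empty_calls_all_negative(self):
        universe = ["a", "b"]
        table = classify_genes({m: set() for m in MARKS}, universe, marks=MARKS)
        assert (table["class"] == "none").all()

    def test_classes_partition_universe(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(200)]
        calls = {
            m: set(rng.choice(universe, size=k, replace=False))
            for m, k in zip(MARKS, (20, 60, 120))
        }
        table = classify_genes(calls, universe, marks=MARKS)
        assert len(table) == len(universe)
        assert table["gene_id"].is_unique
        assert table.groupby("class").size().sum() == len(universe)

    def test_call_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            classify_genes({"m": {"zz"}}, ["a", "b"], marks=("m",))


class TestOverlap:
    def test_full_overlap_small_universe_exact(self):
        """|A|=|B|=5 fully overlapping in a 10-gene universe: P = 1/252,
        the enumeration over all C(10,5) draws."""
        genes = [f"g{i}" for i in range(10)]
        a = set(genes[:5])
        r = overlap_probability(a, a, genes)
        assert r.observed == 5
        assert r.p_value == pytest.approx(1 / 252, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_on_random_small_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        genes = list(range(n))
        a = frozenset(rng.choice(genes, size=int(rng.integers(1, n)), replace=False))
        b = frozenset(rng.choice(genes, size=int(rng.integers(1, n)), replace=False))
        r = overlap_probability({str(x) for x in a}, {str(x) for x in b},
                                [str(g) for g in genes])
        assert r.p_value == pytest.approx(hypergeom_overlap_p(n, a, b), abs=1e-9)

    def test_zero_overlap_upper_tail_is_one(self):
        genes = [f"g{i}" for i in range(10)]
        r = overlap_probability(set(genes[:4]), set(genes[4:8]), genes)
        assert r.observed == 0
        assert r.p_value == 1.0

    def test_sets_equal_universe(self):
        genes = [f"g{i}" for i in range(6)]
        r = overlap_probability(genes, genes, genes)
        assert r.observed == 6
        assert r.p_value == 1.0

    def test_symmetry_in_a_and_b(self):
        genes = [f"g{i}" for i in range(12)]
        a, b = set(genes[:5]), set(genes[3:9])
        ab = overlap_probability(a, b, genes)
        ba = overlap_probability(b, a, genes)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-15)
        assert ab.observed == ba.observed

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_probability({"x"}, set(), ["a", "b"])


class TestCorrelation:
    def test_identity_gives_one(self):
        s = pd.Series([0.1, 0.5, 0.9, 1.3], index=list("abcd"))
        out = occupancy_correlation(s, s)
        assert out.loc[out["subset"] == "all", "r"].iloc[0] == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        """(0,0),(1,1),(2,4): r = 6/√39, checked against the textbook formula
        evaluated with explicit sums."""
        x = pd.Series([0.0, 1.0, 2.0], index=list("abc"))
        y = pd.Series([0.0, 1.0, 4.0], index=list("abc"))
        out = occupancy_correlation(x, y)
        r = out.loc[out["subset"] == "all", "r"].iloc[0]
        assert r == pytest.approx(pearson_by_hand([0, 1, 2], [0, 1, 4]), abs=1e-12)
        assert r == pytest.approx(6 / np.sqrt(39), abs=1e-12)

    def test_independent_scores_uncorrelated(self, rng):
        idx = [f"g{i}" for i in range(10_000)]
        x = pd.Series(rng.normal(size=10_000), index=idx)
        y = pd.Series(rng.normal(size=10_000), index=idx)
        out = occupancy_correlation(x, y)
        assert abs(out.loc[out["subset"] == "all", "r"].iloc[0]) < 0.05

    def test_flag_subsets_reported(self, rng):
        idx = [f"g{i}" for i in range(100)]
        x = pd.Series(rng.normal(size=100), index=idx)
        flags = pd.Series([i < 50 for i in range(100)], index=idx)
        out = occupancy_correlation(x, x + 0.1, flags=flags)
        assert set(out["subset"]) == {"all", "flagged", "unflagged"}
        assert (out["n"] == [100, 50, 50]).all()


class TestTermEnrichment:
    def _mapping(self, members):
        return pd.DataFrame({"gene_id": sorted(members), "term": "T"})

    def test_equal_rates_not_directional(self):
        """Term in 10% of the subset and 10% of the universe: direction none
        and p near 1."""
        universe = [f"g{i}" for i in range(100)]
        term_genes = universe[:10]
        subset = universe[:1] + universe[10:19]  # 1 of 10 carries the term
        out = term_enrichment({"s": subset}, self._mapping(term_genes), universe)
        row = out.iloc[0]
        assert row["direction"] == "none"
        assert row["p_value"] >= 0.99

    def test_over_representation_matches_enumeration(self):
        """Subset of 5 within a 20-gene universe, term in 8: doubled-tail
        two-sided p equals exhaustive enumeration over C(20,5) draws."""
        universe = [str(i) for i in range(20)]
        term_members = frozenset(str(i) for i in range(8))
        subset = frozenset(str(i) for i in range(5))  # all carry the term
        out = term_enrichment(
            {"s": subset}, self._mapping(term_members), universe
        )
        expected = term_two_sided_p(
            20, frozenset(range(8)), frozenset(range(5))
        )
        assert out.iloc[0]["direction"] == "over"
        assert out.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-9)

    def test_absent_term_flagged_under(self):
        universe = [f"g{i}" for i in range(40)]
        term_genes = universe[:20]  # 50% of universe
        subset = universe[20:30]  # none carry it
        out = term_enrichment({"s": subset}, self._mapping(term_genes), universe)
        assert out.iloc[0]["direction"] == "under"
        assert out.iloc[0]["p_value"] < 0.01

    def test_empty_subset_skipped(self):
        universe = ["a", "b"]
        out = term_enrichment({"s": []}, self._mapping(["a"]), universe)
        assert len(out) == 0

    def test_fdr_column_appended(self):
        universe = [f"g{i}" for i in range(30)]
        mapping = pd.DataFrame(
            {"gene_id": universe[:10] + universe[5:15], "term": ["A"] * 10 + ["B"] * 10}
        )
        out = term_enrichment({"s": universe[:5]}, mapping, universe, fdr=True)
        assert "q_value" in out.columns
        assert ((out["q_value"] >= out["p_value"] - 1e-12) & (out["q_value"] <= 1)).all()
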