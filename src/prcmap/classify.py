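"""Chromatin-state classification and gene-set statistics.

Combines per-mark target calls into the eight-way presence/absence
classification of the scored-gene universe. For the canonical mark order
(H2AK119u1, Ring1B, H3K27me3) three layers of the H3K27me3-positive genes
get aliases: TP (triple positive, all three marks), DP (double positive,
Ring1B and H3K27me3 only) and SP (single positive, H3K27me3 only). Also
provides the hypergeometric overlap probability between two gene sets,
Pearson occupancy correlation, and flat term over/under-representation
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapResult",
    "classify_genes",
    "overlap_probability",
    "occupancy_correlation",
    "term_enrichment",
]

CANONICAL_MARKS = ("H2AK119u1", "Ring1B", "H3K27me3")

ALIASES = {
    (True, True, True): "TP",
    (False, True, True): "DP",
    (False, False, True): "SP",
}


def classify_genes(
    calls: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    marks: tuple | None = None,
) -> pd.DataFrame:
    """Assign every universe gene its per-mark flags and class label.

    ``calls`` maps mark name to its positive gene set (each a subset of the
    universe). Returns one row per gene with boolean ``<mark>_pos`` columns,
    a ``class`` label (flag string such as ``+-+`` in mark order, or
    ``none``), and an ``alias`` column carrying TP/DP/SP where applicable.
    Classes are mutually exclusive and exhaustive over the universe.
    """
    universe = pd.Index(sorted(set(universe)), name="gene_id")
    marks = tuple(marks) if marks is not None else tuple(calls.keys())
    flag_cols = {}
    for mark in marks:
        s = set(calls[mark])
        extra = s - set(universe)
        if extra:
            raise ValueError(
                f"call set for {mark!r} contains genes outside the universe: "
                f"{sorted(extra)[:5]}"
            )
        flag_cols[f"{mark}_pos"] = universe.isin(s)
    out = pd.DataFrame(flag_cols, index=universe)
    flags = out.to_numpy()
    labels = np.where(
        flags.any(axis=1),
        ["".join("+" if f else "-" for f in row) for row in flags],
        "none",
    )
    out["class"] = labels
    if marks == CANONICAL_MARKS:
        alias_map = {
            "".join("+" if f else "-" for f in key): alias
            for key, alias in ALIASES.items()
        }
        out["alias"] = out["class"].map(alias_map).fillna("")
    else:
        out["alias"] = ""
    return out.reset_index()


@dataclass(frozen=True)
class OverlapResult:
    """Observed vs expected overlap of two gene sets and its tail probability."""

    n_universe: int
    n_a: int
    n_b: int
    observed: int
    expected: float
    p_value: float


def overlap_probability(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Upper-tail hypergeometric probability of the observed overlap.

    P(X >= observed) where X is the overlap when ``|A|`` genes are drawn
    without replacement from the universe against membership in ``B``.
    Symmetric in A and B.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    n, na, nb = len(universe), len(a), len(b)
    k = len(a & b)
    expected = na * nb / n if n else 0.0
    p = float(stats.hypergeom.sf(k - 1, n, nb, na))
    return OverlapResult(
        n_universe=n, n_a=na, n_b=nb, observed=k, expected=expected, p_value=min(p, 1.0)
    )


def occupancy_correlation(
    scores_x: pd.Series,
    scores_y: pd.Series,
    flags: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation of two gene-wise score vectors.

    Aligns on gene id and drops pairs with a missing value. With ``flags``
    (boolean per gene, e.g. called-positive status) the correlation is also
    reported within each flag subset. Returns rows (subset, n, r).
    """
    x, y = scores_x.align(scores_y, join="inner")
    mask = np.isfinite(x.to_numpy(dtype=float)) & np.isfinite(y.to_numpy(dtype=float))
    x, y = x[mask], y[mask]
    rows = [("all", len(x), _pearson(x, y))]
    if flags is not None:
        f = flags.reindex(x.index).fillna(False).astype(bool)
        for label, sub in ((True, "flagged"), (False, "unflagged")):
            xs, ys = x[f == label], y[f == label]
            rows.append((sub, len(xs), _pearson(xs, ys)))
    return pd.DataFrame(rows, columns=["subset", "n", "r"])


def _pearson(x: pd.Series, y: pd.Series) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def term_enrichment(
    subsets: Mapping[str, Iterable[str]],
    gene_terms: pd.DataFrame,
    universe: Iterable[str],
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-term over/under-representation of gene subsets vs the universe.

    ``gene_terms`` is a flat two-column (gene_id, term) mapping restricted
    to the universe. For every (term, subset): the percentage of subset
    genes carrying the term, the universe percentage, a two-sided p-value
    (doubled smaller hypergeometric tail, capped at 1) and a direction flag
    (``over`` / ``under`` / ``none``). Empty subsets are skipped. With
    ``fdr`` a Benjamini-Hochberg adjusted column is appended.
    """
    universe = set(universe)
    gt = gene_terms[gene_terms["gene_id"].isin(universe)]
    if len(gt) < len(gene_terms.drop_duplicates()):
        outside = set(gene_terms["gene_id"]) - universe
        if outside:
            raise ValueError(
                f"gene->term mapping names genes outside the universe: {sorted(outside)[:5]}"
            )
    n_universe = len(universe)
    term_members = {t: set(g["gene_id"]) for t, g in gt.groupby("term", sort=True)}
    rows = []
    for subset_name in sorted(subsets):
        genes = set(subsets[subset_name]) & universe
        if not genes:
            continue  # skipped per contract; caller may log
        n_sub = len(genes)
        for term, members in term_members.items():
            m = len(members)
            k = len(genes & members)
            pct_subset = 100.0 * k / n_sub
            pct_universe = 100.0 * m / n_universe
            upper = float(stats.hypergeom.sf(k - 1, n_universe, m, n_sub))
            lower = float(stats.hypergeom.cdf(k, n_universe, m, n_sub))
            p = min(1.0, 2.0 * min(upper, lower))
            if k * n_universe > m * n_sub:
                direction = "over"
            elif k * n_universe < m * n_sub:
                direction = "under"
            else:
                direction = "none"
            rows.append(
                (subset_name, term, n_sub, k, pct_subset, pct_universe, direction, p)
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "subset",
            "term",
            "n_subset",
            "n_with_term",
            "pct_subset",
            "pct_universe",
            "direction",
            "p_value",
        ],
    )
    if fdr and len(out):
        out["q_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
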