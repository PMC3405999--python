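"""Expression-change statistics per chromatin class and distance group.

Quantifies de-repression after repressor depletion: per-gene log2 change
between two sample groups, per-class summary statistics with t-based 95%
confidence intervals and Student's t-tests (one-sample vs zero, pairwise
pooled-variance two-sample), rescue-genotype restoration histograms, and
the distance-stratification comparison (nearest positive-gene TSS
distance, groups split at a 50 kb boundary, Mann-Whitney U between
groups — exact for small samples, normal approximation with tie correction
otherwise).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "expression_changes",
    "subset_statistics",
    "restoration_histograms",
    "nearest_positive_distance",
    "distance_stratification",
    "mann_whitney",
]

#: dual significance bands used when labelling test outcomes
SIGNIFICANT_P = 0.001
INSIGNIFICANT_P = 0.01

EXACT_MW_MAX_N = 20

DEFAULT_DISTANCE_EDGES = (50_000, 200_000)


def _band(p: float) -> str:
    if not np.isfinite(p):
        return "undefined"
    if p < SIGNIFICANT_P:
        return "significant"
    if p >= INSIGNIFICANT_P:
        return "insignificant"
    return "intermediate"


def expression_changes(
    expression: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene log2 expression change: mean(group B) − mean(group A)."""
    samples_a = groups.index[groups == group_a]
    samples_b = groups.index[groups == group_b]
    if len(samples_a) == 0 or len(samples_b) == 0:
        raise ValueError(f"both groups must be non-empty: {group_a!r}, {group_b!r}")
    mean_a = expression[list(samples_a)].mean(axis=1)
    mean_b = expression[list(samples_b)].mean(axis=1)
    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "change": mean_b - mean_a}
    ).rename_axis("gene_id")


def _one_sample(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """mean, sd, 95% CI bounds, one-sample t p-value vs 0 (nan when degenerate)."""
    n = values.size
    mean = float(np.mean(values))
    if n < 2:
        return mean, float("nan"), float("nan"), float("nan"), float("nan")
    sd = float(np.std(values, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    if sd == 0.0:
        return mean, 0.0, mean, mean, float("nan")
    p = float(stats.ttest_1samp(values, 0.0).pvalue)
    return mean, sd, mean - half, mean + half, p


def subset_statistics(
    changes: pd.Series,
    classes: pd.Series,
    reference_class: str | None = None,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary statistics of expression changes per chromatin class.

    Per class: n, mean change, SD, t-based 95% CI, one-sample Student's
    t-test of mean ≠ 0 (and, when ``reference_class`` is given, a
    two-sample test against that class), with significance bands:
    ``significant`` for P < 0.001, ``insignificant`` for P ≥ 0.01,
    ``intermediate`` between. Classes with n < 2 report statistics without
    p-values. The second frame holds all pairwise two-sample Student's
    t-tests (pooled variance; Welch behind the flag).

    Returns ``(per_class, pairwise)``.
    """
    changes, classes = changes.align(classes, join="inner")
    mask = np.isfinite(changes.to_numpy(dtype=float))
    changes, classes = changes[mask], classes[mask]
    by_class = {c: changes[classes == c].to_numpy(dtype=float) for c in classes.unique()}

    rows = []
    for cls in sorted(by_class):
        v = by_class[cls]
        mean, sd, lo, hi, p0 = _one_sample(v)
        row = {
            "class": cls,
            "n": v.size,
            "mean_change": mean,
            "sd": sd,
            "ci_low": lo,
            "ci_high": hi,
            "p_vs_zero": p0,
            "band_vs_zero": _band(p0),
        }
        if reference_class is not None:
            if cls == reference_class or reference_class not in by_class:
                row["p_vs_reference"] = float("nan")
            else:
                row["p_vs_reference"] = _two_sample(v, by_class[reference_class], welch)
        rows.append(row)
    per_class = pd.DataFrame(rows)

    pair_rows = []
    names = sorted(by_class)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = _two_sample(by_class[a], by_class[b], welch)
            pair_rows.append(
                {"class_a": a, "class_b": b, "p_value": p, "band": _band(p)}
            )
    pairwise = pd.DataFrame(pair_rows)
    return per_class, pairwise


def _two_sample(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    if a.size < 2 or b.size < 2:
        return float("nan")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def restoration_histograms(
    changes_by_genotype: Mapping[str, pd.Series],
    positive_genes: Iterable[str],
    bins: Sequence[float] | int = 40,
    hist_range: tuple[float, float] = (-2.0, 3.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binned expression-change distributions per genotype and mark status.

    For each rescue genotype the changes of mark-positive and mark-negative
    genes are binned separately (counts sum to subset size). The second
    frame carries the per-(genotype, status) mean change, used to order
    genotypes by how fully repression is restored (smaller mean change on
    positives = fuller restoration).

    Returns ``(histograms, means)``.
    """
    positive = set(positive_genes)
    if isinstance(bins, int):
        edges = np.linspace(hist_range[0], hist_range[1], bins + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    hist_rows, mean_rows = [], []
    for genotype in sorted(changes_by_genotype):
        changes = changes_by_genotype[genotype].dropna()
        flags = changes.index.isin(positive)
        for status, vals in (
            ("positive", changes[flags]),
            ("negative", changes[~flags]),
        ):
            v = vals.to_numpy(dtype=float)
            clipped = np.clip(v, edges[0], edges[-1])  # keep counts conserved
            counts, _ = np.histogram(clipped, bins=edges)
            for left, right, c in zip(edges[:-1], edges[1:], counts):
                hist_rows.append((genotype, status, left, right, int(c)))
            mean_rows.append(
                (
                    genotype,
                    status,
                    v.size,
                    float(np.mean(v)) if v.size else float("nan"),
                    float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
                )
            )
    histograms = pd.DataFrame(
        hist_rows, columns=["genotype", "status", "bin_left", "bin_right", "count"]
    )
    means = pd.DataFrame(
        mean_rows, columns=["genotype", "status", "n", "mean_change", "se"]
    )
    return histograms, means


def nearest_positive_distance(
    positive_genes: Iterable[str], genes: pd.DataFrame
) -> pd.Series:
    """TSS-to-TSS distance from each positive gene to its nearest positive.

    Distances are computed within chromosomes only; a chromosome's lone
    positive gene gets a missing distance.
    """
    positive = set(positive_genes)
    sub = genes[genes["gene_id"].isin(positive)]
    out = pd.Series(np.nan, index=pd.Index(sorted(positive), name="gene_id"), name="distance")
    for _, grp in sub.groupby("chrom", sort=False):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("tss")
        tss = grp["tss"].to_numpy(dtype=np.int64)
        gaps = np.diff(tss)
        left = np.concatenate([[np.iinfo(np.int64).max], gaps])
        right = np.concatenate([gaps, [np.iinfo(np.int64).max]])
        out.loc[grp["gene_id"].to_numpy()] = np.minimum(left, right).astype(float)
    return out


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test; returns (U, p, method).

    The exact null distribution is used when the combined sample size is at
    most 20 and there are no ties; otherwise the normal approximation with
    tie correction (and continuity correction) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < combined.size
    if combined.size <= EXACT_MW_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def distance_stratification(
    positive_genes: Iterable[str],
    genes: pd.DataFrame,
    changes: pd.Series,
    bin_edges: Sequence[int] = DEFAULT_DISTANCE_EDGES,
    exclude: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group positive genes by distance to the nearest positive; compare changes.

    Default edges (50 kb, 200 kb) give three groups: closely juxtaposed
    genes (< 50 kb), intermediate, and isolated (≥ 200 kb); only the 50 kb
    boundary is fixed by the biology of clustered loci, the upper edge is a
    configurable default. Genes in ``exclude`` (e.g. Hox-cluster members,
    for the sensitivity check) are removed before grouping. Expression
    changes are compared between every populated pair of groups with the
    Mann-Whitney U test.

    Returns ``(per_gene, comparisons)``; genes with a missing distance are
    listed ungrouped and excluded from the tests.
    """
    positive = set(positive_genes)
    if exclude:
        positive -= set(exclude)
    dist = nearest_positive_distance(positive, genes)
    edges = sorted(bin_edges)
    labels = [f"<{edges[0]}"]
    labels += [f"{a}-{b}" for a, b in zip(edges[:-1], edges[1:])]
    labels += [f">={edges[-1]}"]

    def group_of(d: float) -> str:
        if not np.isfinite(d):
            return ""
        idx = int(np.searchsorted(edges, d, side="right"))
        return labels[idx]

    per_gene = dist.to_frame()
    per_gene["group"] = [group_of(d) for d in dist]
    per_gene["change"] = changes.reindex(per_gene.index)
    per_gene = per_gene.reset_index()

    grouped = {
        g: sub["change"].dropna().to_numpy()
        for g, sub in per_gene[per_gene["group"] != ""].groupby("group")
    }
    populated = [g for g in labels if g in grouped and grouped[g].size > 0]
    rows = []
    for i, a in enumerate(populated):
        for b in populated[i + 1 :]:
            u, p, method = mann_whitney(grouped[a], grouped[b])
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": grouped[a].size,
                    "n_b": grouped[b].size,
                    "U": u,
                    "p_value": p,
                    "method": method,
                }
            )
    comparisons = pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "U", "p_value", "method"]
    )
    return per_gene, comparisons
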