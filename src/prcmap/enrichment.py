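"""Gene-wise enrichment scores, knockout subtraction, and TSS metaprofiles.

The gene score is the geometric mean of a gene's probe enrichment ratios
within a window around its TSS, realized as the arithmetic mean of log2
ratios. Replicates are averaged per probe first, then probes across the
window. Depletion-sensitive (differential) scores subtract a background
condition — a knockout in which the writer of the mark is absent — from the
control, per gene and mark. Metaprofiles average probe signal in
TSS-relative bins, strand-aware, over a stated gene set; a nucleosome-
occupancy control mark (H2A) can be subtracted bin-wise or gene-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneScoreTable",
    "assign_probes_to_genes",
    "gene_scores",
    "normalize_to_h2a",
    "metaprofile",
]


def assign_probes_to_genes(
    probes: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 5_000
) -> pd.DataFrame:
    """Pair unique probe locations with genes whose TSS window contains them.

    A probe's position is its interval midpoint, ``(start + end) // 2``. A
    probe may pair with several genes when TSS windows overlap. Returns one
    row per (probe_id, gene_id) with the strand-aware TSS-relative position:
    ``(midpoint - tss)`` for + genes, negated for - genes.
    """
    loc = probes[["probe_id", "chrom", "start", "end"]].drop_duplicates("probe_id")
    mid = ((loc["start"].to_numpy() + loc["end"].to_numpy()) // 2).astype(np.int64)
    loc = loc.assign(mid=mid)

    pairs = []
    genes_by_chrom = dict(tuple(genes.groupby("chrom", sort=False)))
    for chrom, grp in loc.groupby("chrom", sort=False, observed=True):
        g = genes_by_chrom.get(chrom)
        if g is None:
            continue
        g = g.sort_values("tss")
        tss = g["tss"].to_numpy(dtype=np.int64)
        gid = g["gene_id"].to_numpy()
        strand = g["strand"].to_numpy()
        m = grp["mid"].to_numpy()
        lo = np.searchsorted(tss, m - window_bp, side="left")
        hi = np.searchsorted(tss, m + window_bp, side="right")
        counts = hi - lo
        keep = counts > 0
        if not keep.any():
            continue
        reps = counts[keep]
        probe_rep = np.repeat(grp["probe_id"].to_numpy()[keep], reps)
        mid_rep = np.repeat(m[keep], reps)
        gene_idx = np.concatenate([np.arange(a, b) for a, b in zip(lo[keep], hi[keep])])
        rel = mid_rep - tss[gene_idx]
        rel = np.where(strand[gene_idx] == "+", rel, -rel)
        pairs.append(
            pd.DataFrame(
                {"probe_id": probe_rep, "gene_id": gid[gene_idx], "rel_pos": rel}
            )
        )
    if not pairs:
        return pd.DataFrame(columns=["probe_id", "gene_id", "rel_pos"])
    return pd.concat(pairs, ignore_index=True)


@dataclass
class GeneScoreTable:
    """Gene-wise enrichment scores and knockout-subtracted differentials.

    ``scores``: long frame (gene_id, mark, condition, score, n_probes); the
    score is the log2 of the geometric mean of the gene's probe ratios.
    Genes with no assigned probes are absent (missing), never zero.
    """

    scores: pd.DataFrame
    window_bp: int

    def pivot(self, mark: str) -> pd.DataFrame:
        """Gene x condition score matrix for one mark."""
        sub = self.scores[self.scores["mark"] == mark]
        return sub.pivot(index="gene_id", columns="condition", values="score")

    def differential(
        self,
        control: str = "control",
        background_map: Mapping[str, str] | None = None,
        default_background: str = "ko",
    ) -> pd.DataFrame:
        """Depletion-sensitive score per (gene, mark): control − background.

        ``background_map`` names the background condition per mark (e.g. the
        PRC2-null sample for H3K27me3, the PRC1-null sample for Ring1B and
        H2AK119u1); marks not listed use ``default_background``. Genes
        missing either condition get a missing differential.
        """
        background_map = background_map or {}
        out = []
        for mark, sub in self.scores.groupby("mark", sort=False):
            background = background_map.get(mark, default_background)
            wide = sub.pivot(index="gene_id", columns="condition", values="score")
            if control not in wide.columns or background not in wide.columns:
                raise KeyError(
                    f"mark {mark!r}: conditions {control!r}/{background!r} not both scored"
                )
            delta = (wide[control] - wide[background]).rename("delta")
            frame = delta.reset_index()
            frame.insert(1, "mark", mark)
            out.append(frame)
        return pd.concat(out, ignore_index=True)


def gene_scores(
    probes: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 5_000,
) -> GeneScoreTable:
    """Aggregate probe log2 ratios to gene-wise geometric-mean scores.

    For each gene, probes whose midpoint lies in ``[TSS - window_bp,
    TSS + window_bp]`` are collected; replicate log2 ratios are averaged per
    probe first, then averaged across the window. The result per (gene,
    mark, condition) equals log2 of the geometric mean of the ratios.
    """
    pairs = assign_probes_to_genes(probes, genes, window_bp)
    # integer probe codes shared between both frames keep the merge cheap
    probe_cat = probes["probe_id"].astype("category")
    work = probes[["mark", "condition", "log2_ratio"]].copy()
    work["pid"] = probe_cat.cat.codes.to_numpy()
    rep_mean = (
        work.groupby(["pid", "mark", "condition"], sort=False, observed=True)[
            "log2_ratio"
        ]
        .mean()
        .reset_index()
    )
    pair_codes = pd.Categorical(
        pairs["probe_id"], categories=probe_cat.cat.categories
    ).codes
    pair_frame = pd.DataFrame({"pid": pair_codes, "gene_id": pairs["gene_id"]})
    merged = rep_mean.merge(pair_frame, on="pid", how="inner")
    scores = (
        merged.groupby(["gene_id", "mark", "condition"], sort=True, observed=True)[
            "log2_ratio"
        ]
        .agg(score="mean", n_probes="size")
        .reset_index()
    )
    scores["mark"] = scores["mark"].astype(str)
    scores["condition"] = scores["condition"].astype(str)
    scores["gene_id"] = scores["gene_id"].astype(str)
    return GeneScoreTable(scores=scores, window_bp=window_bp)


def normalize_to_h2a(values: pd.Series, h2a_values: pd.Series) -> pd.Series:
    """Subtract matched H2A log2 values (nucleosome-occupancy control).

    Aligned on the shared index (genes or profile bins); entries without an
    H2A counterpart come back missing.
    """
    mark, h2a = values.align(h2a_values, join="left")
    return mark - h2a


def metaprofile(
    probes: pd.DataFrame,
    genes: pd.DataFrame,
    gene_set: Iterable[str],
    mark: str,
    condition: str,
    window_bp: int = 5_000,
    bin_bp: int = 250,
) -> pd.DataFrame:
    """Average TSS-relative enrichment profile over a gene set.

    Each probe-gene pair contributes its replicate-averaged log2 ratio at
    the strand-aware relative position of the probe midpoint. Returns one
    row per bin: bin_left, bin_right, bin_center, mean, n_pairs; bins with
    no contributing pair carry a missing mean. The profile spans
    ``[-window_bp, +window_bp]``; ``bin_bp`` must divide ``2 * window_bp``.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene_set")
    unknown = gene_set - set(genes["gene_id"])
    if unknown:
        raise ValueError(f"gene_set contains unannotated genes: {sorted(unknown)[:5]}")
    if (2 * window_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide 2 * window_bp")

    sub = probes[(probes["mark"] == mark) & (probes["condition"] == condition)]
    rep_mean = (
        sub.groupby("probe_id", sort=False, observed=True)["log2_ratio"].mean().reset_index()
    )
    pairs = assign_probes_to_genes(sub, genes[genes["gene_id"].isin(gene_set)], window_bp)
    merged = pairs.merge(rep_mean, on="probe_id", how="inner")

    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    # right-inclusive last bin so rel == +window_bp is kept
    idx = np.clip(np.digitize(merged["rel_pos"].to_numpy(), edges) - 1, 0, len(edges) - 2)
    merged = merged.assign(bin=idx)
    agg = merged.groupby("bin")["log2_ratio"].agg(["mean", "size"])
    out = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "bin_center": (edges[:-1] + edges[1:]) / 2.0,
        }
    )
    out["mean"] = agg["mean"].reindex(range(len(edges) - 1)).to_numpy()
    out["n_pairs"] = agg["size"].reindex(range(len(edges) - 1), fill_value=0).to_numpy()
    return out
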