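"""Simple figures: TSS metaprofiles and expression-change histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_metaprofiles(profiles: dict, ax=None, ylabel: str = "mean log2 enrichment"):
    """Overlay labelled TSS metaprofiles (as returned by ``metaprofile``)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(prof["bin_center"] / 1000.0, prof["mean"], label=label)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("position relative to TSS (kb)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_change_histograms(histograms: pd.DataFrame, status: str = "positive", ax=None):
    """Step histograms of expression changes per genotype for one mark status."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = histograms[histograms["status"] == status]
    for genotype, grp in sub.groupby("genotype"):
        total = grp["count"].sum() or 1
        ax.step(grp["bin_left"], grp["count"] / total, where="post", label=genotype)
    ax.set_xlabel("log2 expression change")
    ax.set_ylabel("fraction of genes")
    ax.set_title(f"{status} genes")
    ax.legend(frameon=False, fontsize=8)
    return ax
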