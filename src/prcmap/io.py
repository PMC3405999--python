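"""Readers and writers for the tab-delimited formats the pipeline touches.

All genomic intervals are 0-based half-open internally; BED semantics are
preserved on round trip. TSS convention: ``start`` for + strand genes,
``end - 1`` for - strand genes.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "PROBE_COLUMNS",
    "read_probe_table",
    "write_probe_table",
    "read_gene_bed",
    "write_gene_bed",
    "read_expression",
    "write_expression",
    "read_sample_groups",
    "read_terms",
    "write_results",
]

PROBE_COLUMNS = [
    "probe_id",
    "chrom",
    "start",
    "end",
    "mark",
    "condition",
    "replicate",
    "log2_ratio",
]

#: fixed float format used for every written table, for byte-stable output
FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def read_probe_table(path) -> pd.DataFrame:
    """Read a probe-level enrichment TSV into a validated DataFrame.

    Requires the full header (:data:`PROBE_COLUMNS`). Rows with a
    non-numeric ratio or ``start >= end`` raise :class:`ParseError` naming
    the 1-based file line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce")
    bad = ~np.isfinite(ratios.to_numpy())
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: non-finite log2_ratio at line {line}")
    df["log2_ratio"] = ratios
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["replicate"] = df["replicate"].astype(np.int64)
    bad = (df["start"] >= df["end"]).to_numpy()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ParseError(f"{path}: interval with start >= end at line {line}")
    return df[PROBE_COLUMNS]


def write_probe_table(df: pd.DataFrame, path) -> None:
    df[PROBE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gene_bed(path) -> pd.DataFrame:
    """Read a BED6 gene annotation; extract the strand-aware TSS.

    Returns columns gene_id, chrom, start, end, strand, tss. Duplicate gene
    ids and strands outside {+,-} raise :class:`ParseError`.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    bad = ~df["strand"].isin(["+", "-"]).to_numpy()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ParseError(f"{path}: malformed strand field at line {line}")
    dup = df["gene_id"].duplicated().to_numpy()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 1
        raise ParseError(f"{path}: duplicate gene_id at line {line}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df[["gene_id", "chrom", "start", "end", "strand", "tss"]]


def write_gene_bed(genes: pd.DataFrame, path, gene_length_bp: int = 2_000) -> None:
    """Write gene annotations as BED6.

    Accepts either explicit start/end columns or a tss column, from which a
    body of ``gene_length_bp`` is laid out downstream of the TSS
    (strand-aware) so that reading the file back recovers the same TSS.
    """
    df = genes.copy()
    if "start" not in df.columns or "end" not in df.columns:
        plus = df["strand"] == "+"
        df["start"] = np.where(plus, df["tss"], df["tss"] - gene_length_bp + 1)
        df["end"] = np.where(plus, df["tss"] + gene_length_bp, df["tss"] + 1)
    out = df[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = df["strand"].to_numpy()
    out.to_csv(path, sep="\t", index=False, header=False)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log2 expression TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids in expression table")
    df.index.name = "gene_id"
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_sample_groups(path) -> pd.Series:
    """Read a two-column sample<TAB>group mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if df["sample"].duplicated().any():
        raise ParseError(f"{path}: sample assigned to more than one group")
    return df.set_index("sample")["group"]


def read_terms(path) -> pd.DataFrame:
    """Read a two-column gene_id<TAB>term mapping (flat, no ontology graph)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term"], dtype=str)
    return df.drop_duplicates()


def write_results(tables: Mapping[str, pd.DataFrame], outdir) -> dict:
    """Write computed tables as ``<name>.tsv`` under ``outdir``.

    Column order is taken from each frame as-is; floats use a fixed format
    so re-running on identical inputs is byte-identical. Returns
    ``{name: path}``.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        paths[name] = path
    return paths
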