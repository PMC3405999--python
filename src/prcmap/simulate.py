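"""Synthetic promoter-array data with planted ground truth.

Emulates the measurement design the pipeline consumes: probe-level log2
ChIP-enrichment ratios tiled around annotated TSSs, a control condition in
which a planted subset of genes carries mark signal, a knockout condition in
which that signal collapses (or persists, for null experiments), independent
replicate noise, and gene-expression matrices with class-dependent
de-repression effects. Every downstream stage of the pipeline can therefore
be checked against the exact membership sets and effects planted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_chip_arrays",
    "simulate_expression",
    "simulate_rescue_expression",
]

DEFAULT_MARKS = ("H2AK119u1", "Ring1B", "H3K27me3")

#: flag-triple aliases in mark order (H2AK119u1, Ring1B, H3K27me3)
CLASS_ALIASES = {
    (True, True, True): "TP",
    (False, True, True): "DP",
    (False, False, True): "SP",
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def _per_mark(value, marks: Sequence[str], name: str) -> dict:
    """Broadcast a scalar to all marks, or validate a per-mark mapping."""
    if isinstance(value, Mapping):
        missing = [m for m in marks if m not in value]
        if missing:
            raise ConfigurationError(f"{name} missing entries for marks: {missing}")
        return {m: value[m] for m in marks}
    return {m: value for m in marks}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated promoter-array experiment.

    Genes are laid out on ``n_chromosomes`` coordinate lines at
    ``gene_spacing_bp``; probes tile ``[TSS - window_bp, TSS + window_bp]``
    every ``probe_spacing_bp``. Per mark, a ``positive_fraction`` of genes
    carries a peak of ``peak_amplitude`` log2 units (flat or Gaussian of
    ``peak_width_bp``); the knockout condition retains
    ``ko_residual_fraction`` of that amplitude. With ``nested_marks`` the
    positive sets are nested in reverse mark order
    (H2AK119u1 ⊂ Ring1B ⊂ H3K27me3), mirroring the layered occupancy of
    Polycomb domains. ``close_pair_fraction`` of first-mark positives are
    relocated ``close_pair_bp`` from another positive to exercise
    nearest-neighbour distance stratification.
    """

    n_genes: int = 10_000
    n_chromosomes: int = 19
    gene_spacing_bp: int = 100_000
    probe_spacing_bp: int = 250
    window_bp: int = 5_000
    marks: tuple = DEFAULT_MARKS
    positive_fraction: Mapping[str, float] | float = field(
        default_factory=lambda: {"H2AK119u1": 0.05, "Ring1B": 0.10, "H3K27me3": 0.20}
    )
    nested_marks: bool = True
    peak_amplitude: Mapping[str, float] | float = 2.0
    peak_shape: str = "gaussian"  # "gaussian" or "flat"
    peak_width_bp: float = 1_000.0
    noise_sd: float = 0.4
    n_replicates: int = 2
    control_condition: str = "control"
    ko_condition: str = "ko"
    ko_residual_fraction: Mapping[str, float] | float = 0.0
    close_pair_fraction: float = 0.25
    close_pair_bp: int = 30_000
    gene_length_bp: int = 2_000
    expression_effects: Mapping[str, float] = field(
        default_factory=lambda: {"TP": 1.0, "DP": 0.5, "SP": 0.25, "none": 0.0}
    )
    expression_noise_sd: float = 0.3
    expression_baseline_mean: float = 7.0
    expression_baseline_sd: float = 1.5
    n_samples_per_group: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ConfigurationError("n_genes and n_chromosomes must be positive")
        if self.probe_spacing_bp <= 0 or self.window_bp <= 0:
            raise ConfigurationError("probe_spacing_bp and window_bp must be positive")
        if self.gene_spacing_bp <= 0:
            raise ConfigurationError("gene_spacing_bp must be positive")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ConfigurationError("noise sds must be non-negative")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.peak_shape not in ("gaussian", "flat"):
            raise ConfigurationError(f"unknown peak_shape {self.peak_shape!r}")
        if not 0.0 <= self.close_pair_fraction <= 1.0:
            raise ConfigurationError("close_pair_fraction must be in [0, 1]")
        for m, f in _per_mark(self.positive_fraction, self.marks, "positive_fraction").items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"positive_fraction[{m}]={f} outside [0, 1]")
        for m, f in _per_mark(
            self.ko_residual_fraction, self.marks, "ko_residual_fraction"
        ).items():
            if f < 0.0:
                raise ConfigurationError(f"ko_residual_fraction[{m}] must be >= 0")

    # convenience accessors resolving scalar-or-mapping fields
    def fraction_of(self, mark: str) -> float:
        return _per_mark(self.positive_fraction, self.marks, "positive_fraction")[mark]

    def amplitude_of(self, mark: str) -> float:
        return _per_mark(self.peak_amplitude, self.marks, "peak_amplitude")[mark]

    def ko_residual_of(self, mark: str) -> float:
        return _per_mark(self.ko_residual_fraction, self.marks, "ko_residual_fraction")[mark]

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth emitted alongside simulated data.

    ``members`` maps mark name to the frozen set of positive gene ids;
    ``classes`` maps every gene id to its chromatin class alias (TP/DP/SP,
    a flag triple for non-aliased combinations, or "none"); ``effects`` maps
    every gene id to its planted log2 expression effect.
    """

    members: Mapping[str, frozenset]
    classes: pd.Series
    effects: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per gene with per-mark flags, class, effect."""
        genes = self.classes.index
        out = pd.DataFrame(index=genes)
        for mark, s in self.members.items():
            out[f"{mark}_true"] = genes.isin(s)
        out["true_class"] = self.classes
        out["planted_effect"] = self.effects
        out.index.name = "gene_id"
        return out.reset_index()


def _seeds(config: SimulationConfig, n: int) -> list:
    return np.random.SeedSequence(config.seed).spawn(n)


def _gene_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place genes on chromosomes at regular spacing; assign strands 50/50."""
    n = config.n_genes
    chrom_idx = np.arange(n) % config.n_chromosomes
    within = np.arange(n) // config.n_chromosomes
    offset = config.window_bp + config.probe_spacing_bp + config.gene_length_bp
    tss = offset + within * config.gene_spacing_bp
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n)],
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "tss": tss.astype(np.int64),
            "strand": strand,
        }
    )


def _plant_membership(
    config: SimulationConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> dict:
    """Draw per-mark positive sets; nested in reverse mark order if configured."""
    ids = genes["gene_id"].to_numpy()
    members: dict = {}
    if config.nested_marks:
        # outermost mark (last in tuple) drawn from the universe, each inner
        # mark drawn from the next-outer set: H2AK119u1 ⊂ Ring1B ⊂ H3K27me3
        pool = ids
        for mark in reversed(config.marks):
            size = int(round(config.fraction_of(mark) * len(ids)))
            size = min(size, len(pool))
            chosen = rng.choice(pool, size=size, replace=False)
            members[mark] = frozenset(chosen)
            pool = chosen
    else:
        for mark in config.marks:
            size = int(round(config.fraction_of(mark) * len(ids)))
            members[mark] = frozenset(rng.choice(ids, size=size, replace=False))
    return members


def _plant_close_pairs(
    config: SimulationConfig,
    genes: pd.DataFrame,
    members: Mapping[str, frozenset],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Relocate a fraction of first-mark positives next to another positive.

    Positives are paired in coordinate order per chromosome and the second
    member of each selected pair is moved to ``close_pair_bp`` downstream of
    the first, producing planted nearest-neighbour distances below the 50 kb
    boundary used in distance stratification.
    """
    if config.close_pair_fraction == 0.0 or not config.marks:
        return genes
    target = members[config.marks[0]]
    genes = genes.copy()
    pos = genes[genes["gene_id"].isin(target)].sort_values(["chrom", "tss"])
    n_moved = 0
    n_to_move = int(round(config.close_pair_fraction * len(pos) / 2))
    for _, grp in pos.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        for k in range(0, len(idx) - 1, 2):
            if n_moved >= n_to_move:
                return genes
            a, b = idx[k], idx[k + 1]
            genes.loc[b, "tss"] = genes.loc[a, "tss"] + config.close_pair_bp
            n_moved += 1
    return genes


def _classify_truth(config: SimulationConfig, genes: pd.DataFrame, members) -> pd.Series:
    flags = np.column_stack(
        [genes["gene_id"].isin(members[m]).to_numpy() for m in config.marks]
    )
    labels = []
    for row in flags:
        key = tuple(bool(x) for x in row)
        if not any(key):
            labels.append("none")
        elif key in CLASS_ALIASES and config.marks == DEFAULT_MARKS:
            labels.append(CLASS_ALIASES[key])
        else:
            labels.append(
                "".join(f"{m}{'+' if f else '-'}" for m, f in zip(config.marks, row))
            )
    return pd.Series(labels, index=genes["gene_id"].to_numpy(), name="true_class")


def _shape_values(config: SimulationConfig, offsets: np.ndarray) -> np.ndarray:
    if config.peak_shape == "flat":
        return np.ones_like(offsets, dtype=float)
    w = float(config.peak_width_bp)
    return np.exp(-0.5 * (offsets / w) ** 2)


def simulate_chip_arrays(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a promoter-array ChIP experiment.

    Returns ``(probes, genes, truth)``: a long probe table with one row per
    (probe, mark, condition, replicate), a gene annotation table, and the
    planted :class:`GroundTruth`. For a positive gene in the control
    condition each probe carries ``amplitude * shape(midpoint - TSS)`` plus
    independent N(0, noise_sd) noise per replicate; in the knockout
    condition the amplitude is multiplied by the mark's residual fraction.
    Identical config (including seed) gives identical output.
    """
    config.validate()
    s_layout, s_members, s_noise = _seeds(config, 3)
    rng_layout = np.random.default_rng(s_layout)
    rng_members = np.random.default_rng(s_members)
    rng_noise = np.random.default_rng(s_noise)

    genes = _gene_layout(config, rng_layout)
    members = _plant_membership(config, genes, rng_members)
    genes = _plant_close_pairs(config, genes, members, rng_layout)
    classes = _classify_truth(config, genes, members)

    effects = classes.map(
        lambda c: config.expression_effects.get(c, config.expression_effects.get("none", 0.0))
    ).rename("planted_effect")
    truth = GroundTruth(members=members, classes=classes, effects=effects)

    offsets = np.arange(
        -config.window_bp, config.window_bp + 1, config.probe_spacing_bp, dtype=np.int64
    )
    n_probes = offsets.size
    n_genes = len(genes)
    shape = _shape_values(config, offsets)

    tss = genes["tss"].to_numpy()
    mids = (tss[:, None] + offsets[None, :]).ravel()  # gene-major probe midpoints
    half = config.probe_spacing_bp // 2
    starts = mids - half
    ends = mids + (config.probe_spacing_bp - half)
    chrom_codes = np.repeat(
        genes["chrom"].astype("category").cat.codes.to_numpy(), n_probes
    )
    chrom_cats = genes["chrom"].astype("category").cat.categories
    probe_ids = np.char.add(
        np.char.add(np.asarray(chrom_cats)[chrom_codes].astype(str), ":"),
        mids.astype(str),
    )

    # one block per (mark, condition, replicate); static columns are tiled
    # once and stored as categoricals to keep assembly and memory cheap
    conditions = (config.control_condition, config.ko_condition)
    signals, mark_codes, cond_codes, reps = [], [], [], []
    n_block = n_genes * n_probes
    for mi, mark in enumerate(config.marks):
        positive = genes["gene_id"].isin(members[mark]).to_numpy()
        base = np.where(positive[:, None], config.amplitude_of(mark) * shape[None, :], 0.0)
        for ci, condition in enumerate(conditions):
            scale = 1.0 if condition == config.control_condition else config.ko_residual_of(mark)
            signal = (base * scale).ravel()
            for rep in range(1, config.n_replicates + 1):
                noise = (
                    rng_noise.normal(0.0, config.noise_sd, size=n_block)
                    if config.noise_sd > 0
                    else 0.0
                )
                signals.append(signal + noise)
                mark_codes.append(mi)
                cond_codes.append(ci)
                reps.append(rep)
    k = len(signals)
    tile_idx = np.tile(np.arange(n_block), k)
    probes = pd.DataFrame(
        {
            "probe_id": pd.Categorical.from_codes(tile_idx, categories=probe_ids),
            "chrom": pd.Categorical.from_codes(
                chrom_codes[tile_idx], categories=chrom_cats
            ),
            "start": starts[tile_idx],
            "end": ends[tile_idx],
            "mark": pd.Categorical.from_codes(
                np.repeat(mark_codes, n_block), categories=list(config.marks)
            ),
            "condition": pd.Categorical.from_codes(
                np.repeat(cond_codes, n_block), categories=list(conditions)
            ),
            "replicate": np.repeat(reps, n_block),
            "log2_ratio": np.concatenate(signals),
        }
    )
    return probes, genes, truth


def _expression_samples(
    genes: pd.Index,
    baseline: np.ndarray,
    effect: np.ndarray,
    noise_sd: float,
    n_per_group: int,
    rng: np.random.Generator,
    group_names: tuple[str, str] = ("before", "after"),
) -> tuple[pd.DataFrame, pd.Series]:
    cols, data = [], []
    for g, shift in zip(group_names, (0.0, 1.0)):
        for i in range(1, n_per_group + 1):
            cols.append(f"{g}_{i}")
            noise = rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd > 0 else 0.0
            data.append(baseline + shift * effect + noise)
    expr = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    expr.index.name = "gene_id"
    groups = pd.Series(
        {c: (group_names[0] if c.startswith(group_names[0]) else group_names[1]) for c in cols},
        name="group",
    )
    return expr, groups


def simulate_expression(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate log2 expression before/after repressor depletion.

    Returns ``(expression, groups)``: a genes x samples log2 matrix and a
    sample→group mapping. "after" samples equal "before" plus the planted
    class effect plus independent noise; group sizes come from
    ``config.n_samples_per_group``.
    """
    config.validate()
    unknown = set(truth.classes.unique()) - set(config.expression_effects)
    if unknown:
        raise ConfigurationError(
            f"truth classes without an expression_effects entry: {sorted(unknown)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    genes = pd.Index(truth.classes.index, name="gene_id")
    baseline = rng.normal(
        config.expression_baseline_mean, config.expression_baseline_sd, size=len(genes)
    )
    effect = truth.effects.to_numpy(dtype=float)
    return _expression_samples(
        genes, baseline, effect, config.expression_noise_sd, config.n_samples_per_group, rng
    )


def simulate_rescue_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    genotype_effects: Mapping[str, float],
    positive_mark: str = "H2AK119u1",
) -> dict:
    """Simulate depletion expression under several rescue genotypes.

    ``genotype_effects`` maps genotype name to the mean log2 de-repression
    planted on genes positive for ``positive_mark``; negative genes get no
    effect. Returns ``{genotype: (expression, groups)}`` with independent
    noise per genotype, emulating a rescue series (mock / wild-type /
    catalytic-mutant transgene).
    """
    config.validate()
    if positive_mark not in truth.members:
        raise ConfigurationError(f"unknown mark {positive_mark!r} in ground truth")
    genes = pd.Index(truth.classes.index, name="gene_id")
    positive = genes.isin(truth.members[positive_mark]).astype(float)
    ss = np.random.SeedSequence(config.seed).spawn(5)[4].spawn(len(genotype_effects))
    out = {}
    for sub, (genotype, eff) in zip(ss, sorted(genotype_effects.items())):
        rng = np.random.default_rng(sub)
        baseline = rng.normal(
            config.expression_baseline_mean, config.expression_baseline_sd, size=len(genes)
        )
        out[genotype] = _expression_samples(
            genes,
            baseline,
            eff * positive,
            config.expression_noise_sd,
            config.n_samples_per_group,
            rng,
        )
    return out
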