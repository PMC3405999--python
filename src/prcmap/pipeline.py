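"""End-to-end pipeline: simulate/load → score → call → classify → diffexpr.

A run is a pure function of its configuration (plus input files when not
simulating): all randomness flows from the config's seed, outputs are
written with fixed float formatting, and the manifest records checksums so
repeated runs can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__, io, simulate
from .classify import classify_genes, overlap_probability
from .diffexpr import distance_stratification, expression_changes, subset_statistics
from .enrichment import gene_scores
from .mixture import DegenerateFitError, TwoGaussianMixture

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("prcmap")


class ValidationError(ValueError):
    """Configuration invalid; nothing was written."""


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline run configuration.

    Either ``simulate`` holds :class:`~prcmap.simulate.SimulationConfig`
    overrides, or ``inputs`` names existing probe/gene/expression/group
    files. ``threshold_multiplier`` is the k of the mean + k·sd calling
    rule (3 by default).
    """

    outdir: str
    seed: int = 0
    simulate_params: Mapping[str, Any] | None = None
    inputs: Mapping[str, str] | None = None
    window_bp: int = 5_000
    control_condition: str = "control"
    background_map: Mapping[str, str] = dataclasses.field(default_factory=dict)
    default_background: str = "ko"
    threshold_multiplier: float = 3.0
    max_iter: int = 500
    tol: float = 1e-8
    group_a: str = "before"
    group_b: str = "after"
    distance_bin_edges: tuple = (50_000, 200_000)
    distance_exclude: tuple = ()
    raw: Mapping[str, Any] = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValidationError("threshold_multiplier must be positive")
        if (self.simulate_params is None) == (self.inputs is None):
            raise ValidationError("config needs exactly one of 'simulate' or 'inputs'")
        if self.inputs is not None:
            for key in ("probes", "genes", "expression", "groups"):
                path = self.inputs.get(key)
                if path is None:
                    raise ValidationError(f"inputs missing required path {key!r}")
                if not os.path.exists(path):
                    raise ValidationError(f"input file does not exist: {path}")


def load_config(path_or_dict) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file path or a plain dict."""
    if isinstance(path_or_dict, (str, os.PathLike)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    cfg = RunConfig(
        outdir=raw.get("outdir", "prcmap_out"),
        seed=int(raw.get("seed", 0)),
        simulate_params=raw.get("simulate"),
        inputs=raw.get("inputs"),
        window_bp=int(raw.get("window_bp", 5_000)),
        control_condition=raw.get("control_condition", "control"),
        background_map=raw.get("background_map", {}) or {},
        default_background=raw.get("default_background", "ko"),
        threshold_multiplier=float(raw.get("threshold_multiplier", 3.0)),
        max_iter=int(raw.get("max_iter", 500)),
        tol=float(raw.get("tol", 1e-8)),
        group_a=raw.get("group_a", "before"),
        group_b=raw.get("group_b", "after"),
        distance_bin_edges=tuple(raw.get("distance_bin_edges", (50_000, 200_000))),
        distance_exclude=tuple(raw.get("distance_exclude", ())),
        raw=raw,
    )
    cfg.validate()
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: RunConfig) -> str:
    # outdir is a location, not an analysis parameter: keep it out of the
    # hash so reruns into different directories are recognizably identical
    payload = {
        k: v for k, v in dataclasses.asdict(cfg).items() if k not in ("raw", "outdir")
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config) -> dict:
    """Execute all stages in dependency order; return the run manifest.

    On validation failure nothing is written. Any stage failure propagates
    with the stage named in the log. The manifest (written last as
    ``manifest.json``) carries the config hash, package version, per-stage
    gene counts, output checksums and warnings; identical config ⇒
    identical manifest.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    cfg.validate()
    warnings: list[str] = []
    counts: dict[str, int] = {}
    tables: dict[str, pd.DataFrame] = {}

    # --- stage: acquire inputs -------------------------------------------
    if cfg.simulate_params is not None:
        log.info("stage simulate")
        sim_kwargs = dict(cfg.simulate_params)
        sim_kwargs.setdefault("seed", cfg.seed)
        for key in ("marks", "expression_effects", "positive_fraction",
                    "peak_amplitude", "ko_residual_fraction"):
            if key in sim_kwargs and isinstance(sim_kwargs[key], list):
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_cfg = simulate.SimulationConfig(**sim_kwargs)
        probes, genes, truth = simulate.simulate_chip_arrays(sim_cfg)
        expression, groups = simulate.simulate_expression(sim_cfg, truth)
        tables["ground_truth"] = truth.to_frame()
    else:
        log.info("stage load")
        probes = io.read_probe_table(cfg.inputs["probes"])
        genes = io.read_gene_bed(cfg.inputs["genes"])
        expression = io.read_expression(cfg.inputs["expression"])
        groups = io.read_sample_groups(cfg.inputs["groups"])
    counts["genes_annotated"] = len(genes)
    counts["probe_rows"] = len(probes)

    # --- stage: score -----------------------------------------------------
    log.info("stage score")
    table = gene_scores(probes, genes, window_bp=cfg.window_bp)
    delta = table.differential(
        control=cfg.control_condition,
        background_map=cfg.background_map,
        default_background=cfg.default_background,
    )
    tables["gene_scores"] = table.scores
    tables["differential_scores"] = delta
    counts["genes_scored"] = delta["gene_id"].nunique()

    # --- stage: call ------------------------------------------------------
    log.info("stage call")
    marks = tuple(delta["mark"].unique())
    calls = {}
    fit_rows = []
    for mark in marks:
        values = delta.loc[delta["mark"] == mark].set_index("gene_id")["delta"]
        fit = TwoGaussianMixture(values, multiplier=cfg.threshold_multiplier).fit(
            max_iter=cfg.max_iter, tol=cfg.tol, seed=cfg.seed
        )
        fit_rows.append(
            {
                "mark": mark,
                "weight_low": fit.weight_low,
                "weight_high": fit.weight_high,
                "mean_low": fit.mean_low,
                "mean_high": fit.mean_high,
                "sd_low": fit.sd_low,
                "sd_high": fit.sd_high,
                "threshold": fit.threshold,
                "converged": fit.converged,
                "degenerate": fit.degenerate,
                "n_values": fit.n_values,
            }
        )
        try:
            calls[mark] = set(fit.call_targets(values, mark=mark).positives)
        except DegenerateFitError as exc:
            warnings.append(f"{mark}: {exc}")
            calls[mark] = set()
    tables["mixture_fits"] = pd.DataFrame(fit_rows)
    call_frames = [
        pd.DataFrame({"gene_id": sorted(s), "mark": m}) for m, s in calls.items()
    ]
    tables["target_calls"] = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else pd.DataFrame(columns=["gene_id", "mark"])
    )
    for mark in marks:
        counts[f"called_{mark}"] = len(calls[mark])

    # --- stage: classify --------------------------------------------------
    log.info("stage classify")
    universe = sorted(delta["gene_id"].unique())
    class_table = classify_genes(calls, universe, marks=marks)
    tables["gene_classes"] = class_table
    counts["genes_classified"] = len(class_table)

    overlap_rows = []
    for i, a in enumerate(marks):
        for b in marks[i + 1 :]:
            r = overlap_probability(calls[a], calls[b], universe)
            overlap_rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "observed": r.observed,
                    "expected": r.expected,
                    "p_value": r.p_value,
                }
            )
    tables["overlaps"] = pd.DataFrame(overlap_rows)

    # --- stage: diffexpr --------------------------------------------------
    log.info("stage diffexpr")
    changes = expression_changes(expression, groups, cfg.group_a, cfg.group_b)
    tables["expression_changes"] = changes.reset_index()
    classes = class_table.set_index("gene_id")["alias"].where(
        class_table.set_index("gene_id")["alias"] != "",
        class_table.set_index("gene_id")["class"],
    )
    per_class, pairwise = subset_statistics(changes["change"], classes)
    tables["subset_statistics"] = per_class
    tables["subset_pairwise"] = pairwise
    counts["genes_with_changes"] = int(changes["change"].notna().sum())

    first_mark = marks[0]
    if len(calls[first_mark]) >= 2:
        per_gene, comparisons = distance_stratification(
            calls[first_mark],
            genes,
            changes["change"],
            bin_edges=cfg.distance_bin_edges,
            exclude=cfg.distance_exclude,
        )
        tables["distance_groups"] = per_gene
        tables["distance_comparisons"] = comparisons
    else:
        warnings.append(f"distance stratification skipped: <2 {first_mark} positives")

    # --- stage: write -----------------------------------------------------
    log.info("stage write")
    paths = io.write_results(tables, cfg.outdir)
    manifest = {
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "seed": cfg.seed,
        "counts": counts,
        "checksums": {name: _sha256(p) for name, p in sorted(paths.items())},
        "warnings": warnings,
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
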