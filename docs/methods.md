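# Methods

## Gene-wise enrichment scores

A gene's score for one mark and condition is the geometric mean of the
enrichment ratios of the probes assigned to it, realized on the log
scale: replicate log2 ratios are averaged per probe first, then probe
values are averaged across the window. Replicate-first averaging is
symmetric and, under equal replicate counts, identical in expectation
to pooling; it also makes the score well-defined when replicate counts
differ per probe. Probes are assigned by interval midpoint
(`(start+end)//2`, floor division) falling within ±`window_bp` of the
TSS; the midpoint is the standard summary for tiling probes and the
floor makes assignment integer-exact. Genes with no assigned probe are
reported missing, never zero — a zero is a valid measurement, a missing
gene is not.

The window default is ±5 kb, matching the span over which promoter
metaprofiles are drawn; the scoring window for the original arrays is
not documented, so it is exposed as a parameter rather than asserted.

Knockout subtraction operates on gene scores: Δ = score(control) −
score(background condition), where the background condition is the
sample in which the mark's writer is absent (a PRC1-null sample for
H2AK119u1/Ring1B, a PRC2-null sample for H3K27me3). The engine is
mark-agnostic: the background condition is configured per mark.
H2A normalization (subtracting the log2 enrichment of bulk H2A, a
nucleosome-occupancy control) is applied to metaprofiles and available
gene-wise, but is off by default for target calling, since knockout
subtraction already cancels occupancy effects.

## Two-Gaussian mixture threshold

Differential scores are modelled as a mixture of a background and an
enriched normal component. The fit is maximum likelihood via EM on the
raw values; a binned-histogram least-squares fit of the same model is
kept in the test suite as an independent oracle, and the two agree
within ±0.1 per parameter on planted samples. Numerical choices:

- **Initialization** (deterministic): μ_low = median, μ_high = 95th
  percentile, both σ = overall sd / 2, weights 0.9/0.1. Quantile
  initialization makes runs reproducible without a random start.
- **Convergence**: relative log-likelihood change < 1e-8 or 500
  iterations. The log-likelihood trace is retained in the results
  object and is non-decreasing (EM guarantee, up to the σ floor).
- **σ floor** 1e-3 score units, preventing singular components.
- **Degeneracy**: component weight < 1e-4 or a σ pinned at the floor at
  convergence flags the fit; up to 5 jittered restarts (seeded) are
  attempted first. Degenerate fits refuse to call targets unless the
  caller opts in with `allow_degenerate=True` — the opt-in exists for
  the exact-arithmetic limit (noise-free scores collapse to two point
  masses whose threshold is still meaningful).
- **Labelling**: the "low" component is the one with the smaller mean;
  mean ties break by smaller σ.
- **Threshold**: μ_low + k·σ_low with k = 3 by default; k is exposed so
  sensitivity analyses around the 3-sd rule are one flag away. Calls
  use strict inequality (Δ > threshold), a measure-zero choice stated
  for bit-exact reproducibility.

Fitting refuses fewer than 50 finite values: below that a two-component
fit is not meaningfully constrained.

The distribution is fitted to replicate-averaged scores (one value per
gene), not per replicate, consistent with reporting a single score per
gene.

## Classification and set statistics

Per-mark call sets combine into presence/absence triples over the
scored-gene universe; classes are mutually exclusive and exhaustive.
For the canonical mark order the three layers of the H3K27me3+ set get
their usual aliases (TP/DP/SP). The universe is the set of genes scored
on the array, not all genome genes — overlaps among assayed genes are
the relevant reference.

The overlap probability of two gene sets is the one-sided upper-tail
hypergeometric probability of observing at least the observed
intersection; the source analyses state only "the probability of the
overlap", so the hypergeometric reading is a documented interpretation,
pinned by an exhaustive-enumeration oracle in the tests. Term
enrichment uses the same hypergeometric model two-sided (doubled
smaller tail, capped at 1) with an over/under direction flag; p-values
are reported raw by default, with Benjamini–Hochberg behind a flag,
because the analogous analyses report raw per-term p-values.

## Expression statistics

Per-gene change is mean(log2 group B) − mean(log2 group A). Per-class
summaries report mean, SD, t-based 95% CI, a one-sample Student's
t-test against zero and pairwise two-sample Student's t-tests with
pooled variance (Welch behind a flag; the classical test is named by
the source analyses). Significance bands follow the dual convention
used there: significant below 0.001, insignificant at or above 0.01,
and results between reported as "intermediate" rather than forced into
either band. Classes with n < 2 report statistics without p-values;
all-equal degenerate inputs report p as undefined. Because the
one-sample-vs-zero and vs-reference-group readings are both plausible,
both tests are emitted, labelled.

Distance stratification measures TSS-to-TSS distance from each
positive gene to its nearest positive neighbour on the same chromosome
(never across chromosomes); singleton-chromosome genes carry a missing
distance and leave the comparison. Genes are grouped at configurable
edges, default <50 kb / 50–200 kb / ≥200 kb — only the 50 kb boundary
is biologically fixed (clustered loci such as Hox), the upper edge is a
default. Group changes are compared by Mann-Whitney U: the exact null
distribution when the combined sample is ≤20 without ties, otherwise
the normal approximation with tie and continuity correction. An
exclusion list supports the sensitivity check of removing clustered
loci (e.g. Hox genes) before grouping.

## Synthetic data

The generator emulates the measurement design, not the instrument:

- Genes are laid out on `n_chromosomes` coordinate lines at
  `gene_spacing_bp` (default 100 kb), strands Bernoulli(½). Probes tile
  [TSS−window, TSS+window] every `probe_spacing_bp` (defaults ±5 kb,
  250 bp — configurable, not claimed as any vendor's design).
- Positive sets per mark are drawn nested by default
  (H2AK119u1 ⊂ Ring1B ⊂ H3K27me3, fractions 0.05/0.10/0.20 — the
  layered occupancy structure of Polycomb domains at roughly the
  proportions such arrays report), and each gene gets a chromatin class
  and a planted expression effect (defaults TP +1.0, DP +0.5, SP +0.25,
  none 0, in log2 units, descending with layer depth).
- Probe signal is simulated directly on the log2 scale (the analysis
  consumes log-ratios only; no intensity-level model): positive genes
  carry amplitude × shape(position) with a Gaussian shape (width 1 kb)
  centred on the TSS by default, a flat shape retained for
  exact-arithmetic tests; amplitude default 2.0 log2 units; i.i.d.
  N(0, noise_sd²) noise per replicate, noise default 0.4; the knockout
  condition keeps `ko_residual_fraction` of the amplitude (default 0;
  1 gives a null experiment where knockout ≡ control).
- A configurable fraction of first-mark positives (default 25%) is
  relocated 30 kb from another positive to exercise the <50 kb distance
  group.
- Expression: per-gene baseline N(7, 1.5²) log2 units; "after" samples
  add the planted class effect; i.i.d. N(0, 0.3²) noise per sample;
  3 samples per group by default (typical expression-array replicate
  counts). The rescue generator plants one effect per genotype on
  mark-positive genes only.
- One master seed; layout, membership, ChIP noise and expression noise
  use sub-seeds spawned deterministically, so identical configs are
  byte-identical and stages can be re-drawn independently.

What the generator does **not** emulate: dye bias, spatial artifacts,
probe GC effects, probe-specific affinity, intensity-dependent
variance, correlated replicate error, expression effect heterogeneity
within a class, or cross-hybridization. Passing tests therefore show
the analysis is correct under its own model assumptions — planted
effects recovered, null rates controlled, exact statistics exact — not
that the thresholds transfer unchanged to vendor arrays.

## Pipeline

`run_pipeline` is a pure function of (config, input files): all
randomness flows from the config seed, floats are written at fixed
precision, and the manifest records a config hash (excluding the
output location) plus per-output SHA-256 checksums, so repeat runs are
verifiably byte-identical. Validation failures occur before any output
is written; a stage failure halts with the stage named.

## Problem sizes and verification

The test suite and acceptance script run the analysis at 10,000 genes
(41 probes per gene, 2 conditions, 2 replicates — 1.6M probe rows per
mark), 20 independent null simulations, and 4,000-gene profile
simulations; these sizes make every planted-truth recovery check well
powered while keeping a full verification run in the low minutes on a
single core. The end-to-end de-repression check evaluates CI coverage
of planted class means over five independent expression-noise
replicates, requiring majority coverage per class: a single 95%
interval misses its target about one run in twenty by construction,
while any estimator bias beyond ~2 SE fails the majority check
reliably, so the test retains its power without testing a coin flip.

## Known limitations

- Exactly two mixture components; no FDR-calibrated alternative to the
  mean+3sd rule.
- Terms are flat labels; no ontology graph propagation.
- The scoring window and the original arrays' probe coverage are
  user-set assumptions, not reconstructions of the vendor design.
- Peak calling outside promoter windows (contiguous genomic segments)
  is out of scope.
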