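# prcmap

Target-gene identification and chromatin-state classification for
ChIP-on-chip promoter arrays, built around the knockout-subtraction /
Gaussian-mixture-threshold approach used to map Polycomb marks
(H2AK119u1, Ring1B, H3K27me3) around transcription start sites in mouse
embryonic stem cells.

## The problem

Promoter tiling arrays report, per probe, a log2 enrichment ratio of
ChIP DNA over input. Deciding which *genes* carry a histone mark from
these noisy probe ratios needs three ingredients this package provides:

1. **Gene-wise scoring.** Probes whose midpoint falls within a window
   around a gene's TSS (default ±5 kb) are aggregated into the
   geometric mean of their enrichment ratios — computed as the
   arithmetic mean of log2 ratios, with replicates averaged per probe
   first. Subtracting the same score measured in cells where the mark's
   writer has been knocked out (Ring1A/B-null for H2AK119u1 and Ring1B,
   PRC2-null for H3K27me3) isolates the depletion-sensitive signal
   Δ_g = score_control(g) − score_knockout(g).
2. **Mixture thresholding.** The distribution of Δ over genes is modelled
   as a two-component Gaussian mixture — background plus enriched —
   fitted by maximum likelihood (EM). Genes above the background
   component's mean + 3 sd are called positive:

   Δ ~ w·N(μ_low, σ_low²) + (1−w)·N(μ_high, σ_high²),  call g ⇔ Δ_g > μ_low + 3σ_low

3. **Layered classification.** Per-mark calls combine into the
   presence/absence classes of the H3K27me3 domain: TP
   (H2AK119u1+ Ring1B+ H3K27me3+), DP (Ring1B+ H3K27me3+) and SP
   (H3K27me3+ only), the three layers whose differential de-repression
   after PRC1 loss is the biological readout.

Downstream statistics cover what such a study reports: per-class
expression changes with t-based 95% CIs and Student's t-tests,
hypergeometric set-overlap probabilities, flat term
over/under-representation, Pearson occupancy correlation, strand-aware
TSS metaprofiles (optionally H2A-normalized), rescue-genotype
restoration histograms, and Mann-Whitney comparisons of de-repression
between genes grouped by distance to their nearest positive neighbour
(<50 kb vs beyond).

Because the original arrays are not required, a first-class synthetic
generator (`prcmap.simulate`) produces probe tables, gene annotations
and expression matrices with planted ground truth, so every stage is
verifiable at desk scale.

## Worked example

```python
import prcmap

cfg = prcmap.SimulationConfig(n_genes=2000, seed=7)
probes, genes, truth = prcmap.simulate_chip_arrays(cfg)
scores = prcmap.gene_scores(probes, genes, window_bp=5000)
delta = scores.differential()

u1 = delta[delta["mark"] == "H2AK119u1"].set_index("gene_id")["delta"]
fit = prcmap.TwoGaussianMixture(u1).fit(seed=7)
print(fit.summary())

calls = fit.call_targets(u1, mark="H2AK119u1")
planted = truth.members["H2AK119u1"]
print(f"\ncalled {len(calls)} genes; {len(calls.positives & planted)} of "
      f"{len(planted)} planted positives recovered")
```

prints

```
Two-Gaussian mixture fit
========================================
n values                           2000
weight (low, high)                 0.9500, 0.0500
mean (low, high)                   -0.0010, 0.4900
sd (low, high)                     0.0606, 0.0634
threshold (mean_low + 3.0 sd_low)  0.1807
log-likelihood                     2368.8619
iterations / restarts              8 / 0
converged / degenerate             True / False

called 102 genes; 100 of 100 planted positives recovered
```

Reading the summary: 95% of genes sit in a background component centred
at ≈0 (their enrichment does not depend on the depleted writer), 5% in
an enriched component at ≈0.49 log2 units — the planted 2.0-amplitude
Gaussian peak averaged over the ±5 kb window. The calling threshold
0.18 recovers all 100 planted positives with 2 false calls.

The same flow runs from the shell:

```bash
prcmap simulate --config sim.yaml --outdir data/
prcmap score --probes data/probes.tsv --genes data/genes.bed --out out/
prcmap call  --scores out/differential_scores.tsv --mark H2AK119u1 --out out/
prcmap run   --config run.yaml        # full pipeline + manifest
```

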