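# schet

Single-cell transcriptomic heterogeneity analysis for spike-in-calibrated
plate/microfluidics experiments: from a genes × cells count matrix to
subpopulations, signed co-expression modules, cross-dataset module
preservation, and a cell-cycle explanation of the dominant axis of
heterogeneity.

## The problem

Cultured cell populations that look homogeneous by surface markers — for
example umbilical-cord-derived mesenchymal stromal cells expanded for
therapy — still show transcriptomic substructure at single-cell resolution.
The questions this package answers are: *which genes vary more than
technical noise allows, do the variable genes organize into reproducible
co-expression modules across donors and passages, and is the dominant
module simply cell-cycle phase?*

The pipeline implements, as reusable and tested components:

- **Normalization** — median-of-ratios size factors
  (s_j = median_g k_gj / (∏_c k_gc)^(1/n), reference genes positive in
  every cell, spike-ins excluded), the low-expression filter (detected in
  ≥ 1/10 of cells and mean ≥ 1 read), and log2(x+1) transformation.
- **Variable-gene detection** — ERCC spike-ins calibrate a technical
  mean–noise trend CV² = a₁/μ + a₀; genes are tested against it with
  T = (n−1)·CV²/trend(μ) ~ χ²ₙ₋₁ (upper tail, Benjamini–Hochberg).
- **Error model / differential expression** — per-gene EM fit of a dropout
  mixture (low-mean Poisson(λ₀) with weight π₀, otherwise negative binomial
  with mean μ·s_j and variance m + φm²), and a likelihood-ratio test of
  shared vs group-specific μ (χ²₁, optional parametric bootstrap).
- **Subpopulations** — hierarchical clustering of cells (1 − Pearson
  correlation, average linkage, silhouette-selected K) and PCA embeddings.
- **Network** — signed adjacency a_ij = ((1+cor)/2)^β with soft power
  β = 12, the topological overlap measure, dynamic-hybrid-style module
  detection on the 1 − TOM dendrogram, module eigengenes, module–subcluster
  significance, eigengene correlations, intramodular connectivity (kWithin)
  hub ranking, and top-150-edge export for network viewers.
- **Preservation** — permutation Z-summary (mean of density and
  connectivity component Zs against random same-size gene sets);
  Zsummary ≥ 10 is the conventional strong-preservation bound.
- **Cell cycle** — G1/S and G2/M signature scores by expression-binned
  control pools, noncycling/cycling classification, and Fisher-exact
  association of individual genes with the G2/M phase.
- **Screening & enrichment** — the three-criterion featured-gene screen
  (subcluster-specific overexpression; replicated in ≥ 2 datasets; on the
  cell-surface list) and hypergeometric gene-set over-representation with
  BH control.
- **Synthetic data** — a generator with planted cell-cycle phases, an
  anti-correlated immune module, spike-ins, NB noise and logistic dropout,
  returning full ground truth for parameter-recovery testing.

## Worked example

Simulate a dataset (100 cells × 1,000 genes, 92 spike-ins, planted
cell-cycle and immune modules) and run every stage:

```sh
schet --outdir sim simulate --n-cells 100 --n-genes 1000 --seed 7
schet --outdir run --seed 7 run-all sim/counts.tsv --genesets sim/genesets.tsv
```

Printed summary of the run directory:

```
HVGs: 158 of 1000                 # genes above the spike-in noise trend
trend: a1 = 1.42, a0 = 0.101      # fitted technical CV^2 = a1/mu + a0
turquoise  group2: r = 0.89, p = 1.8e-35
blue       group2: r = -0.88, p = 4.7e-34
eigengene corr turquoise-blue: -0.89
phase calls: 68 G1/S, 32 G2/M
```

Reading the numbers: the spike-in trend says a typical gene carries ~10%
squared technical coefficient of variation plus shot noise; 158 genes
exceed it significantly. Hierarchical clustering finds two subpopulations,
and the largest co-expression module (`turquoise`, the planted cell-cycle
module) is almost perfectly aligned with subcluster 2 (r = 0.89) while the
second module (`blue`, the planted immune module) is anti-correlated with
the same cells — the turquoise–blue eigengene correlation of −0.89
reproduces the inverse cycle/immune relationship the analysis is designed
to expose. The cell-cycle scores classify roughly the planted fraction of
cells as G2/M.

Per-stage outputs (size factors, HVG table, clusters, module assignments
with kWithin, eigengenes, module–trait table, edge list, preservation
Z-summaries, cell-cycle scores, featured-gene report, enrichment table)
are plain TSV files under the output directory, with a `run_log.json`
recording the seed, every parameter and a config hash.

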