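# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical choices that matter when reading results.

## Normalization

Size factors are classic median-of-ratios: the reference for gene g is its
geometric mean across cells, and s_j is the median over reference genes of
k_gj divided by that reference. Reference genes must be strictly positive
in every cell; spike-ins are excluded by default because their abundance
tracks capture efficiency rather than biological depth (configurable).
Factors are identified only up to a global constant, so they are rescaled
to geometric mean 1 for cross-run comparability; relative factors are
exactly equivariant under per-cell count scaling when the reference set is
unchanged. The low-expression filter operationalizes "detected in at least
1/10 cells and average 1 reads per cell" as: raw count > 0 in at least
⌈n/10⌉ cells AND mean raw count ≥ 1 (both boundaries inclusive); it is
applied to raw counts, since the rule is phrased in reads. All correlation
and PCA work downstream uses log2(x+1) of normalized values.

## Technical-noise trend and variable genes

Spike-ins calibrate CV² = a₁/μ + a₀ via iteratively reweighted least
squares on (1/μ, CV²) with weights 1/fitted², the right scale for the
multiplicative sampling noise of a CV² estimate. At least 5 usable
spike-ins are required: a 3-point dilution series (as spike-in sets named
"1, 4, 7" suggest) cannot support a stable two-parameter fit. A negative
â₁ is clamped to 0 with a warning. Genes are tested with
T = (n−1)·CV²/trend(μ) against the upper tail of χ²ₙ₋₁ with BH control
(default FDR 0.1); genes with zero mean get p = 1, and only genes passing
the low-expression filter are eligible for flagging.

**Known limitation.** The χ²ₙ₋₁ reference assumes the sample variance has
Gaussian-like sampling behavior. For overdispersed counts the sample CV²
has excess kurtosis (≈ 6φ plus 1/μ terms), so far-tail p-values are
anticonservative by a factor of roughly 3 at p ≈ 10⁻³ under the
generator's technical-noise model. In practice the test's sensitivity for
genuinely variable genes is high (≈ 0.96 on the planted benchmark) and the
full-null call rate at FDR 0.1 is far below nominal (< 1%), but the
empirical FDR in a sparse-signal regime (50 true positives among 2,000)
runs near 0.24 rather than the nominal 0.1–0.15. Users who need strict FDR
control should treat the HVG set as a ranking, not a calibrated discovery
set.

## Dropout-mixture error model and differential expression

Each gene's counts follow π₀·Poisson(λ₀) + (1−π₀)·NB(μ·s_j, φ) with
variance m + φm² for the NB component. λ₀ is fixed at 0.1 (estimating it
per gene is unidentifiable at ~50 cells); φ has a floor of 10⁻⁴ to avoid
the Poisson boundary. The EM M-step solves the weighted NB mean by damped
Newton in log μ (the score in log μ is monotone) and profiles log φ by
bounded scalar minimization, refreshed every fifth sweep after the first
five since it moves little; any M-step that fails to improve the
observed-data likelihood terminates the fit, so the log-likelihood trace
is non-decreasing by construction. An all-zero gene returns the degenerate
π₀ = 1 fit, flagged but not an error.

DE between two cell groups is a likelihood-ratio test of shared-μ vs
group-specific-μ (π₀, φ, λ₀ shared), referred to χ²₁; log2FC =
log2(μ̂_A/μ̂_B). This replaces the full Bayesian machinery of the original
single-cell error-model approach with its testable core: the mixture
family and a p < 0.05 decision rule. Measured type-I fraction at α = 0.05
on identical groups is ≈ 0.05–0.075, inside the accepted [0.01, 0.10]
band, and pooled null p-values are not anticonservative by KS. A seeded
parametric bootstrap of the null fit is available where the asymptotic
χ²₁ is doubted.

## Subpopulations

Cells cluster on HVG log values standardized per gene (z-scores across
cells) — without standardization the shared baseline expression profile
dominates cell–cell correlations. Distance is 1 − Pearson over HVGs,
average linkage; K defaults to the maximum-silhouette cut in 2..8. Group
ids are size-ordered for stable reporting. PCA uses centered log values
with a deterministic sign convention (largest-magnitude loading positive).

## Signed network and modules

Adjacency a_ij = ((1 + cor)/2)^β with β = 12, the standard signed form;
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij). Module
detection is a documented simplification of the dynamic hybrid cut:
average-linkage clustering of 1 − TOM, a static cut at a fraction of the
merge-height range (0.98 − 0.03·deep_split; 0.92 at the default
deep_split 2), branches of at least min_module_size (default 30) become
modules, and unassigned genes whose correlation with a module eigengene
exceeds 0.3 are pulled in (the PAM-like stage). The cut fraction was set
from the geometry of planted-block benchmarks: true modules complete their
merges early in the height range while unstructured genes merge in a
narrow band near the maximum height, so any cut in the wide gap between
works; 0.92 sits safely inside it. Eigengenes are first principal
components of standardized module gene profiles, oriented to correlate
positively with their genes. Module display names are size-ordered from
the conventional palette (largest "turquoise", second "blue", ...), making
names deterministic. Module–subcluster significance is the Pearson r of an
eigengene against a one-hot group indicator with the Student-t p
(n−2 df); single-cell groups are reported missing.

## Module preservation

Four component statistics are computed for each reference module in the
test dataset: meanCor (mean off-diagonal correlation), meanAdj (mean
signed adjacency) — the density pair — and cor.kIM (cross-dataset
correlation of intramodular connectivity) with cor.cor (correlation of
vectorized module correlation matrices) — the connectivity pair. Each is
standardized against n_perm (default 200) random same-size gene sets drawn
without replacement from the shared gene universe, excluding the module's
own genes; Zdensity and Zconnectivity are the medians of their pairs and
Zsummary their mean. The null is not expression-matched to the module — a
documented simplification; on the planted benchmarks, density Zs carry the
signal (connectivity Zs hover near zero for homogeneous modules, which
also happens with the full published composite). The reference/test
orientation is explicit in the API and recorded in outputs.

## Cell-cycle scoring

Signature scores use expression-binned control pools: genes are ranked by
mean log expression into 25 equal-occupancy bins; a signature gene's
relative expression is its log value minus the per-cell mean of the
non-signature genes in its bin; a cell's score is the mean over the set,
centered to zero across cells. Scores are exactly invariant to adding a
per-cell constant to log values and to pure depth changes. Classification:
noncycling if both scores ≤ 0 (the configurable threshold), otherwise the
argmax phase with ties toward G1/S. Editable default G1/S and G2/M gene
lists (human symbols) ship with the package; tests use the generator's
planted sets so nothing depends on the shipped lists. Phase-call accuracy
against planted truth treats predicted {noncycling, G1/S} as the
non-G2/M side, since the generator's truth has no cycling-intensity axis.
Gene–phase association splits cells at a gene's upper-quartile expression
and tests the 2×2 table against G2/M membership by two-sided Fisher exact.

## Screening and enrichment

Candidates are genes of the two largest modules of any dataset. Criterion
1 requires one-vs-rest overexpression (BH q < 0.05, positive log2FC) in
exactly one subcluster of a dataset — q rather than raw p is a deliberate,
configurable tightening. Criterion 2 requires that support in ≥ 2
datasets; criterion 3 requires membership in the user-supplied surface
list, which is never hard-coded. Near-misses are reported with the failed
criterion. Over-representation is the classic upper-tail hypergeometric
test per term with BH control and a corrected-p < 0.05 rule; term
dependency handling (elimination-style algorithms) is out of scope.

## Synthetic data

The generator emulates a microfluidic-capture experiment: defaults of 50
cells, 5,000 genes and 92 spike-ins mirror the study scale; recovery tests
and the pipeline demo use an explicit 200 × 2,000 configuration for
statistical headroom. Expected values are baseline_g · s_c ·
2^(effect·weight): cell phases are drawn from (G0/G1, S, G2/M) proportions
(0.60, 0.15, 0.25); cycle-module genes gain +1.5 log2 units in G2/M (half
in S, so the two-score plane is a continuum), immune-module genes lose 1.0
log2 unit in G2/M — producing the inverse cycle–immune correlation the
network analysis recovers. Baselines are lognormal with log2 mean 4.0 and
SD 2.0, matching deep full-length single-cell libraries (million-read
scale over a few thousand expressed genes); the NB dispersion 0.1 is
technical capture noise of the magnitude spike-in calibrations typically
show. Dropout mixes in Poisson(0.1) with logistic probability decreasing
in log2 expected value (midpoint 1 count, unit slope). Spike-ins have
fixed concentrations scaled by the cell's depth factor and no phase
effect. An optional knob plants "variable" background genes with extra
lognormal heterogeneity (SD 1.0 in log2) for variable-gene recovery tests.

What the generator does **not** emulate: batch and chemistry effects, gene
length bias, UMI structure, doublets, ambient RNA, or correlated biological
programs beyond the two planted modules. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to every artifact of real data.

## Determinism and numerical conventions

All sampling flows through seeded `numpy.random.Generator` instances;
permutation nulls and bootstraps take explicit seeds. Pipeline TSVs are
written with a fixed float format (%.10g), so a fixed seed and fixed
inputs give byte-identical outputs. Correlations are clipped to [−1, 1];
zero-variance genes get zero correlation (with a warning) rather than NaN;
TOM of a complete unit-weight graph is exactly 1. Tie-breaks: top edges by
lexicographic gene ids; classification ties toward G1/S; cluster and
module labels ordered by decreasing size.
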