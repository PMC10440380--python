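# Methods

`nashtx` implements the statistical core of an early-vs-late western-diet
liver transcriptome analysis: a 2×2×2 mouse feeding study (diet ∈ {LFD,
WD}, time ∈ {1, 40} weeks, sex ∈ {F, M}) profiled by bulk RNA-seq, combined
with a reanalyzed single-cell liver atlas used to attribute bulk expression
changes to cell types. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data can and cannot
show.

## Bulk screens

**Normalization.** Counts are quantile-normalized: every sample's sorted
expression vector is replaced by the mean sorted vector across samples.
Ties within a sample receive the mean of the reference values over the tied
rank block (the `ties="average"` convention). One consequence worth knowing:
a tied column's sorted vector is the tie-averaged reference, so the "all
sorted columns identical" property holds exactly only for tie-free data.
Values then move to log2 scale with a pseudocount (default 1.0, standard
for count data with zeros).

**Per-timepoint differential expression.** WD vs LFD at each timepoint,
sexes pooled as replicates. The test is Welch's unpaired t-test on log2
values — robust to the mild variance heterogeneity that survives quantile
normalization. Fold change is `2^(mean_log2_WD − mean_log2_LFD)`. A gene is
called **up** when fold change ≥ 2 and BH q ≤ 0.1, **down** when fold
change ≤ 0.5 and q ≤ 0.1 (both gates inclusive). Genes with zero variance
in both groups get p = NaN, are excluded from the BH ranking and reported
`ns` with a logged count. BH correction is run separately per timepoint
(each screen is an independent comparison).

**Diet × time interaction.** Per gene, a fixed-effects 2×2 ANOVA on log2
expression. The interaction is tested through its cell-mean contrast
`L = (WD40 − LFD40) − (WD1 − LFD1)` with

    F = L² / (MS_within · Σ 1/n_ij),   df = (1, N − 4),

which is exact for balanced and unbalanced designs, equals the squared
regression t for the interaction coefficient, and coincides with the Type
II/III sum of squares for the highest-order term (cross-checked in the test
suite against `statsmodels` `anova_lm`). Genes with zero within-cell
variance get F = NaN.

**BH step-up.** `q_(i) = min_{j≥i}(p_(j)·m/j)` capped at 1, NaN passed
through and excluded from `m`, ties broken by input position for
reproducibility. One implementation serves the DE, interaction, marker and
enrichment screens.

**Progressive genes.** Genes induced early and strongly upregulated late:
interaction q ≤ 0.1 (inclusive) with log2FC strictly > 0 at 1 week and
strictly > 1 (fold change > 2) at 40 weeks. The fold-change gates are
strict and the FDR gate inclusive.

## Cluster summaries

Per-gene expression is collapsed to geometric means over the four diet-time
groups, computed as `2^(mean log2(v + pc)) − pc` floored at 0. Profiles are
z-scored per gene by default (so clusters capture shape rather than
magnitude; genes with flat profiles map to the zero profile) and clustered
with k-means (k = 8 default, Lloyd + k-means++, best of 10 restarts,
seeded). No canonical cluster numbering exists for k-means output, so
clusters are relabeled 1..k by descending size with ties broken by
the smallest member gene id — a pure permutation, asserted in tests.

Each cluster is then summarized as one value per group. The default
statistic is the **median** of the member genes' geometric means (robust
to the skew of expression values; `mean` and `sum` are selectable). Even-sized medians are midpoints; empty clusters produce a NaN
row with a warning.

## Single-cell markers

The reanalysis pipeline is the de facto standard: cell/gene detection
filters → per-cell library-size normalization to 10,000 counts
("normalized UMI") → log1p → top-2,000 dispersion-ranked highly variable
genes → 30-component PCA → either Leiden community detection on a 15-NN
graph or k-means (the dependency-light fallback). All steps are seeded and
deterministic.

A gene is a **marker** of cluster c when

1. its mean normalized UMI in c exceeds `umi_min` (default 1.0 — applied on
   the per-cell-scaled values, not log values),
2. the one-sided Wilcoxon rank-sum test of c vs all other cells is
   significant at BH q ≤ 0.05 (corrected within each cluster's screen), and
3. log2((mean_in + ε)/(mean_rest + ε)) ≥ 1, with ε = 1e-9 guarding empty
   denominators.

With the **uniqueness guarantee** (default on), a gene is retained only if
it is a candidate in exactly one cluster *and* its mean stays at or below
`umi_min` in every other cluster — the strictest reading of "uniquely
expressed", chosen because it prevents double assignment downstream.
Raising `umi_min` can therefore only shrink the catalog (tested across a
grid). Clusters with fewer than two cells are excluded from testing with a
warning, but their means still count against other clusters' uniqueness.
Sub-populations (e.g., macrophage subtypes) are obtained by re-running the
clustering on one parent cluster's cells; subcluster labels are namespaced
`parent/sub_i` and all other labels are untouched. Cell-type names are
always user-supplied; the package never infers biological identity.

## Cell-type assignment

A bulk gene maps to the cell type owning it in the marker catalog;
otherwise it is `unassigned`, with `not_measured` as a distinct reason for
genes absent from the single-cell gene universe. Non-unique catalogs
resolve ties by highest log2FC-vs-rest, then lexicographic type name
(logged). Summaries report counts and percentages per type under a
declared denominator — all queried genes (default, the bar-plot convention)
or assigned genes only; both are available because the two conventions give
visibly different percentages on real data.

## Enrichment

**ORA** is a one-sided hypergeometric tail `P(X ≥ k)` over an explicit
background, BH-corrected across sets; sets disjoint from the background are
skipped with a warning. **Preranked GSEA** uses the classic weighted
running sum: hits incremented by `|score|^w / Σ_hits|score|^w` (w = 1
default), misses decremented by `1/(N−K)`; ES is the maximum signed
deviation. Significance comes from gene-label permutations (phenotype
permutation is impossible for preranked input): NES = ES / mean |ES| of
same-sign permutations, p = (1+b)/(1+m) over same-sign permutations. A set
covering the entire ranked list has no misses and raises an error; sets
below the minimum usable size (3) are skipped with a warning rather than
aborting a whole analysis over one stale collection entry. The platform
concordance helper reports Pearson and Spearman correlation with two-sided
p-values on paired vectors, as given (log-transform upstream when
comparing platforms on log scale).

## Synthetic data

The bulk generator reproduces the target design's sampling frame: 4 LFD
and 8 WD
animals per sex per timepoint (48 samples). Counts are negative binomial
with mean `2^(baseline + shift) · s_j` and variance `μ + αμ²`: baseline
log2 means uniform on (3, 9), shared dispersion α = 0.1, and per-sample
library factors log-normal with log-sd 0.2 (exercising the normalization).
Effects are additive on log2: main diet effects (default 1.0 log2,
random sign, 10% of genes) shift both WD cells; interaction effects
(default +2.0 log2, 10% of genes) shift only the WD-40wk cell — a diet
response that emerges with feeding duration. A truth ledger records flags
and true log2 fold changes per gene; the flagged counts are exact
(`round(frac·n_genes)`), and every generator is a pure function of its
config including the seed.

The single-cell generator plants `markers_per_type` disjoint marker genes
per type. Markers get a deliberately low baseline (`marker_baseline_umi`,
0.4 normalized UMI at scale 10⁴) and `marker_fold` × baseline (default 8)
in their own type only; this is what makes a gene *cell-type-unique* — a
marker with a typical baseline (~6 normalized UMI) everywhere could never
satisfy the uniqueness rule's "≤ umi_min in all other clusters" condition.
Library sizes are log-normal around 5,000 UMIs; counts are NB with
dispersion 0.2. `simulate_linked` runs both generators over one gene
universe and makes the planted markers the bulk interaction genes, so the
whole bulk→marker→assignment chain can be scored against ground truth.

**What the generators do not emulate:** batch structure, sex-specific
effects (sexes are generated but carry no effect), gene-gene correlation,
ambient RNA, doublets, or zero inflation beyond what NB sampling produces.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the declared noise model, not performance on real tissue.

## Statistical behavior worth knowing

* **FDR control.** On additive log2 Gaussian data (the regime of the
  calibration experiments: 2,000 genes, 6 samples per cell, noise sd 0.5,
  10% planted 1.0-log2 interactions) the BH-corrected interaction screen's
  mean false-discovery proportion is ≈0.089 at q ≤ 0.1 and ≈0.9% at
  q ≤ 0.01 — at the theoretical value π₀·q. At the strict cutoff only a
  couple of discoveries survive per replicate, so the per-replicate FDP is
  heavy-tailed and its average needs thousands of replicates to stabilize;
  the acceptance experiments use 10,000 (script) and 1,000 with an explicit
  Monte-Carlo-error allowance (tests).
* **Composition bias.** On the NB generator with planted effects, the
  same screen's FDP after quantile normalization is ~0.2: when 10% of
  genes gain 4-fold in one cell, forcing identical per-sample
  distributions shifts every null gene in that cell, creating spurious
  opposite-direction interactions. This is a property of quantile (and
  total-count) normalization under asymmetric DE, shared by any pipeline
  built on it; sensitivity is unaffected (0.96 for 2.0-log2 effects at
  dispersion 0.1). Offset-based normalizations (e.g., median-of-ratios)
  mitigate this but are deliberately out of scope.

## Problem sizes in the test suite

Simulated instances are sized for interactive runs: bulk fixtures of
500–2,000 genes × 48 samples, single-cell fixtures of 2–3 types × 50–150
cells × 300–1,500 genes, and 1,000–10,000 replicate calibration runs of the
vectorized interaction screen. These sizes are the package's own choices;
all thresholds and effect sizes are the defaults stated above.

## Known limitations

* The DE engine is Welch's t-test, not an empirical-Bayes moderated test;
  with 8–16 samples per group moderation would add little, but at smaller
  n the variance estimates are noisy.
* Quantile normalization's composition bias (above) inflates the
  interaction screen's false discoveries when a large asymmetric fraction
  of the transcriptome responds.
* Marker derivation assumes the normalized-UMI floor is meaningful on the
  per-cell-scaled (not log) scale; deeply sequenced datasets may need a
  different `umi_min`.
* Percentages in assignment summaries depend visibly on the denominator
  convention; both are reported and neither is privileged.
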