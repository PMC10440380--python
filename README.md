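# nashtx

Tools for analyzing early-vs-late diet-induced changes in the liver
transcriptome, written for the common NASH study design: mice fed a
western diet (WD) or a low-fat control diet (LFD), sampled early (1 week)
and late (40 weeks), with bulk RNA-seq on all groups and a single-cell
liver atlas available for cell-type attribution.

The package chains six analysis stages behind one library / CLI surface:

1. **Normalization** — quantile normalization of the count matrix, then
   log2 with a pseudocount.
2. **Per-timepoint DE** — Welch's unpaired t-test, WD vs LFD with sexes
   pooled; a gene is called at fold change ≥ 2 (up) or ≤ 0.5 (down) with
   Benjamini–Hochberg FDR ≤ 0.1; overlap bookkeeping across timepoints.
3. **Diet × time interaction screen** — per-gene fixed-effects 2×2 ANOVA;
   the interaction F is the squared cell-mean contrast
   `L = (WD₄₀−LFD₄₀) − (WD₁−LFD₁)` over `MS_within·Σ1/nᵢⱼ` on (1, N−4)
   degrees of freedom, BH-corrected.
4. **Cluster summaries** — per-group geometric means of the interaction
   genes, k-means (k = 8) on row-standardized profiles, and one median
   value per cluster and group.
5. **Single-cell markers and assignment** — filter → counts-per-10k
   normalization → log1p/HVG/PCA → Leiden or k-means clustering;
   cell-type-unique marker genes (mean normalized UMI > 1.0, one-sided
   Wilcoxon rank-sum BH q ≤ 0.05, log2FC ≥ 1 vs rest, expressed above the
   floor in no other cluster); bulk genes are then assigned to the cell
   type owning them in the catalog.
6. **Enrichment** — hypergeometric over-representation against GMT gene
   sets, preranked GSEA with a gene-label permutation null, and a
   Pearson/Spearman concordance helper for cross-platform checks.

A seeded synthetic-data module generates matched bulk (negative-binomial
counts on the study's 4 LFD / 8 WD per-sex-per-timepoint frame, with
planted main and interaction effects) and single-cell (clustered UMIs with
planted cell-type-unique markers) datasets plus a ground-truth ledger, so
every stage is testable without any download. See `docs/methods.md` for
models, assumptions and limitations.

## Worked example

```python
import nashtx as nx

bundle = nx.simulate_linked(
    nx.BulkSimConfig(n_genes=2000, seed=1),
    nx.ScSimConfig(n_genes=2000, seed=1),
)
expr = nx.log2_transform(nx.quantile_normalize(bundle["bulk_counts"]))
de1  = nx.de_per_timepoint(expr, bundle["design"], time=1)
de40 = nx.de_per_timepoint(expr, bundle["design"], time=40)
overlap = nx.overlap_sets(de1, de40)

inter = nx.interaction_test(expr, bundle["design"])
sig = list(inter.index[inter["q_value"] <= 0.1])

cat = nx.derive_markers(nx.normalize_umis(bundle["sc_counts"]),
                        bundle["sc_labels"])
assignment = nx.assign_genes(sig, cat,
                             sc_universe=set(bundle["sc_counts"].gene_ids))
summary = nx.assignment_summary(assignment)
```

printing, for this seed:

```
1 wk:  96 DE genes (51 up, 45 down) = 4.8% of universe
40 wk: 283 DE genes (210 up, 73 down) = 14.2% of universe
common to both timepoints: 41
interaction screen: 262 genes at q <= 0.1 (196/200 planted recovered)
marker catalog: 80 unique markers across 4 cell types
  type2          20 genes    7.6%
  type3          20 genes    7.6%
  type4          19 genes    7.3%
  type1          19 genes    7.3%
  unassigned    184 genes   70.2%
```

Reading it: of 2,000 simulated genes, the early screen calls 96 and the
late screen 283, with 41 genes responding at both timepoints; the
interaction screen recovers 196 of the 200 planted diet×time genes; the
marker catalog recovers the 80 planted cell-type-unique markers (20 per
type), and the interaction genes that originate from a planted cell type
are assigned back to it, while genes with no cell-type origin remain
unassigned.

The same flow runs from the shell:

```sh
nashtx simulate --outdir fixture --n-genes 2000 --seed 1 --sc
nashtx de --counts fixture/bulk_counts.tsv --design fixture/design.tsv \
          --time 40 --out de_40wk.tsv
nashtx run --config config.yaml     # full pipeline from a YAML config
```

Every stage writes plain TSVs plus a `run_manifest.json`; identical
config + seed reproduces byte-identical outputs.

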