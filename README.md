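# iratri

Predicting immune-checkpoint-blockade (ICB) response from single-cell
transcriptomes and paired TCR repertoires of four immunotherapy
response-associated T cell (IRAT) subsets.

## The problem

Many cancer patients do not benefit from ICB therapy, and biomarkers that
generalize across cancer types are scarce. Four tumor-infiltrating T cell
subsets track ICB outcome consistently across cancers: CD4+ CXCL13+ Tfh
and CD8+ CXCL13+ T cells expand in responders (the tumor-suppressive, TS,
group), while CD4+ TGF-β1+ T and CD8+ Temra cells expand in non-responders
(the tumor-promoting, TP, group). `iratri` implements, as a tested and
reusable pipeline, a response-prediction procedure built on these subsets:

1. **QC and normalization** — cells with <200 or >6000 detected genes or a
   mitochondrial fraction above threshold are removed; counts are CP10K
   log-normalized: `x = ln(1 + 10⁴·c/C)`.
2. **Responder pathways** — per cancer type and IRAT subset, a two-tailed
   Wilcoxon rank-sum test (one group vs rest) yields Bonferroni-significant
   genes ranked by decreasing average log2FC; a preranked GSEA (weighted
   Kolmogorov–Smirnov running sum, weight exponent 1) with a permutation
   null selects pathways positively and significantly enriched in
   responders above the non-responder enrichment.
3. **GSEA index** — per sample and IRAT subset, the sum of enrichment
   scores ES of the selected pathways on that sample's own
   IRAT-vs-rest ranking.
4. **Response-specific TCRs** — paired-chain clonotypes (CDR3α|CDR3β amino
   acids; single-chain cells discarded) are compared across groups:
   `R-specific = R \ (NR ∪ naive ∪ normal)` and symmetrically. The clonal
   FC index per sample and subset is
   `log2((F_R + ½)/(F_NR + ½))`, F counting cells bearing R-/NR-specific
   clonotypes.
5. **Classifier** — the 8 features (GSEA + clonal FC index × 4 subsets)
   feed a binomial GLM with elastic-net penalty (α = 0.3, λ by 10-fold
   cross-validated deviance), evaluated over 100 stratified 70/30 resplits;
   final classes by majority vote (ties → non-responder).
6. **Response Index** — per sample,

   RI = | Σ_TS F_R/F_NR / Σ_TP F_R/F_NR | × ( Σ_TS Σ_l ES_l + Σ_TP Σ_n ES_n )

   the product of the composite clonal FC and composite GSEA indices.

Real cohorts are not required: a first-class synthetic-data module
generates multi-cancer cohorts (negative-binomial expression, paired TCR
contigs, GMT gene sets) with planted pathway effects and group-exclusive
clonal expansion, so every stage can be validated against ground truth.

## Worked example

```python
from iratri import PipelineConfig, SimConfig, run_pipeline

config = PipelineConfig(sim=SimConfig(seed=1), seed=1)
summary = run_pipeline(config, "runs/demo")
print(summary["mean_auc"], summary["confusion"]["accuracy"])
print(summary["median_ri_responder"], summary["median_ri_nonresponder"])
```

On the default synthetic cohort (2 cancer types; 20 R + 20 NR
post-treatment samples plus treatment-naive and normal samples; 500
cells/sample; planted TS-pathway effect of 1 log2 unit and response-specific
clonal expansion) this prints:

```
1.0 1.0
6.191591683887404 0.3876993461313508
```

i.e. the bootstrapped classifier separates responders from non-responders
perfectly (mean AUC and majority-vote accuracy 1.0), and the median RI of
responders (6.19) sits far above non-responders (0.39; one-sided
Mann–Whitney p = 3.4e-08 in `summary["ri_mannwhitney_p"]`). The run
directory holds every intermediate: QC report, selected pathways, per-sample
GSEA and clonal FC index tables, per-round model results, and the RI table.

The same pipeline is scriptable from the shell:

```
irat-ri simulate --seed 1 --out fixture/
irat-ri run --seed 1 --out runs/demo
```

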