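# Methods

This note documents the statistical procedures implemented in `iratri`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not demonstrate.

## Quality control and normalization

A cell is retained iff `min_genes ≤ detected ≤ max_genes` (detected =
genes with count > 0; defaults 200 and 6000) and its mitochondrial
fraction — raw mitochondrial counts over raw total counts, genes matched
by a configurable prefix, default `MT-` — is at most `max_mito_fraction`
(default 0.30; 0.10 is the conventional stricter choice for public data).
Boundary values are retained: only strict violations remove a cell. When
no gene matches the prefix, the mitochondrial criterion is skipped with a
warning. QC is idempotent.

Normalization is counts-per-10,000 with natural log1p:
`norm[g,c] = ln(1 + 10⁴·count[g,c]/Σ_g count[g,c])`. Zero-total cells are
an error naming the barcode. The transform preserves sparsity and is
rank-preserving within a cell, and commutes with cell subsetting.

Doublet removal, batch integration, clustering and annotation are out of
scope: the pipeline consumes pre-labeled cell types (synthetic truth or a
user-supplied annotation column).

## Differential expression

One-group-vs-rest two-sided Wilcoxon rank-sum on the normalized layer.
When both groups have ≤ 10 cells the p-value is computed by exhaustive
enumeration of all C(n₁+n₂, n₁) group assignments of the pooled ranks
(valid under ties), with the two-sided convention
`p = min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. Larger groups use the normal
approximation with tie correction and a 0.5 continuity correction; at ~12
cells per group the two agree to well under 0.01 on continuous data.
All-constant genes get p = 1 and log2FC = 0. Both Bonferroni and
Benjamini–Hochberg (step-up) adjusted columns are emitted; the
model-construction path retains genes at Bonferroni-adjusted p < 0.05.

The effect size is `avg_log2fc = log2((mean expm1(norm) in + ε) /
(mean expm1(norm) out + ε))` with ε = 1e-9 — note the tiny pseudocount
deliberately lets genes absent from one group reach large magnitudes,
which only affects ranking order at the extremes.

Ranked lists sort retained genes by decreasing avg_log2fc, ties broken
lexicographically by gene identifier so rankings are deterministic.

## Preranked GSEA

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum with weight exponent 1: walking the ranked list, a hit advances the
sum by |score| normalized to the in-set total (uniform weights when all
in-set scores are zero) and a miss retreats by 1/(N − m). ES is the
signed maximum deviation from zero; when the positive and negative
extremes tie exactly in magnitude the positive one is reported. The
implementation evaluates only the 2m candidate extremes (immediately
after/before each hit), which is algebraically identical to the full
N-step walk; tests compare it against a brute-force walk.

Significance uses a gene-set resampling null: `n_perm` random same-size
sets drawn from the ranked genes, two-sided on |ES|, with the plus-one
estimator `p = (1 + #{|ES_null| ≥ |ES_obs|})/(1 + n_perm)`. The default is
10,000 permutations; the pipeline caches the null per (ranking, set size)
since equal-size sets share it. This null conditions on the observed
ranking, which is the appropriate question here (is this *set* unusual on
this ranking), and avoids re-running the differential expression per
permutation.

Pathway selection, per cancer type and IRAT subset: a pathway is selected
iff its responder-group enrichment has p < 0.05, ES > 0, and exceeds the
non-responder ES for the same pathway (a pathway absent on the
non-responder side contributes ES 0). Selection is strictly per cancer
type; an empty selection is legitimate and yields a zero GSEA index.

### Per-sample GSEA index

The cohort-level selection yields pathways per (cancer, subset), but the
classifier needs one observation per sample. The index for sample s and
subset k is the sum of ES of the selected pathways evaluated on sample
s's own ranking — all genes ranked by avg_log2fc of s's subset-k cells
against s's other cells (no significance filter at this level: with a few
dozen cells per subset per sample a Bonferroni filter would empty the
list, and the ES only needs a ranking). Samples with fewer than
`min_cells` (default 10) subset cells get a missing index, later imputed
at the feature stage. This is the one construction that honors both "sum
of ES over selected pathways" and "one observation per sample"; it is a
design decision, not a uniquely determined reading.

## TCR repertoires

A clonotype is the pair of CDR3 amino-acid sequences of a cell's TRA and
TRB chains, keyed `"α|β"`. Cells missing either chain are discarded and
counted. Cells with multiple contigs per chain keep the lexicographically
smallest CDR3 — a deterministic stand-in for UMI-based picking, which the
synthetic data do not model. V/J gene calls are ignored. Contig tables in
both the 10x (`barcode, chain, cdr3`) and AIRR (`cell_id, locus,
junction_aa`) dialects are auto-detected.

Response-specific repertoires per cancer type:
`r_specific = R \ (NR ∪ naive ∪ normal)`, symmetrically for `nr_specific`,
where R/NR are post-treatment labeled samples, naive the pre-treatment and
normal the normal-tissue repertoires.

The clonal FC index for a cell type, per sample, counts cells bearing
responder-specific (F_R) and non-responder-specific (F_NR) clonotypes and
reports `log2((F_R + ½)/(F_NR + ½))` — a Haldane pseudocount of ½ on both
proportions keeps the index finite when one side is zero. Cells (not
unique clonotypes) are counted by default, consistent with clonal
*frequency*; a unique-clonotype mode is available. Units with no
specific-bearing cells get a missing index.

Cohort-level expansion comparisons use the two-sided Fisher exact test on
the 2×2 (specific-bearing × response group) table and Welch's t-test on
per-cell clonal-frequency vectors, BH-corrected across cell types.

## Response classifier

Features: per post-treatment labeled sample, {GSEA index, clonal FC
index} × four IRAT subsets = 8 columns; label 1 = responder. Features are
standardized to zero mean and unit variance; missing entries are imputed
as the training mean (0 after standardization) and flagged.

The model is a binomial GLM with elastic-net penalty in the glmnet
parameterization, `(1/n)Σ −ℓᵢ + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)`, mixing α = 0.3
(30% lasso / 70% ridge). λ is chosen on a 100-point log grid descending
four decades from λ_max = max|Xᵀ(y − ȳ)|/(nα) by 10-fold
label-stratified cross-validated binomial deviance (fold count reduced
with a warning when a class is smaller than the fold count; no 1-SE
rule). The solver is the standard IRLS + cyclic coordinate descent with
soft thresholding, warm-started along the path; the kernel is JIT
compiled. At λ → 0 it reproduces the unpenalized IRLS solution to ~1e-6,
and at matched λ it agrees with an independent saga-based solver to
~1e-9 (both are test assertions).

Evaluation: 100 rounds of stratified random 70/30 resplits (resplitting,
not resampling with replacement). Each round re-standardizes on its
training samples (leak-free), refits the CV'd model, scores the held-out
30%, and records the round AUC (Mann–Whitney pair-ordering probability,
ties ½) and hard predictions at probability 0.5. Rounds with a
single-class test set contribute predictions but no AUC. Final classes by
majority vote: responder iff strictly more than half of a sample's
held-out predictions are 1 — an exact 50/50 tie is a non-responder call.
A sample never drawn into any test set is classified by a model refit on
all data and flagged. Confusion statistics (accuracy, sensitivity,
specificity, precision, Cohen's κ) are computed from the voted classes.
Feature weightage is the mean across rounds of the absolute
standardized-scale coefficient (coefficients fitted on raw features would
first be multiplied by the feature's training sd); it is invariant to
rescaling a raw feature.

## Response Index

TS group = {CD4 CXCL13+ Tfh, CD8 CXCL13+ T}; TP group = {CD4 TGF-β1+ T,
CD8 Temra}. Both group assignments are configurable (`ts_cell_types` /
`tp_cell_types`), so a variant grouping — e.g. one that places CD8
CXCL13+ T on the tumor-promoting side — can be evaluated directly; the
default follows the subsets' response associations. Per sample:

* composite GSEA = Σ over TS∪TP subsets of their GSEA index;
* composite FC, "formula" mode (default): |Σ_TS t_k / Σ_TP t_k|; "text"
  mode: |Σ_TS t_k| / Σ_TP t_k. The per-subset term t_k is either the
  Haldane-corrected ratio (F_R + ½)/(F_NR + ½) ("ratio" mode, default) or
  the log2 clonal FC index ("index" mode). The two composite readings and
  the two term readings are not equivalent; all are implemented because
  no single intended reading is recoverable.
* RI = composite FC × composite GSEA. A zero TP sum is ε-guarded (1e-9)
  and flagged; missing per-sample terms are neutral (ratio 1, index 0,
  ES 0) and flagged.

RI is invariant to permuting subsets within a group and linear in the
composite GSEA index.

## Cohort-level composition statistics

Cell-type proportions between two groups use the pooled two-proportion
z-test (p = 1 when the pooled proportion is degenerate), BH-corrected
across cell types, with `log_fc = log2((k₁/n₁ + ε)/(k₂/n₂ + ε))`,
ε = 1e-9. Pseudotime comparisons min-max scale the pooled lineage to
[0, 1] and apply Welch's t-test (Satterthwaite df); constant pooled
pseudotimes are an error. Pseudotime construction itself (PC1 ordering or
trajectory inference) is upstream of this package.

## Synthetic cohorts

The generator emulates a multi-cancer ICB cohort: per cancer type,
post-treatment responder and non-responder samples plus treatment-naive
and normal samples (defaults: 2 cancers; 20 R + 20 NR + 6 pre + 4 normal
samples cohort-wide; 500 cells/sample; 1000 genes). Counts are negative
binomial (dispersion 2) with log-normal gene means (meanlog −0.7,
sdlog 1), chosen so a typical cell detects ~400 genes and passes default
QC while QC still has teeth on degraded inputs; ten `MT-` genes with
8-fold elevated means give mitochondrial fractions around 8%. Each cell
type carries ten 4-fold up-shifted marker genes. Twenty disjoint 25-gene
pathways are drawn from the remaining gene universe; four are planted
with a 2^`pathway_effect` mean shift in TS subsets of R samples and four
in TP subsets of NR samples (default effect 1 log2 unit).

TCRs: 92% of cells carry a paired clonotype; CDR3s are unique random
amino-acid strings of length 12–18 (C…F framing), uniqueness enforced by
rejection sampling. Per (cell type, response group), a configurable
fraction of TCR⁺ cells draws from a group-exclusive expanded pool
(defaults: 0.5 own-group in the concordant subsets, 0.1 in the
discordant, 0.05 in background types), 25% from a shared pool sampled by
all groups, and the rest are singletons; 4% of TCR⁺ cells yield only one
chain to exercise the pairing filter. Group-specific pools are exclusive
by construction, so the planted specificity map is exact ground truth;
realized truth is recorded from the actual draws (a shared clone that
happens to occur only in R samples is truthfully R-specific).

Three independent random streams (expression, TCR, assignment) derive
from the seed, so outputs are bit-identical under a fixed seed and
changing one block's parameters does not perturb the others.

What the generator does **not** emulate: transcriptome-wide co-expression
and batch structure, UMI depth variation, V/J usage and clonotype
sequence similarity, per-cancer effect-size heterogeneity (effect sizes
are tunable, not calibrated to any real cohort). Passing tests therefore
demonstrate correctness of the procedures and recoverability of planted
effects at realistic magnitudes — not clinical performance on real data.

## Null calibration and a label-circularity caveat

The permuted-label mode permutes the sample response labels seen by the
classifier and the RI comparison, holding the assembled features fixed —
the standard permutation null, under which the bootstrapped mean AUC is
0.5 within sampling error and type-I errors of the component tests sit at
their nominal levels (asserted in tests).

Permuting labels *upstream* of the repertoire set-difference is not a
null: the response-specific repertoire construction is label-circular.
For any labeling whatsoever, some clonotypes are exclusive to one group
by sampling alone (singletons above all), so the per-sample clonal FC
features track whichever labels defined the groups, and the classifier
recovers those labels almost perfectly. This is an inherent property of
building group-exclusive-repertoire features and evaluating on the same
samples; applying the procedure to real data therefore warrants held-out
samples whose TCRs did not participate in the specificity extraction.

## Problem sizes and numerical settings

Defaults throughout: GSEA n_perm 10,000; bootstrap 100 rounds; λ grid 100
points; coordinate-descent tolerance 1e-7 (1e-12 in oracle-equivalence
tests); IRLS weights floored at 1e-5 and linear predictors clipped at
±30 inside the sigmoid. The test suite scales cohorts down (e.g. 150–250
cells/sample, 100–500 permutations, 8–20 bootstrap rounds) except for the
planted-recovery checks, which run the full default cohort; the
acceptance script runs the full default configuration.
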