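# Methods

## Scope and data model

The package operates on cells × genes matrices tagged with their scale
(`tpm`, `umi`, `log`, `centered`) plus a per-gene annotation (chromosome, arm,
0-based half-open coordinates, aggregate expression).  All containers are thin
wrappers around pandas objects; matrices travel as MatrixMarket + TSV or dense
TSV.  Read alignment/quantification, graph-based clustering with batch
harmonization, RNA velocity, and regulon *inference* are out of scope: the
pipeline starts from a quantified matrix and, for regulons, from an externally
binarized activity matrix.

## Expression transforms and QC

* `E = log2(TPM/10 + 1)`.  The `/10` rescale reflects the ~1e5-transcript
  complexity of a single-cell library, so that E ≈ log2(expected transcript
  count + 1).
* Smart-seq2-like QC removes cells with < 2000 detected genes (detection =
  TPM > 0; the zero-threshold field convention) or mean housekeeping E < 2.5.
  The housekeeping list is a configuration input; synthetic runs use the
  generator's housekeeping module.  Housekeeping expression is evaluated on
  the E scale.
* Gene filter: keep genes with TPM > 10 in ≥ 10 cells.  Cells are filtered
  before genes.
* 10X-like QC keeps cells whose detected-gene count lies in [mean/2, 2·mean]
  — the mean over all input cells, computed once before filtering — and whose
  mitochondrial-UMI fraction is ≤ 5%.
* Relative expression `Er` centers each gene to mean zero within a cell group
  (anatomical compartment); a pan-compartment mode re-centers across all
  cells before cross-compartment score comparisons.

## CNA inference

Windows of 100 consecutive genes (step 1) within each chromosome average `Er`
clipped to ±3; the clip stops single-gene outliers from mimicking dosage.
Chromosomes shorter than the window collapse to a single window so every
chromosome stays represented.  Calling pools query cells with spike-in window
profiles of known non-malignant cells and cuts a Ward tree on correlation
distance into k clusters (default 2 per sample).  A cluster anchors the
CNA-negative class when it holds ≥ 50% of all spike-ins *or* when spike-ins
make up ≥ 50% of its members; the second clause makes a flat cohort — cells
indistinguishable from the references — all-negative regardless of how the
tree happens to split.  The per-cell CNA signal reported by the calling step
is the mean squared deviation of the cell's windows from the spike-in mean
profile.  Re-baselining against the references matters: in a mostly-malignant
cohort the per-gene centering baseline is itself malignant, so the raw mean
squared window value is largest for *normal* cells and would invert any
ROC against malignancy.

## Malignant-cell classification

Cells cluster by k-means on the top principal components of `Er`
(deterministic for a fixed seed); any clustering of comparable quality would
do, as only cluster membership enters the rules.  A cluster is labeled a
normal cell type when that type's mean control-matched marker score exceeds 1
and every other type's mean; the threshold mirrors the cycling-call scale,
since no separate marker cutoff is established.  Final classes: normal =
marker cluster ∧ CNA-negative; malignant = CNA-positive ∧ non-marker cluster;
anything discordant is excluded rather than guessed.  CNA-positive cells
inside marker clusters are excluded (conservative).  Samples listed in an
override set model CNA-quiet tumors: their CNA-negative non-marker cells are
rescued as malignant.  Cross-sample co-clustering rescue is reduced to this
per-sample switch.

## Metaprogram discovery

* Over-dispersed genes: variance of E z-scored within 20 equal-frequency bins
  of `Ea`, top 10,000 (all, if fewer).  This is a binned variance z-score in
  the spirit of overdispersion-based variable-gene selection; zero-variance
  genes are never selected while alternatives remain.
* NMF: multiplicative-update minimization of the Frobenius loss on `Er` with
  negatives zeroed, initialized with deterministic NNDSVDa (zeros filled with
  the matrix mean).  The hand-written solver exists because the per-iteration
  reconstruction error must be observable (it is non-increasing, which the
  tests assert) and runs must be bit-reproducible; sklearn's NMF is used in
  the tests as an independent cross-check on planted structure, never as the
  implementation.  Default k = 10 per sample; a generous k is harmless since
  redundant factors merge downstream.
* Factors are represented by their top-30 genes (ties broken
  lexicographically), scored on all compartment cells, and clustered by Ward
  linkage on 1 − Pearson of the score vectors.  The tree is cut at the
  coarsest level at which every multi-member cluster has mean pairwise r >
  0.5; singletons are dropped unless whitelisted (the whitelist models manual
  inspection of programs with known-cell-type character).  Retained clusters
  merge into metaprograms by the top-30 genes of the average weight vector,
  absent genes counting as zero.
* Signature genes per assigned population: one-vs-rest Wilcoxon rank-sum on
  uncentered log values with Bonferroni correction over tested genes,
  requiring adjusted p < 0.05, ≥ 1 log2-unit mean difference (the 2-fold rule
  on the log scale, consistent with log-scale input), and expression (E > 0)
  in ≥ 50% of the population's cells.

## Scoring and states

Control sets hold, per signature gene, the 100 genes nearest in `Ea` (ties by
gene id; never the gene itself).  Controls are pooled with multiplicity —
the 100-fold-larger construction; per-gene paired differencing would give the
same mean.  Assignment is argmax over metaprogram scores with lexicographic
tie-break.  Cycling uses max(SC_S, SC_G2M) > 1: the alternative reading
(*both* below 1 for non-cycling) is equivalent for the call boundary chosen
here and the max-rule is the one implemented.  NSC score = SC_NSC −
max(SC_glial, SC_ependymal); cells with NSC score ≤ 0 get lineage = SC_glial
− SC_ependymal (positive toward the glial-progenitor trajectory; the sign
convention is documented here and in the output header).

## Program comparison

Score correlations are plain Pearson over cells with Ward ordering for
display; zero-variance vectors yield missing entries.  Profile correlations
restrict to pooled population-specific signature genes to suppress background
correlation and drop missing genes pairwise.  Shared/specific gene classes
between two tumor types use aggregated (median, log2) expression: common iff
both > 3; X-specific iff X > 3 and X − other > 2; the both-above rule takes
precedence when both fire; units are median log2 expression.

## Regulon aggregation

Activity is the proportion of active cells per (metaprogram, regulon).
Specific TFs: activity strictly > 0.5 in the metaprogram and ≥ 1.5× the
activity in every other metaprogram ("at least 50% greater" read as
non-strict).  Specificity is evaluated within the metaprogram set passed in
(within-compartment by default).

## Bulk survival stratification

Bulk scoring reuses the single-cell scorer verbatim with samples as rows.
Dichotomization defaults to two-cluster 1-D Ward with the higher-mean cluster
labeled high; a median split is available, and both can be reported side by
side since the original segregation procedure is not pinned down.  Group
comparison is Kaplan–Meier with the two-sample log-rank test (lifelines);
the test oracle is an independent observed-minus-expected computation.
PFS and OS are handled identically through caller-supplied time/event
columns.  Multivariable Cox modelling is out of scope; `covariate_table`
formats a cohort for external Cox tooling.

## Synthetic-data generator

The generator emulates: log-normal baseline gene abundance (meanlog 0,
sdlog 1); housekeeping genes boosted ×5 so their expression is stably high as
QC assumes; modules (normal-type markers, expression programs, S/G2M) of 30
genes by default — matching the top-30 metaprogram representation, so planted
modules and recovered metaprograms live on the same footing — up-regulated
×4 in their cells; chromosome-arm CNAs applied multiplicatively on expected
expression *before* count sampling, so the dosage signal the window method
detects is present where counts are drawn; negative-binomial counts
(gamma–Poisson, dispersion 0.15, library size 150,000) renormalized to TPM.
Cycling malignant cells additionally activate S or G2M.  Bulk cohorts mix
program mean profiles by a Dirichlet composition; the default composition is
a two-component mixture (target-enriched alpha 12 vs target-depleted alpha 1
against 6) emulating high- and low-expressing bulk tumors, which is also what
the two-cluster dichotomization is designed to recover.  Survival times are
exponential with hazard h0·exp(β·target fraction), censored by an independent
exponential calibrated to 20%.

Not emulated: read-level noise, doublets, ambient RNA, batch effects beyond
per-sample composition, gene-length bias, dropout beyond what the count model
induces.  Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated generative assumptions, not robustness to every
artifact of real data.

## Problem sizes and numerical choices

Benchmarks use a 2,000-gene, 10-chromosome genome; CNA/classification cohorts
of 3 samples × 300 cells (20% normal; ×1.5 gain + ×0.5 loss on two arms);
metaprogram cohorts of 4 samples × 400 malignant cells with 3 shared planted
modules; scoring-null runs of 200 random 30-gene signatures on a 300-cell
Poisson-noise cohort (the designated null configuration: dispersion → 0,
fold-up 1); survival studies of 100 cohorts (n = 200) at β = log 3 and 200 at
β = 0.  These sizes were chosen as the smallest at which the planted effects
are unambiguous for the statistics involved.  NMF runs at most 500 iterations
with relative tolerance 1e-6 and an epsilon of 1e-12 in the multiplicative
updates; correlation distances are clipped at 0; flat profiles fall back to
Euclidean distance where correlation is undefined.

## Known limitations

* Per-sample k for NMF and the program whitelist are configuration, not
  model selection.
* The CNA caller assumes the spike-in references are genuinely CNA-free;
  contaminated references shift the negative anchor.
* Classification accuracy depends on the expression clustering separating
  normal types; heavily mixed clusters push cells into `excluded`.
* Bulk scoring inherits the single-cell control-matching assumption that
  `Ea` computed on the cohort is a fair expression-level proxy; very small
  cohorts (< ~20 samples) make the control sets noisy.
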