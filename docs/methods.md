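# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the design choices behind `dhgomics`.

## Study design being modelled

The pipeline targets a two-cohort case/control serum study of dampness-heat
gout: a discovery cohort used for model building and marker selection, and a
smaller independent validation cohort used only for frozen-model evaluation.
Two omics layers are analysed — untargeted LC-MS metabolomics (feature-level
intensities, hundreds to tens of thousands of features) and DIA proteomics
(protein-level intensities) — and their pathway-level evidence is
intersected before being anchored to an 11-item clinical symptom table
(3 primary symptoms, 5 secondary symptoms, 3 tongue-pulse findings).

## Preprocessing

* **Missing-value filter.** A feature is dropped when its missing fraction
  *strictly exceeds* `max_missing_fraction` (default 0.20), computed across
  all samples rather than per group — the simplest defensible reading of a
  ">20% missing removed" rule.
* **Imputation.** Half-minimum: each missing cell becomes half the feature's
  observed minimum.  This is the de facto standard for left-censored LC-MS
  data and is consistent with the generator's censoring mechanism below.
* **Transform and scaling.** log2, then Pareto scaling (centre, divide by
  √SD) before multivariate modelling — the metabolomics convention that
  tempers the dominance of high-abundance features without fully whitening
  them.  Unit-variance and no-scaling variants are config options.  A
  constant feature under unit-variance scaling becomes a zero vector with a
  warning rather than an error.  Note that a *second* application of the
  log/scale step to its own output is not mathematically an identity (the
  output is centred and signed); the idempotence guarantee covers the filter
  and imputation stages, which are exactly idempotent.

## OPLS-DA

Class labels are coded y ∈ {−1, +1} and centred.  The NIPALS construction
with Trygg–Wold orthogonal signal deflation is used: the predictive weight
vector is w ∝ Xᵀy (unit norm); for each of `n_ortho` orthogonal components
the loading p of the current predictive score is orthogonalised against w,
normalised, and the resulting y-uncorrelated component t·pᵀ is subtracted
from X; a single predictive component (t, p, q) is then fit on the residual.
Because Xᵀy is untouched by y-orthogonal variation, the predictive weights
and undeflated scores are definitionally invariant to injected orthogonal
structure — the property the tests assert.

* **R²Y** is the fraction of centred-y variance explained by t·q; **R²X**
  sums the X variance captured by the predictive and orthogonal components.
* **Q²** comes from stratified k-fold cross-validation (default 7 folds,
  fold assignment seeded): the entire model, including centring, is refit
  per fold and PRESS accumulates over held-out samples.  The fold count is a
  convention (the classical SIMCA default), not a sensitive choice.
* **Permutation test** (default 100 permutations): labels are permuted over
  the whole cohort, the full pipeline including cross-validated Q² is refit,
  and p = (1 + #{permuted ≥ observed}) / (1 + n) for both Q² and R²Y — hence
  the smallest reportable p is 1/(n+1) ≈ 0.0099 at n = 100, reported as
  p < 0.01.
* **VIP** uses the single predictive component by default, VIP_j =
  √F·|w_j|/‖w‖, which satisfies mean(VIP²) = 1 exactly.  A toggle includes
  orthogonal components weighted by the (near-zero) y-variance they explain;
  this barely changes the scores and exists for comparability with software
  that sums over all components.

## Univariate screening

Two-sided Wilcoxon–Mann–Whitney per feature: exact when both groups have
≤ 12 samples and no ties, otherwise the mid-rank normal approximation with
continuity correction.  Benjamini–Hochberg q-values are computed across all
tested features of a layer and always reported; the metabolite *selection*
gate uses the raw p (p < 0.05) together with VIP > 0.5 and |log2 FC| >
log2 1.5 ≈ 0.585.  The fold-change threshold follows the "FC > 1.5" reading
rather than "log2 FC > 1.5" (FC > 2.83): the two appear interchangeably in
this literature and the milder gate is the one consistent with tripartite
VIP/p/FC screens of this size; the threshold is config-exposed.  Proteins
use p < 0.05 with linear FC > 2 or < 0.5, the conventional DIA screen.
Fold changes are differences of group means of log2 intensities (case minus
control), and trend is Up exactly when log2 FC > 0.

## Pathway enrichment, intersection, and symptom weighting

Over-representation is the one-sided hypergeometric upper tail with the
universe restricted to the features that survived preprocessing in that
layer — using the whole database as universe would inflate significance for
panels that never entered the analysis.  The enrichment score is −log10 of
the raw p (a q-based score is available by flag).  Cross-omics intersection
keeps pathways with raw p < 0.05 in *both* layers, ordered by the summed
−log10 p.

Symptom weighting assigns 3/2/1 points per linked primary/secondary/
tongue-pulse symptom; with the packaged 11-item table the maximum attainable
score is 3·3 + 5·2 + 3·1 = 22.  "Integrating enrichment with symptom
relevance" is implemented as a rank sum: both criteria are converted to
ordinal ranks (ties by pathway id) and added, with final ties broken by
enrichment score then id.  Rank sums are scale-free — they do not depend on
how the enrichment score is defined — which is why they were preferred over
a weighted sum of raw scores (also available).  The crucial pathways are the
smallest top-of-ranking prefix whose linked symptoms cover the full table;
a fixed k can be forced instead (the upstream analyses this emulates use
k = 4 or 5 interchangeably).

The hub-protein procedure on a PPI edge list deduplicates to a simple
undirected graph, keeps the top 25 nodes by degree (ties by id), recomputes
degree in the induced subgraph, and returns nodes with recomputed degree
strictly greater than 5.

## Biomarker panel and diagnostics

* **RF mean decrease accuracy.** An explicit bootstrap forest of 500
  scikit-learn decision trees (`max_features="sqrt"`): per tree, out-of-bag
  accuracy is compared with the accuracy after permuting one feature's OOB
  values; drops average over trees and are reported in percentage points.
  The forest is assembled in-package because the classical per-tree OOB
  permutation importance needs the bootstrap membership of every tree.
  The default threshold (> 14 points) is interpreted in percentage points of
  OOB accuracy; with several redundant strong markers the measured MDA of
  each is diluted, which is why the panel is the *union* of the RF and SVM
  screens rather than their intersection.
* **SVM averaged importance.** A linear-kernel SVM (the only kernel with a
  direct weight-based importance) is fit on standardised features per
  balanced subsample (default 50 subsamples of 80% of the minority class
  size per class, drawn without replacement); importance is |w| normalised
  to sum 1, averaged.  Default threshold > 0.01.
* **Panel assembly** restricts passers to members of the crucial pathways
  and records which criteria each marker passed.  Assembly is monotone:
  lowering either threshold never removes a marker.
* **ROC.** The AUC is the Mann–Whitney concordance probability (ties count
  ½); confidence intervals use the DeLong variance of the placement values.
  Per-marker AUCs are reported orientation-free (≥ 0.5 with the direction
  flagged).  Combined-panel evaluation pools held-out scores from
  Monte-Carlo cross-validation: per iteration a class-balanced training set
  (⅔ of the minority class size per class) is drawn, the classifier
  (logistic regression, 500-tree random forest, or linear SVM; inputs
  standardised inside the model pipeline) is fit, and all held-out samples
  are scored.  SVM decision values pass a logistic link so the per-sample
  probability plots are comparable across model kinds.  Validation-cohort
  evaluation applies the frozen discovery-cohort model unchanged.

## Synthetic cohorts and what they do (not) show

The generator draws per-feature baseline log2 intensities uniformly over
≈ 4 orders of magnitude, adds Normal(0, `noise_sd`) noise per cell, and
shifts planted features by `effect_log2fc` in cases only, with alternating
sign so both up- and down-regulated markers occur.  Missingness is
left-censored: per feature, the lowest `missing_rate` fraction of cells is
masked — the mechanism that makes half-minimum imputation and the 20% filter
meaningful.  Defaults are desk-scale study conditions: 30/30 samples, 500
metabolite and 300 protein features, 10 planted each, effect 2 on the log2
scale, noise SD 0.5, 10% missingness, 20 pathways of 10 members with 4
planted pathways; the validation cohort defaults to 25/15.  The pathway
database distributes the planted metabolites *and* proteins round-robin over
the planted pathways (so both layers enrich them) and fills with unplanted
features; the symptom link table partitions the 11 symptoms over the planted
pathways, so the minimal covering set size equals the number of planted
pathways by construction (decoy pathways receive at most one singleton
edge, which can never reduce the covering count below the partition size).

The generator deliberately omits retention-time/adduct chemistry, batch and
injection-order drift, QC samples, feature correlation beyond the class
effect, and non-Gaussian heavy tails.  Passing recovery tests therefore
demonstrates the *correctness of the inference chain under its stated
model*, not expected performance on real serum data, where effect sizes are
smaller, features are correlated, and missingness is only partly
intensity-driven.  One visible consequence in the diagnostics: a planted
panel keeps a latent two-cluster structure even after label shuffling, so
the pooled MCCV AUC of a single shuffle is highly variable (≈ 0.33–0.66 at
the default scale); null calibration is therefore assessed as the mean over
shuffles, which sits at 0.5 as it should.

## Determinism and numerical conventions

One run seed fans out to per-stage seeds via a stable blake2s hash of the
stage name, so stage re-runs reproduce full-run behaviour; all stochastic
routines (CV folds, permutations, bootstraps, subsamples, MCCV splits) are
generator-seeded, and fixed seeds give bit-identical outputs.  Ties are
broken lexicographically by id everywhere a total order is needed.  Missing
cells in the TSV dialect are empty strings — never 0, never a literal NA —
because zero-versus-missing confusion is the classic omics I/O failure.
Monoisotopic masses use IUPAC atomic masses with the proton (1.00727646 Da),
not the hydrogen atom, as the adduct charge carrier; ppm errors are relative
to the theoretical m/z; the default 10 ppm tolerance is Orbitrap-plausible
and makes the packaged 56-compound table self-consistent (largest observed
deviation ≈ 7 ppm, for prostaglandin E2).

## Problem sizes used in tests and the acceptance script

Module tests run on matrices of tens of features and ≤ 30 samples; the
end-to-end recovery experiments use the default study-scale conditions
(30/30 × 500 features) with 20 replicates for the panel-recall estimate, 30
replicates for null-calibration checks, 100 permutations for the reported
permutation p, and 50 MCCV iterations — sizes chosen so the full suite and
the acceptance script each complete in a few minutes on a single CPU while
keeping Monte-Carlo standard errors well inside the asserted margins.

## Known limitations

* The OPLS-DA fits a single predictive component (the two-class case);
  multi-class variants are out of scope.
* Protein selection uses raw p per the conventional DIA rule; q-values are
  reported but not gated on.
* The enrichment intersection treats layers independently; no
  topology-aware or correlation-adjusted pathway scoring is attempted.
* The curated pathway→symptom evidence is consumed as a table; the package
  does not attempt to derive it.
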