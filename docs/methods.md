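# Methods

This note documents the models and procedures implemented in `bltsub`,
the defaults they use, and the choices made where the design was open.

## Normalization

Expression enters on the linear scale (strictly positive intensities),
is log2-transformed, and each sample is centered by its own median over
*all* genes in the file (not panel-restricted):
`value[g,s] = log2(raw[g,s]) − median_g(log2(raw[·,s]))`.  Log base 2 is
the microarray convention.  The scale is tracked on the matrix object and
a second normalization is refused rather than silently reapplied.
Missing values are a hard error; no imputation is attempted.

## Subtype assignment

Samples are clustered on the union of the luminal and basal marker panels.
Each gene is z-scored across samples first (population SD; zero-variance
genes dropped with a warning) so that Euclidean distance weights genes
equally.  Stage 1 is agglomerative clustering with Ward's criterion
(squared-Euclidean / Ward-2, as implemented in `scipy.cluster.hierarchy`),
cut at k = 2; each cluster is named by whichever panel has the higher mean
z-score inside it, and identical names for both clusters is a hard
"degenerate separation" error with the offending panel means in the
message.  Stage 2 makes the historically manual double-negative
separation explicit and deterministic: any sample whose mean z-score is
below `dn_threshold` (default −0.5, a CLI flag) on *both* panels is
re-labeled double-negative, and the remaining samples are re-clustered at
k = 2 and renamed.  The pass is single: stage-2 re-clustering cannot
create further double-negatives.

A consequence of z-scoring worth knowing: when the two stage-1 clusters
partition the whole cohort, their panel z-means cannot both be
luminal-dominated (per-gene z-scores sum to zero), so the degeneracy
guard can only fire after double-negative removal — it is kept in both
stages as a defensive contract.

## Prediction strength

For a pair of subtypes, their samples are pooled on the same z-scored
marker space used for clustering and randomly halved `n_splits` times
(default 50, seeded).  Each half is clustered by k-means (k = 2,
k-means++ seeding, 10 restarts, 300-iteration cap, tolerance 1e−6); for
each test cluster `A_kj` the co-assignment proportion
`(1/(n_kj(n_kj−1))) Σ_{i≠i′} D_ii′` is computed, where `D_ii′ = 1` iff the
nearest-training-centroid rule puts both samples in the same training
cluster; the split's value is the minimum over test clusters (clusters of
size < 2 are skipped with a warning; all skipped is an error), and the
reported statistic is the mean over splits.  `k = 1` is definitionally 1.
The split count is a choice — the statistic's original description leaves
it open — and 50 makes the Monte-Carlo error on the mean small relative
to the 80 % interpretation threshold.

## Posterior strength

Per-sample assignment confidence is the Bayes posterior
`P(g|x) ∝ f_g(x) P(g)` under Gaussian class densities with per-group means,
one pooled within-group covariance, and priors equal to training group
frequencies.  The pooled covariance is shrunk convexly toward its own
diagonal, `Σ_λ = (1−λ)S + λ diag(S)`, with the intensity λ chosen
analytically (Schäfer–Strimmer: off-diagonal entries shrunk toward zero by
`Σ Var(s_ij) / Σ s_ij²`, clipped to [0,1]) unless given explicitly.
Shrinkage is necessary because the marker dimension (48) can exceed the
double-negative group size.  Log-density arithmetic subtracts the
per-sample maximum before exponentiation, so posteriors are finite
arbitrarily far from the means and each row sums to 1 to machine
precision.  A posterior ≥ 0.80 for the assigned class is flagged a
"strong" prediction.

## The BLT classifier

*Selection.*  An L1-penalized multinomial logistic regression (saga
solver) is fit on the z-scored candidate panel over a path of 40
penalties, λ ∈ [0.1, 1000]; a gene counts as selected when any class
coefficient is non-zero, the path point with selected-gene count closest
to the target (default 28) wins, and ties go to the sparser model.
Multinomial rather than binomial selection matches the three-subtype
discriminant framing; the realized luminal/basal split of the selected
set is reported rather than enforced.  Selection runs once on the full
training cohort, outside cross-validation — deliberately mirroring the
original procedure, with its acknowledged optimism; nested selection is a
caller's one-line change (re-run selection inside the fold loop).

*Fit and score.*  Discriminant directions solve the between/within
generalized eigenproblem `B v = λ S_w v` with the same shrunk pooled
covariance as the posterior model (this also keeps perfectly collinear
gene pairs finite).  The BLT weights are the negated first-direction
coefficients, globally sign-flipped if necessary so that the mean luminal
training score exceeds the mean basal score; `BLT(s) = Σ_i W_i E_i(s)` is
linear in expression, and `LD1 = −BLT` by construction.  With three
training groups a second direction (LD2) is retained for the
two-dimensional projection.

*Cutoff and ROC.*  The cutoff minimizing luminal/basal misclassification
is found on a 1000-point even grid over the score range
(double-negatives excluded); among tied candidates the one closest to
the tied set's median is returned.  The ROC uses thresholds at every
unique score plus ±∞ with the "call luminal when score ≥ threshold"
rule; trapezoidal AUC under this construction equals the Mann–Whitney
U-statistic divided by n₁n₂ exactly, ties counted half — a property the
tests verify against `scipy.stats.mannwhitneyu`.  The optimal operating
point minimizes `(1−sens)² + (1−spec)²`.  Cutoffs are data-dependent
outputs, not constants: every cohort gets its own.

*Cross-validation.*  Stratified k-fold (default 5, seeded, folds reduced
with a warning when the smallest class is smaller).  Per fold a
Gaussian-posterior discriminant classifier is refit on the training
samples using the *fixed* selected gene set, held-out samples are
assigned to their maximum-posterior class, and fold accuracies are
averaged.

## Phenotype scores

The EMT score of sample j is `Σ_i w_i G_ij` over the 76-gene signature,
with `w_i` the Pearson correlation of gene i with the E-cadherin (CDH1)
anchor across the analyzed cohort (the anchor's own weight is exactly 1;
absent genes are dropped with a warning, zero-variance genes get weight
0), then mean-centered so the cohort grand mean is zero.  Negative scores
indicate an activated EMT state.  Weights are computed on the analyzed
cohort itself because the definition is a within-cohort correlation;
Pearson is the default reading of "correlation coefficient".  The immune
and checkpoint scores are the per-sample median over the panel genes
minus the grand mean of those medians; at least half the panel must be
present, and even-count medians use the midpoint convention.

## IHC surrogate classifier

The rule caller encodes the reciprocal staining pattern: GATA3 above the
positivity threshold (default 10 %, from the repeated "scattered cells in
under 10 % of the tumor" observation) with KRT5/6 at or below it calls
luminal; the mirror pattern calls basal; both at or below calls
double-negative; coexpression above the threshold on both markers is
noninformative (the "strong uniform positivity for both" case, ≥ the 50 %
strong threshold, is reported with its own rule string).  The 50 %
strong-uniform threshold is a quantification of a qualitative
description and is a flag.  The quantitative route fits a logistic
regression on the two raw staining proportions (no interaction), with a
small always-on L2 ridge (1e−4, intercept unpenalized) so the fit stays
defined under complete separation — the common case for these markers —
and evaluates it by leave-one-out cross-validation at probability
threshold 0.5, luminal vs basal only.  Contingency summaries report
per-mRNA-subtype counts and nearest-integer percentages (half away from
zero).  Note that 48 of 59 is 81.4 % and therefore reported as 81 %.

## Synthetic cohort generator

The generator draws linear-scale expression as
`2^Normal(μ_g + shift, σ)` with per-gene baselines `μ_g ~ Normal(6, 1)`
(microarray-like log2 dynamic range, stored with the cohort) so that all
effect sizes are exact log2-unit shifts.  Defaults define the study
conditions: 100 luminal / 85 basal / 15 double-negative samples
(TCGA-like luminal/basal proportions with the double-negative group
enlarged enough to be estimable), marker shift δ = 2, EMT and immune
shifts 1, noise SD σ = 1, 15 % of basal samples additionally shifted
+δ/2 on the luminal panel (the co-expressing basal subgroup), 500
unshifted background genes, seed 17.  Double-negative samples keep both
marker panels at baseline, shift the epithelial half of the 76-gene EMT
panel (including CDH1, CLDN1, TJP1) down by δ_EMT and the mesenchymal
transcription-factor half (including ZEB2) up by δ_EMT, and the immune
and checkpoint panels are graded 0 / +δ_imm/2 / +δ_imm for
luminal / basal / double-negative.  IHC staining proportions come from
per-subtype Beta distributions — luminal GATA3 ~ Beta(8,2) and
KRT5/6 ~ Beta(1,19), basal reversed, double-negative both Beta(1,19) —
reproducing the reciprocal pattern.  Panel gene names are synthetic
placeholders sized like the real panels (the published 28/76/128-gene
membership lists live in supplementary material), so panel files and
real symbol lists are interchangeable.  Within-subtype variance defaults
are stated choices, not fitted values: the cohorts' within-subtype
variances are not published.

What the generator does *not* emulate: read-level RNA-seq noise, batch
and platform effects, probe artifacts, gene–gene correlation beyond the
block shifts, or tumor purity variation.  Passing the recovery tests
therefore shows the pipeline is correct and well-conditioned under the
assumed generative structure, not that real cohorts will reach the same
accuracies.

## Numerical choices and problem sizes

Determinism throughout: a single global seed fans out to per-stage seeds
(CRC32 of the stage name XOR the seed, kept below 2³¹), and identical
config + seed reproduce cohorts and manifests byte-for-byte.  The
end-to-end experiments run at cohort size 200 with 10 independent seeds
and the cluster-validity statistics use 50 splits — sizes at which the
Monte-Carlo error of every reported mean is far below the decision
thresholds while a full run stays in the tens of seconds.  Degenerate
inputs fail loudly: non-positive linear values, duplicate identifiers,
single-sample groups, all-small test clusters, missing model genes, and
single-class ROC/cutoff/LOOCV inputs are all errors, not warnings.

## Known limitations

The published cohort-level metrics (AUCs of 0.984/0.948/0.914 etc.) are
properties of the TCGA and GEO cohorts and can only be recomputed from
those matrices, which this package treats as optional external inputs;
the synthetic analogues reported here characterize the implementation,
not those datasets.  The LASSO-outside-CV optimism is inherited by
design.  The double-negative threshold rule is a deterministic stand-in
for expert manual separation and its default (−0.5 z) is a judgment
call.  One IHC record per case is assumed; reconciling multiple
pathologist reads is out of scope.
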