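# bltsub — luminal/basal molecular subtyping of bladder cancer

Invasive bladder cancer splits into two intrinsic expression subtypes,
**luminal** (KRT20, GATA3, FOXA1, XBP1, CD24, UPK2 — differentiated
urothelium) and **basal** (KRT5/6, KRT14, CDH3, CD44 — undifferentiated
basal layer), plus a small **double-negative** group expressing neither
panel, with an activated epithelial–mesenchymal transition (EMT) and an
elevated immune infiltrate.  `bltsub` implements the quantitative
machinery for calling and validating these subtypes from a gene-by-sample
expression matrix, for computational-oncology users who want the whole
chain as tested, scriptable Python:

* **Subtyping** — Ward/Euclidean hierarchical clustering on the z-scored
  28 luminal + 20 basal marker genes, cut at k = 2, with an explicit
  rule (mean z below a threshold on *both* panels) separating the
  double-negative group before re-clustering.
* **Cluster validity** — the prediction strength
  `ps(k) = min_j (1/(n_kj(n_kj−1))) Σ_{i≠i′∈A_kj} D[C(X_tr,k), X_te]_{ii′}`
  over random train/test halvings with k-means, and per-sample Bayes
  posterior strength under Gaussian class densities `x ~ N(u_g, Σ)` with a
  shared shrunk covariance and frequency priors (posterior ≥ 80 % = strong
  assignment).
* **BLT score** — the basal-to-luminal transition score
  `BLT(s) = Σ_i W_i · E_i(s)`, where the `W_i` are the *negated* first
  linear-discriminant coefficients on LASSO-selected marker genes
  (luminal tumors score positive); plus the grid-searched cutoff, ROC
  analysis with the closest-to-top-left optimal point
  `MIN[(1−sens)² + (1−spec)²]`, stratified 5-fold cross-validated
  three-class accuracy, and the two-dimensional (LD1, LD2) projection.
* **Phenotype scores** — the 76-gene EMT score `Σ_i w_i G_ij` with
  `w_i = corr(gene_i, CDH1)` across the cohort, mean-centered; and immune /
  checkpoint scores (per-sample panel median minus the grand mean of
  medians).
* **IHC surrogate classifier** — semiquantitative GATA3 / KRT5-6 rules
  (reciprocal positivity at a 10 % threshold) and a two-marker logistic
  regression with leave-one-out cross-validation, with contingency
  summaries against mRNA subtypes.
* **Synthetic cohorts** — a seeded generator that emulates the statistical
  structure above (subtype proportions, marker shifts, a basal subgroup
  co-expressing luminal markers, EMT and graded immune shifts, Beta-drawn
  IHC staining proportions), so every stage is testable without external
  data.

## Worked example

The numbered drivers under `analysis/` run the whole study on one
generated cohort; each step prints what it found and writes its tables
under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_subtype_clustering.py
python analysis/03_cluster_validity.py
python analysis/04_blt_classifier.py
python analysis/05_phenotype_scores.py
python analysis/06_ihc_classifier.py
```

With the default cohort (100 luminal / 85 basal / 15 double-negative,
marker shift 2 log2 units, noise SD 1, seed 17) this prints:

```
clustered: 100 luminal / 88 basal / 12 double-negative
agreement with simulation truth: 98.5%
prediction strength luminal vs basal: 100.0%
LASSO selected 27 genes (15 luminal + 12 basal)
grid-searched BLT cutoff: 2.921
ROC vs truth: AUC 1.000; optimal point sensitivity 100.0%, specificity 100.0%
5-fold cross-validated three-class accuracy: 99.0%
       emt score group means   luminal: +0.61  basal: +0.37  double_negative: -6.20
    immune score group means   luminal: -0.26  basal: +0.19  double_negative: +0.68
logistic-regression LOOCV accuracy (GATA3 + KRT5/6): 100.0%
```

Read: clustering recovers the simulated subtypes almost perfectly; the
BLT score separates luminal (positive side) from basal (negative side)
cleanly at this effect size; double-negative tumors have the lowest EMT
score (activated EMT) and the highest immune/checkpoint scores; and the
two IHC markers suffice for luminal-vs-basal prediction.

The same pipeline is available as a CLI (`bltsub simulate`, `subtype`,
`validity`, `blt fit/score/roc/cv`, `scores`, `ihc classify/loocv/contingency`)
and end-to-end as `bltsub run-all --config cfg.txt --out outdir`, which
writes a JSON manifest of every metric and is byte-reproducible for a
fixed config and seed.

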