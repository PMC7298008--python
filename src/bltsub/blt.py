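"""The basal-to-luminal transition (BLT) classifier.

From a candidate panel of luminal and basal marker genes, an L1-penalized
multinomial logistic fit selects the informative subset; a linear
discriminant analysis on the selected genes yields discriminant directions;
the unidimensional BLT score of a sample is

    BLT(s) = sum_i W_i * E_i(s)

with ``W_i`` the *negated* first-discriminant coefficients, oriented so
luminal tumors score positive and basal tumors negative.  A grid-searched
cutoff minimizes misclassification, ROC analysis reports AUC and the
optimal (closest-to-top-left) operating point, stratified cross-validation
measures three-class accuracy, and the (LD1, LD2) projection separates all
three subtypes in two dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from bltsub.io import ExpressionMatrix, SubtypeLabelSet
from bltsub.validity import fit_posterior_model, posterior_strengths, shrunk_pooled_covariance

logger = logging.getLogger(__name__)


@dataclass
class BLTModel:
    selected_genes: list[str]
    weights: np.ndarray           # W_i, negated first-discriminant coefficients
    ld2_weights: np.ndarray | None
    cutoff: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.selected_genes) != len(self.weights):
            raise ValueError("one weight per selected gene required")
        if self.ld2_weights is not None:
            self.ld2_weights = np.asarray(self.ld2_weights, dtype=float)
            if len(self.ld2_weights) != len(self.weights):
                raise ValueError("LD2 weight length mismatch")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_point: tuple[float, float, float]  # (threshold, sens, spec)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=1, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)


def select_markers_lasso(m: ExpressionMatrix, labels: SubtypeLabelSet,
                         candidate_genes: list[str], target_nonzero: int = 28,
                         n_lambda: int = 40) -> list[str]:
    """LASSO marker selection over a regularization path.

    Fits an L1-penalized multinomial logistic regression on the z-scored
    candidate genes for a grid of penalties; a gene counts as selected when
    any class coefficient is non-zero.  The path point whose selected-gene
    count is closest to ``target_nonzero`` wins; ties go to the larger
    penalty (sparser model).  Returned genes keep the candidate-panel order.
    """
    genes = [g for g in candidate_genes if g in m.data.index]
    missing = set(candidate_genes) - set(genes)
    if missing:
        raise ValueError(f"candidate genes absent from matrix: {sorted(missing)[:5]}")
    common = [s for s in m.samples if s in labels.labels.index]
    y = labels.labels.loc[common].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes for marker selection")
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < 5:
            logger.warning("class %s has only %d samples", cls, cnt)

    X = _zscore_rows(m.data.loc[genes, common]).to_numpy().T
    order = {g: i for i, g in enumerate(candidate_genes)}

    # C = 1/lambda; descending lambda = ascending C
    Cs = np.logspace(-3.0, 1.0, n_lambda)
    best: tuple[int, float, list[str]] | None = None  # (|count-target|, lambda, genes)
    for C in Cs:
        clf = LogisticRegression(l1_ratio=1.0, C=float(C), solver="saga",
                                 max_iter=5000, tol=1e-5, random_state=0)
        clf.fit(X, y)
        nz = np.any(np.abs(clf.coef_) > 1e-10, axis=0)
        selected = [g for g, flag in zip(genes, nz) if flag]
        count = len(selected)
        if count < 2:
            continue
        lam = 1.0 / C
        key = (abs(count - target_nonzero), -lam)  # ties -> larger lambda
        if best is None or key < (best[0], -best[1]):
            best = (abs(count - target_nonzero), lam, selected)
    if best is None:
        raise ValueError("no penalty on the path selects >= 2 genes")
    return sorted(best[2], key=lambda g: order[g])


def fit_blt(m: ExpressionMatrix, labels: SubtypeLabelSet,
            selected_genes: list[str], shrinkage: float | None = None) -> BLTModel:
    """Linear discriminant fit on the selected genes.

    Discriminant directions solve the between/within generalized
    eigenproblem ``B v = lambda S_w v`` with the pooled within-group
    covariance shrunk toward its diagonal (same contract as the posterior
    model).  ``W = -v1``, globally sign-flipped if needed so the mean
    luminal BLT score exceeds the mean basal score.  With three training
    groups a second direction (LD2) is retained.
    """
    genes = [g for g in selected_genes if g in m.data.index]
    missing = set(selected_genes) - set(genes)
    if missing:
        raise ValueError(f"selected genes absent from matrix: {sorted(missing)[:5]}")
    common = [s for s in m.samples if s in labels.labels.index]
    y = labels.labels.loc[common]
    groups = list(dict.fromkeys(y))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if (y == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    X = m.data.loc[genes, common].to_numpy().T  # samples x genes
    Sw, intensity = shrunk_pooled_covariance(X, y.to_numpy(), shrinkage)

    grand = X.mean(axis=0)
    B = np.zeros_like(Sw)
    for g in groups:
        mu = X[(y == g).to_numpy()].mean(axis=0)
        d = (mu - grand)[:, None]
        B += (y == g).sum() * (d @ d.T)
    B /= len(common)

    evals, evecs = eigh(B, Sw)
    idx = np.argsort(evals)[::-1]
    v1 = evecs[:, idx[0]]
    weights = -v1
    ld2 = evecs[:, idx[1]].copy() if len(groups) >= 3 else None

    score = X @ weights
    if "luminal" in groups and "basal" in groups:
        lum_mean = score[(y == "luminal").to_numpy()].mean()
        bas_mean = score[(y == "basal").to_numpy()].mean()
        if lum_mean < bas_mean:
            weights = -weights

    return BLTModel(selected_genes=genes, weights=weights, ld2_weights=ld2,
                    metadata={"shrinkage": intensity, "groups": groups,
                              "n_train": len(common)})


def blt_score(model: BLTModel, m: ExpressionMatrix) -> pd.Series:
    """BLT(s) = sum_i W_i * E_i(s); linear in expression."""
    missing = [g for g in model.selected_genes if g not in m.data.index]
    if missing:
        raise ValueError(f"model genes missing from matrix: {missing}")
    E = m.data.loc[model.selected_genes].to_numpy()
    return pd.Series(model.weights @ E, index=m.samples, name="blt_score")


def _lum_bas(scores: pd.Series, labels: SubtypeLabelSet) -> tuple[np.ndarray, np.ndarray]:
    common = scores.index.intersection(labels.labels.index)
    y = labels.labels.loc[common]
    s = scores.loc[common]
    lum = s[(y == "luminal").to_numpy()].to_numpy()
    bas = s[(y == "basal").to_numpy()].to_numpy()
    return lum, bas


def optimal_cutoff(scores: pd.Series, labels: SubtypeLabelSet,
                   grid_size: int = 1000) -> float:
    """Grid-searched cutoff minimizing luminal/basal misclassification.

    Double-negative samples are excluded.  1000 evenly spaced candidates
    span [min score, max score]; a sample is called luminal when its score
    exceeds the cutoff.  Ties are broken toward the candidate closest to
    the median of the tied candidates.
    """
    lum, bas = _lum_bas(scores, labels)
    if len(lum) == 0 or len(bas) == 0:
        raise ValueError("both luminal and basal samples are required")
    grid = np.linspace(min(lum.min(), bas.min()), max(lum.max(), bas.max()), grid_size)
    miscls = np.array([(lum <= c).sum() + (bas > c).sum() for c in grid])
    tied = grid[miscls == miscls.min()]
    med = np.median(tied)
    return float(tied[np.argmin(np.abs(tied - med))])


def roc(scores: pd.Series, labels: SubtypeLabelSet,
        positive: str = "luminal") -> ROCCurve:
    """ROC of the BLT score for luminal (positive) vs basal.

    Thresholds run through every unique score plus +/- infinity; a sample
    is called positive when its score is >= the threshold.  AUC is the
    trapezoidal area, which with this construction equals the Mann-Whitney
    U-statistic divided by n1*n2 (ties counted half).  The optimal point
    minimizes (1 - sensitivity)^2 + (1 - specificity)^2.
    """
    lum, bas = _lum_bas(scores, labels)
    pos, neg = (lum, bas) if positive == "luminal" else (bas, lum)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for ROC")

    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate((pos, neg)))[::-1], [-np.inf]))
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    dist2 = (1.0 - sens) ** 2 + (1.0 - spec) ** 2
    i = int(np.argmin(dist2))
    return ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                    auc=auc, optimal_point=(float(thresholds[i]), float(sens[i]), float(spec[i])))


def cv_accuracy(m: ExpressionMatrix, labels: SubtypeLabelSet,
                selected_genes: list[str], folds: int = 5, seed: int = 0) -> float:
    """Stratified k-fold accuracy of the discriminant classifier.

    The gene set is fixed (selection is not re-run inside the folds); per
    fold a Gaussian-posterior discriminant model is refit on the training
    samples and held-out samples are assigned to their maximum-posterior
    class.  Fold accuracies are averaged.
    """
    common = [s for s in m.samples if s in labels.labels.index]
    y = labels.labels.loc[common]
    min_class = int(y.value_counts().min())
    if min_class < folds:
        logger.warning("reducing folds from %d to %d (smallest class)", folds, min_class)
        folds = min_class
    if folds < 2:
        raise ValueError("smallest class too small for cross-validation")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accuracies = []
    idx = np.arange(len(common))
    for tr, te in skf.split(idx, y.to_numpy()):
        tr_samples = [common[i] for i in tr]
        te_samples = [common[i] for i in te]
        if len(set(y.iloc[tr])) < 2:
            raise ValueError("a training fold contains a single class")
        tr_labels = SubtypeLabelSet(y.loc[tr_samples], provenance=labels.provenance)
        sub_tr = ExpressionMatrix(m.data[tr_samples], scale=m.scale)
        sub_te = ExpressionMatrix(m.data[te_samples], scale=m.scale)
        model = fit_posterior_model(sub_tr, tr_labels, selected_genes)
        table = posterior_strengths(model, sub_te)
        accuracies.append(float((table.assigned == y.loc[te_samples]).mean()))
    return float(np.mean(accuracies))


def ld_projection(model: BLTModel, m: ExpressionMatrix) -> pd.DataFrame:
    """Two-dimensional (LD1, LD2) projection; LD1 = -BLT score exactly."""
    if model.ld2_weights is None:
        raise ValueError("model has no second discriminant (fit on 2 groups)")
    scores = blt_score(model, m)
    E = m.data.loc[model.selected_genes].to_numpy()
    ld2 = model.ld2_weights @ E
    return pd.DataFrame({"LD1": -scores.to_numpy(), "LD2": ld2}, index=m.samples)
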