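"""Cluster-validity statistics.

Two complementary measures of subtype-assignment confidence:

* cohort-level *prediction strength* — for a pair of subtypes, samples are
  pooled, randomly halved, each half clustered by k-means, and ps(k) is the
  minimum over test clusters of the proportion of within-cluster sample
  pairs that the training-half centroids also co-assign;
* per-sample *posterior strength* — the Bayes posterior of each subtype
  under Gaussian class densities with a shared (shrunk) covariance and
  frequency priors; a posterior >= 0.80 for the assigned class counts as a
  strong prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans

from bltsub.io import ExpressionMatrix, SubtypeLabelSet

logger = logging.getLogger(__name__)

STRONG_POSTERIOR = 0.80


@dataclass
class PSConfig:
    k: int = 2
    n_splits: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


@dataclass
class PSResult:
    pair: tuple[str, str]
    ps_per_split: list[float]
    ps_mean: float

    def __post_init__(self) -> None:
        if any(not 0.0 <= v <= 1.0 for v in self.ps_per_split):
            raise ValueError("split-level prediction strength outside [0, 1]")


def _zscore_rows(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    X = X.loc[keep]
    return X.sub(X.mean(axis=1), axis=0).div(sd[keep], axis=0)


def _co_assignment_min(test_assign: np.ndarray, train_assign_of_test: np.ndarray,
                       k: int) -> float:
    """min over test clusters of the pairwise co-assignment proportion."""
    values = []
    skipped = 0
    for j in range(k):
        members = np.where(test_assign == j)[0]
        n_kj = len(members)
        if n_kj < 2:
            skipped += 1
            continue
        ta = train_assign_of_test[members]
        # sum over ordered pairs i != i' of 1[same training cluster]
        same = sum(int((ta == c).sum()) ** 2 for c in np.unique(ta)) - n_kj
        values.append(same / (n_kj * (n_kj - 1)))
    if skipped:
        logger.warning("%d test cluster(s) of size < 2 skipped", skipped)
    if not values:
        raise ValueError("all test clusters had fewer than 2 members")
    return min(values)


def prediction_strength(m: ExpressionMatrix, labels: SubtypeLabelSet,
                        pair: tuple[str, str], cfg: PSConfig | None = None,
                        genes: list[str] | None = None) -> PSResult:
    """Prediction strength ps(k) for one subtype pair.

    Samples of the two subtypes are pooled on the z-scored marker-gene
    space (``genes``; default all genes), randomly halved ``n_splits``
    times; each half is clustered by k-means (k-means++ seeding, 10
    restarts) and the split's ps is the minimum over test clusters of the
    fraction of sample pairs the training centroids co-assign.
    """
    cfg = cfg or PSConfig()
    cols = [s for s in m.samples if labels.labels.get(s) in pair]
    for lab in pair:
        n_lab = sum(labels.labels.get(s) == lab for s in cols)
        if n_lab < 2 * cfg.k:
            raise ValueError(f"subtype {lab!r} has {n_lab} samples; need >= {2 * cfg.k}")
    sub = m.data[cols]
    if genes is not None:
        sub = sub.loc[[g for g in genes if g in sub.index]]
    X = _zscore_rows(sub).to_numpy().T  # samples x features
    n = X.shape[0]
    half = n // 2
    if cfg.k > half:
        raise ValueError(f"k={cfg.k} exceeds half-cohort size {half}")

    rng = np.random.default_rng(cfg.seed)
    per_split: list[float] = []
    for _ in range(cfg.n_splits):
        perm = rng.permutation(n)
        tr, te = perm[:half], perm[half:]
        if cfg.k == 1:
            per_split.append(1.0)
            continue
        km_seed = int(rng.integers(0, 2**31 - 1))
        km_tr = KMeans(n_clusters=cfg.k, n_init=10, max_iter=300, tol=1e-6,
                       random_state=km_seed).fit(X[tr])
        km_te = KMeans(n_clusters=cfg.k, n_init=10, max_iter=300, tol=1e-6,
                       random_state=km_seed + 1).fit(X[te])
        d = ((X[te, None, :] - km_tr.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        train_assign_of_test = d.argmin(axis=1)
        per_split.append(_co_assignment_min(km_te.labels_, train_assign_of_test, cfg.k))

    return PSResult(pair=tuple(pair), ps_per_split=per_split,
                    ps_mean=float(np.mean(per_split)))


# ---------------------------------------------------------------------------
# Gaussian posterior model


def shrunk_pooled_covariance(X: np.ndarray, groups: np.ndarray,
                             shrinkage: float | None = None) -> tuple[np.ndarray, float]:
    """Pooled within-group covariance with convex shrinkage toward its diagonal.

    ``shrinkage=None`` selects the intensity analytically (Schafer-Strimmer:
    the off-diagonal entries are shrunk toward zero with weight
    ``sum Var(s_ij) / sum s_ij^2`` over i != j, clipped to [0, 1]).  Returns
    (covariance, intensity).
    """
    n, p = X.shape
    centered = X.copy()
    for g in np.unique(groups):
        mask = groups == g
        centered[mask] -= X[mask].mean(axis=0)
    dof = n - len(np.unique(groups))
    if dof < 1:
        raise ValueError("not enough samples to pool a covariance")
    S = centered.T @ centered / dof

    if shrinkage is None:
        # variance of the entries of the (biased) sample covariance
        w = centered[:, :, None] * centered[:, None, :]  # n x p x p
        w_mean = w.mean(axis=0)
        var_s = ((w - w_mean) ** 2).sum(axis=0) * n / ((n - 1) ** 3)
        off = ~np.eye(p, dtype=bool)
        denom = (S[off] ** 2).sum()
        shrinkage = 1.0 if denom == 0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))

    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    cov = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    return cov, shrinkage


@dataclass
class PosteriorModel:
    """Gaussian class-density model with shared covariance and frequency priors."""

    features: list[str]
    group_means: pd.DataFrame          # groups x features
    covariance: np.ndarray             # features x features, SPD
    priors: pd.Series                  # group -> frequency
    shrinkage: float

    def __post_init__(self) -> None:
        if abs(float(self.priors.sum()) - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("covariance must be positive-definite after shrinkage")


def fit_posterior_model(m: ExpressionMatrix, labels: SubtypeLabelSet,
                        marker_genes: list[str],
                        shrinkage: float | None = None) -> PosteriorModel:
    """Fit group means, shrunk pooled covariance, and frequency priors."""
    genes = [g for g in marker_genes if g in m.data.index]
    if not genes:
        raise ValueError("no marker genes present in the matrix")
    common = [s for s in m.samples if s in labels.labels.index]
    y = labels.labels.loc[common]
    groups = sorted(y.unique(), key=lambda s: list(y.unique()).index(s))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (y == g).sum() < 2:
            raise ValueError(f"group {g!r} has a single sample")

    X_df = m.data.loc[genes, common].T  # samples x features
    # drop features with zero pooled within-group variance
    pooled_var = np.zeros(len(genes))
    for g in groups:
        block = X_df[y == g].to_numpy()
        pooled_var += ((block - block.mean(axis=0)) ** 2).sum(axis=0)
    keep = pooled_var > 0
    if not keep.all():
        dropped = [genes[i] for i in np.where(~keep)[0]]
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped[:5])
        genes = [g for g, k in zip(genes, keep) if k]
        X_df = X_df[genes]

    X = X_df.to_numpy()
    cov, intensity = shrunk_pooled_covariance(X, y.to_numpy(), shrinkage)
    means = pd.DataFrame(
        {g: X_df[y == g].mean(axis=0) for g in groups}
    ).T
    priors = pd.Series({g: float((y == g).mean()) for g in groups})
    return PosteriorModel(features=genes, group_means=means, covariance=cov,
                          priors=priors, shrinkage=intensity)


@dataclass
class PosteriorTable:
    """Per-sample class posteriors with the >= 80% strong-assignment flag."""

    probs: pd.DataFrame       # samples x groups, rows sum to 1
    assigned: pd.Series       # sample -> argmax group
    strong: pd.Series         # sample -> bool

    def strong_fraction(self, labels: SubtypeLabelSet | None = None,
                        subtype: str | None = None) -> float:
        """Fraction of strong assignments, optionally within one true subtype."""
        flags = self.strong
        if labels is not None and subtype is not None:
            members = labels.of(subtype)
            flags = flags.loc[flags.index.intersection(members)]
        return float(flags.mean())


def posterior_strengths(model: PosteriorModel, m: ExpressionMatrix) -> PosteriorTable:
    """Bayes posteriors P(g | x) under the fitted Gaussian model.

    Log-density arithmetic is stabilized by subtracting the per-sample
    maximum before exponentiation, so far-from-mean samples cannot
    over/underflow.
    """
    missing = [g for g in model.features if g not in m.data.index]
    if missing:
        raise ValueError(f"model features missing from matrix: {missing[:5]}")
    X = m.data.loc[model.features].to_numpy().T  # samples x features

    cho = np.linalg.cholesky(model.covariance)
    groups = list(model.group_means.index)
    log_post = np.empty((X.shape[0], len(groups)))
    for j, g in enumerate(groups):
        diff = X - model.group_means.loc[g].to_numpy()
        sol = solve_triangular(cho, diff.T, lower=True)
        maha = (sol ** 2).sum(axis=0)
        log_post[:, j] = -0.5 * maha + np.log(model.priors[g])

    log_post -= log_post.max(axis=1, keepdims=True)
    w = np.exp(log_post)
    probs = w / w.sum(axis=1, keepdims=True)
    probs_df = pd.DataFrame(probs, index=m.samples, columns=groups)
    assigned = probs_df.idxmax(axis=1)
    strong = probs_df.max(axis=1) >= STRONG_POSTERIOR
    return PosteriorTable(probs=probs_df, assigned=assigned, strong=strong)
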