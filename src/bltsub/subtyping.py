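"""Marker-panel hierarchical subtyping.

Two-stage procedure: Ward/Euclidean clustering of samples on the z-scored
luminal+basal marker space cut at k=2, then an explicit double-negative
rule (mean within-cohort z below a threshold on BOTH panels) followed by
re-clustering of the remaining samples.  Replaces the manual separation of
double-negative tumors with a deterministic threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from bltsub.io import ExpressionMatrix, MarkerPanel, SubtypeLabelSet, LOG_MEDIAN

logger = logging.getLogger(__name__)


def zscore_genes(m: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Per-gene z-scores across samples (population SD); returns genes x samples.

    Zero-variance genes are dropped with a warning — they carry no distance
    information.
    """
    sub = m.data.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = sub.index[~keep].tolist()
        logger.warning("dropping %d zero-variance gene(s): %s", len(dropped), dropped[:5])
    sub = sub.loc[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)


def _cut_two(z_samples: np.ndarray) -> np.ndarray:
    """Ward-linkage clustering of sample rows cut at k=2 (labels 1/2)."""
    tree = linkage(z_samples, method="ward")
    return fcluster(tree, t=2, criterion="maxclust")


def _name_clusters(z: pd.DataFrame, assignment: np.ndarray,
                   lum_genes: list[str], bas_genes: list[str]) -> dict[int, str]:
    """Name each cluster by which panel's mean z-score is higher inside it."""
    names: dict[int, str] = {}
    diag = {}
    for c in np.unique(assignment):
        cols = z.columns[assignment == c]
        lum_mean = float(z.loc[z.index.intersection(lum_genes), cols].to_numpy().mean())
        bas_mean = float(z.loc[z.index.intersection(bas_genes), cols].to_numpy().mean())
        names[int(c)] = "luminal" if lum_mean > bas_mean else "basal"
        diag[int(c)] = (lum_mean, bas_mean)
    if len(set(names.values())) < len(names):
        raise ValueError(
            "degenerate separation: both clusters map to the same subtype; "
            f"cluster panel means (luminal, basal) = {diag}"
        )
    return names


def cluster_subtypes(m: ExpressionMatrix, luminal_panel: MarkerPanel,
                     basal_panel: MarkerPanel, dn_threshold: float = -0.5) -> SubtypeLabelSet:
    """Assign luminal / basal / double_negative labels by marker clustering.

    Stage 1: Ward/Euclidean agglomeration on the union of panel genes
    (z-scored per gene), cut at k=2, clusters named by the dominant panel.
    Stage 2: samples whose mean z-score falls below ``dn_threshold`` on both
    panels are re-labeled double_negative; the remaining samples are
    re-clustered at k=2 and renamed.  Single pass — stage 2 cannot create
    further double-negatives.
    """
    if m.scale != LOG_MEDIAN:
        raise ValueError("cluster_subtypes requires a normalized matrix")
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    lum = luminal_panel.intersect(m.genes)
    bas = basal_panel.intersect(m.genes)
    if len(lum) < 3 or len(bas) < 3:
        raise ValueError(
            f"panel/gene intersection too small (luminal {len(lum)}, basal {len(bas)}; need >= 3 each)"
        )

    union = lum + [g for g in bas if g not in lum]
    z = zscore_genes(m, union)

    assignment = _cut_two(z.to_numpy().T)
    _name_clusters(z, assignment, lum, bas)  # stage-1 naming must be non-degenerate

    mean_lum = z.loc[z.index.intersection(lum)].mean(axis=0)
    mean_bas = z.loc[z.index.intersection(bas)].mean(axis=0)
    dn_mask = (mean_lum < dn_threshold) & (mean_bas < dn_threshold)

    labels = pd.Series(index=m.samples, dtype=object)
    labels[dn_mask] = "double_negative"

    rest = m.samples[~dn_mask]
    if len(rest) < 2:
        raise ValueError("fewer than 2 samples left after double-negative separation")
    z_rest = z[rest]
    assignment2 = _cut_two(z_rest.to_numpy().T)
    names2 = _name_clusters(z_rest, assignment2, lum, bas)
    labels[rest] = [names2[int(c)] for c in assignment2]

    return SubtypeLabelSet(labels, provenance="clustered")
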