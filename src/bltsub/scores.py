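"""EMT and immune phenotype scores.

Two simple, cohort-centered scalar summaries per sample:

* the EMT score is a weighted sum of a 76-gene signature, each weight the
  Pearson correlation of that gene with the E-cadherin (CDH1) anchor across
  the cohort, mean-centered so the cohort grand mean is zero — negative
  scores indicate an activated (mesenchymal) EMT state;
* the immune (or checkpoint) score is the per-sample median expression over
  an immune gene panel minus the grand mean of those medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from bltsub.io import ExpressionMatrix, MarkerPanel

logger = logging.getLogger(__name__)


@dataclass
class EMTSignature:
    genes: list[str]
    weights: pd.Series   # gene -> correlation with the anchor
    anchor: str = "CDH1"

    def __post_init__(self) -> None:
        if self.anchor not in self.weights.index:
            raise ValueError("anchor missing from weights")
        if abs(self.weights[self.anchor] - 1.0) > 1e-12:
            raise ValueError("anchor weight must be 1")
        w = self.weights.to_numpy()
        if np.any((w < -1 - 1e-12) | (w > 1 + 1e-12)):
            raise ValueError("weights must lie in [-1, 1]")


def emt_weights(m: ExpressionMatrix, signature_genes: list[str],
                anchor: str = "CDH1") -> EMTSignature:
    """Per-gene Pearson correlation with the anchor across samples.

    Genes absent from the matrix are dropped with a warning; zero-variance
    genes get weight 0.  The anchor's own weight is exactly 1.
    """
    if anchor not in m.data.index:
        raise ValueError(f"anchor {anchor!r} not in matrix")
    if m.n_samples < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    a = m.data.loc[anchor].to_numpy()
    if a.std(ddof=0) == 0:
        raise ValueError("anchor has zero variance")

    present = [g for g in signature_genes if g in m.data.index]
    absent = [g for g in signature_genes if g not in m.data.index]
    if absent:
        logger.warning("dropping %d signature gene(s) absent from matrix: %s",
                       len(absent), absent[:5])
    weights = {}
    for g in present:
        x = m.data.loc[g].to_numpy()
        if x.std(ddof=0) == 0:
            logger.warning("zero-variance gene %s gets weight 0", g)
            weights[g] = 0.0
        elif g == anchor:
            weights[g] = 1.0
        else:
            weights[g] = float(np.corrcoef(x, a)[0, 1])
    if anchor not in weights:
        weights[anchor] = 1.0
        present = present + [anchor]
    return EMTSignature(genes=present, weights=pd.Series(weights).loc[present], anchor=anchor)


def emt_score(m: ExpressionMatrix, sig: EMTSignature) -> pd.Series:
    """score_j = sum_i w_i G_ij, mean-centered across the cohort."""
    genes = [g for g in sig.genes if g in m.data.index]
    if not genes:
        raise ValueError("no signature genes present in the matrix")
    w = sig.weights.loc[genes].to_numpy()
    raw = w @ m.data.loc[genes].to_numpy()
    centered = raw - raw.mean()
    return pd.Series(centered, index=m.samples, name="emt_score")


def median_signature_score(m: ExpressionMatrix, panel: MarkerPanel) -> pd.Series:
    """Per-sample panel median minus the grand mean of those medians.

    Requires at least half the panel's genes to be present.  Used for both
    the 128-gene immune panel and the checkpoint ligand/receptor panel.
    """
    if m.n_samples == 0:
        raise ValueError("empty cohort")
    present = panel.intersect(m.genes)
    if len(present) < 0.5 * len(panel):
        raise ValueError(
            f"panel {panel.name}: only {len(present)}/{len(panel)} genes present (need >= 50%)"
        )
    med = m.data.loc[present].median(axis=0)
    return (med - med.mean()).rename(f"{panel.name.lower()}_score")
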