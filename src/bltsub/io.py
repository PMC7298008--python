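"""Core containers and file formats.

Expression matrices travel as tab-separated text (genes as rows, samples as
columns), gene panels as GMT or one-gene-per-line lists, subtype labels as
two-column CSV.  Normalization follows the microarray convention: log2
transform, then per-sample median centering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The three molecular subtypes, in canonical order.
SUBTYPES = ("luminal", "basal", "double_negative")

#: Recognized panel roles.
PANEL_ROLES = ("luminal", "basal", "emt", "immune", "checkpoint", "custom")

LINEAR = "linear"
LOG_MEDIAN = "log_median_normalized"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Values must be finite; on the linear scale they must be
        strictly positive.
    scale
        ``"linear"`` (raw intensities) or ``"log_median_normalized"``
        (log2, per-sample median subtracted).
    """

    data: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG_MEDIAN):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if self.scale == LINEAR and not (values > 0).all():
            raise ValueError("linear-scale expression must be strictly positive")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present], scale=self.scale)


@dataclass
class MarkerPanel:
    """A named, ordered gene set with a declared role."""

    name: str
    genes: list[str]
    role: str = "custom"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.name!r} contains duplicate genes")
        if self.role not in PANEL_ROLES:
            raise ValueError(f"unknown panel role {self.role!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, genes) -> list[str]:
        """Panel genes present in ``genes``, panel order preserved."""
        available = set(genes)
        return [g for g in self.genes if g in available]


@dataclass
class SubtypeLabelSet:
    """Per-sample subtype assignment.

    ``labels`` maps sample identifier to one of :data:`SUBTYPES`;
    ``provenance`` records whether labels are simulation truth, the output
    of clustering, or model predictions.
    """

    labels: pd.Series
    provenance: str = "truth"

    def __post_init__(self) -> None:
        if self.provenance not in ("truth", "clustered", "predicted"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.labels.index.has_duplicates:
            raise ValueError("a sample is labeled more than once")
        bad = set(self.labels.unique()) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")
        self.labels = self.labels.astype(object)

    @property
    def samples(self) -> pd.Index:
        return self.labels.index

    def of(self, subtype: str) -> pd.Index:
        return self.labels.index[self.labels == subtype]

    def counts(self) -> dict[str, int]:
        return {s: int((self.labels == s).sum()) for s in SUBTYPES}

    def agreement(self, other: "SubtypeLabelSet") -> float:
        """Fraction of shared samples with identical labels."""
        common = self.labels.index.intersection(other.labels.index)
        if len(common) == 0:
            raise ValueError("label sets share no samples")
        return float((self.labels.loc[common] == other.labels.loc[common]).mean())


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV into a linear-scale matrix.

    First column holds gene identifiers, the header row sample identifiers.
    Duplicate gene rows are collapsed by their mean (with a warning);
    duplicate sample identifiers are an error, as is any non-numeric cell.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty expression file")
    sample_ids = header.rstrip("\n").split("\t")[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample identifiers {dupes}")

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        logger.warning("collapsing %d duplicated gene row(s) by mean: %s", len(dupes), dupes[:5])
        values = values.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(values.astype(float), scale=LINEAR)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; values round-trip to 12 significant digits."""
    df = m.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.12g", lineterminator="\n")


def read_panels(path, roles: dict[str, str] | None = None) -> list[MarkerPanel]:
    """Read marker panels from a GMT file or a one-gene-per-line list.

    GMT lines are ``name<TAB>description<TAB>gene1<TAB>gene2...``.  A file
    without tab-separated fields is treated as a single panel named after
    the file stem.  ``roles`` maps panel name to role (default ``custom``).
    Repeated genes within a set are deduplicated, order preserved.
    """
    path = Path(path)
    roles = roles or {}
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty panel file")

    panels: list[MarkerPanel] = []
    if any("\t" in ln for ln in lines):
        seen_names: set[str] = set()
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {ln!r}")
            name, genes = fields[0], fields[2:]
            genes = [g for g in genes if g]
            if name in seen_names:
                raise ValueError(f"{path}: duplicate panel name {name!r}")
            seen_names.add(name)
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("panel %s: %d repeated gene(s) removed", name, len(genes) - len(deduped))
            panels.append(MarkerPanel(name, deduped, role=roles.get(name, "custom")))
    else:
        name = path.stem
        genes = list(dict.fromkeys(ln.strip() for ln in lines))
        panels.append(MarkerPanel(name, genes, role=roles.get(name, "custom")))
    return panels


def write_gmt(panels, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for p in panels:
            fh.write("\t".join([p.name, p.role] + list(p.genes)) + "\n")


def read_labels(path, provenance: str = "truth") -> SubtypeLabelSet:
    """Read a ``sample,label`` CSV."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample,label")
    series = pd.Series(df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="sample"))
    return SubtypeLabelSet(series, provenance=provenance)


def write_labels(labels: SubtypeLabelSet, path) -> None:
    df = pd.DataFrame({"sample": labels.labels.index, "label": labels.labels.to_numpy()})
    df.to_csv(path, index=False, lineterminator="\n")


def normalize_expression(m: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform and subtract the per-sample median.

    ``value[g, s] = log2(raw[g, s]) - median_g(log2(raw[., s]))``; afterward
    every sample's median is 0 (exactly, for odd gene counts).  Refuses
    input that is already normalized rather than silently reapplying.
    """
    if m.scale != LINEAR:
        raise ValueError("matrix is already normalized")
    logged = np.log2(m.data)
    centered = logged - logged.median(axis=0)
    return ExpressionMatrix(centered, scale=LOG_MEDIAN)
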