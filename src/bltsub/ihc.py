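"""Immunohistochemistry surrogate classifier.

Two routes from staining proportions to subtype calls: a semiquantitative
rule on GATA3 (nuclear, luminal marker) and KRT5/6 (cytoplasmic, basal
marker), and a logistic-regression model on the quantitative proportions
evaluated by leave-one-out cross-validation.  A contingency summary compares
IHC calls against mRNA-derived subtypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from bltsub.io import SubtypeLabelSet, SUBTYPES

logger = logging.getLogger(__name__)

IHC_MARKERS = ("gata3", "krt20", "upk2", "krt5_6", "krt14")
PATTERN_FLAGS = ("basal_layer_only", "scattered_cells", "strong_uniform")


@dataclass
class IHCRecord:
    """Per-case staining proportions, each in [0, 1].

    GATA3 is scored as the proportion of positive tumor nuclei, the other
    markers as the proportion of positive tumor tissue area.
    """

    case: str
    proportions: dict[str, float]
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.proportions:
            raise ValueError(f"case {self.case}: no marker measured")
        for marker, p in self.proportions.items():
            if marker not in IHC_MARKERS:
                raise ValueError(f"case {self.case}: unknown marker {marker!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"case {self.case}: proportion {marker}={p} outside [0, 1]")
        self.flags = frozenset(self.flags)
        bad = self.flags - set(PATTERN_FLAGS)
        if bad:
            raise ValueError(f"case {self.case}: unknown flags {sorted(bad)}")


@dataclass
class IHCCall:
    case: str
    call: str  # luminal | basal | double_negative | noninformative
    rule: str


def rule_classify(rec: IHCRecord, pos_threshold: float = 0.10,
                  strong_threshold: float = 0.50) -> IHCCall:
    """Semiquantitative two-marker call from GATA3 and KRT5/6.

    Reciprocal positivity/negativity is the discriminating pattern:
    GATA3-positive, KRT5/6 at or below the positivity threshold (scattered
    cells in <10% of the tumor are tolerated) calls luminal; the mirror
    pattern calls basal; both negative calls double-negative; coexpression
    above the positivity threshold on both markers is noninformative.
    """
    for marker in ("gata3", "krt5_6"):
        if marker not in rec.proportions:
            raise ValueError(f"case {rec.case}: marker {marker} missing")
    g = rec.proportions["gata3"]
    k = rec.proportions["krt5_6"]
    if g > pos_threshold and k > pos_threshold:
        if g > strong_threshold and k > strong_threshold:
            return IHCCall(rec.case, "noninformative", "strong positivity for both markers")
        return IHCCall(rec.case, "noninformative", "coexpression above positivity threshold")
    if g > pos_threshold:
        return IHCCall(rec.case, "luminal", "GATA3 positive, KRT5/6 negative")
    if k > pos_threshold:
        return IHCCall(rec.case, "basal", "KRT5/6 positive, GATA3 negative")
    return IHCCall(rec.case, "double_negative", "negative for both markers")


def _design(records: list[IHCRecord], labels: SubtypeLabelSet,
            marker_pair: tuple[str, str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    by_case = {r.case: r for r in records}
    rows, y, cases = [], [], []
    for case, label in labels.labels.items():
        if label not in ("luminal", "basal"):
            continue
        if case not in by_case:
            continue
        rec = by_case[case]
        for marker in marker_pair:
            if marker not in rec.proportions:
                raise ValueError(f"case {case}: marker {marker} missing")
        rows.append([rec.proportions[m] for m in marker_pair])
        y.append(1 if label == "luminal" else 0)
        cases.append(case)
    return np.asarray(rows, dtype=float), np.asarray(y, dtype=int), cases


def lr_loocv(records: list[IHCRecord], labels: SubtypeLabelSet,
             marker_pair: tuple[str, str] = ("gata3", "krt5_6"),
             ridge: float = 1e-4) -> tuple[float, pd.Series]:
    """Leave-one-out accuracy of a two-marker logistic regression.

    Luminal-vs-basal only (double-negative cases are excluded).  For each
    case the model is refit on the remaining n-1 and the held-out case is
    predicted at probability 0.5.  A small L2 ridge (intercept unpenalized)
    keeps the fit defined under complete separation.

    Returns (accuracy, per-case predicted label Series).
    """
    X, y, cases = _design(records, labels, marker_pair)
    n = len(y)
    if n < 6:
        raise ValueError(f"need >= 6 luminal/basal cases, have {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class input")

    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("a leave-one-out training set has a single class")
        clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=10_000)
        clf.fit(X[mask], y[mask])
        p = clf.predict_proba(X[i:i + 1])[0, 1]
        preds[i] = int(p >= 0.5)
    accuracy = float((preds == y).mean())
    pred_labels = pd.Series(
        np.where(preds == 1, "luminal", "basal"),
        index=pd.Index(cases, name="case"),
        name="predicted",
    )
    return accuracy, pred_labels


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


CALL_CATEGORIES = ("luminal", "basal", "double_negative", "noninformative")


def contingency_summary(calls: list[IHCCall], truth: SubtypeLabelSet) -> dict:
    """Cross-tabulate IHC calls against mRNA subtypes.

    For each mRNA subtype: counts and nearest-integer percentages
    (half away from zero) of cases in each IHC category, plus overall
    concordance (calls matching the mRNA subtype; noninformative never
    matches).
    """
    by_case = {c.case: c for c in calls}
    common = [s for s in truth.labels.index if s in by_case]
    unmatched = [c.case for c in calls if c.case not in set(truth.labels.index)]
    if unmatched:
        raise ValueError(f"IHC calls with no mRNA label: {unmatched[:5]}")
    if not common:
        raise ValueError("no overlap between IHC calls and mRNA labels")

    summary: dict = {"subtypes": {}, "n": len(common)}
    concordant = 0
    for subtype in SUBTYPES:
        members = [s for s in common if truth.labels[s] == subtype]
        if not members:
            continue
        counts = {cat: 0 for cat in CALL_CATEGORIES}
        for s in members:
            counts[by_case[s].call] += 1
        concordant += counts[subtype]
        total = len(members)
        summary["subtypes"][subtype] = {
            "n": total,
            "counts": counts,
            "percent": {cat: _round_half_away(100.0 * c / total) for cat, c in counts.items()},
        }
    summary["overall_concordance"] = concordant / len(common)
    return summary


def read_ihc(path) -> list[IHCRecord]:
    """Read an IHC CSV: ``case,gata3,krt20,upk2,krt5_6,krt14,flags``.

    Marker columns are optional; empty cells mean 'not measured'; flags is
    a semicolon-separated list.
    """
    df = pd.read_csv(path, dtype={"case": str})
    if "case" not in df.columns:
        raise ValueError(f"{path}: missing 'case' column")
    records = []
    for _, row in df.iterrows():
        props = {
            m: float(row[m]) for m in IHC_MARKERS
            if m in df.columns and pd.notna(row[m])
        }
        flags = frozenset()
        if "flags" in df.columns and pd.notna(row.get("flags")) and str(row["flags"]).strip():
            flags = frozenset(str(row["flags"]).split(";"))
        records.append(IHCRecord(case=str(row["case"]), proportions=props, flags=flags))
    return records


def write_ihc(records: list[IHCRecord], path) -> None:
    rows = []
    for r in records:
        row = {"case": r.case}
        for m in IHC_MARKERS:
            row[m] = r.proportions.get(m, "")
        row["flags"] = ";".join(sorted(r.flags))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
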