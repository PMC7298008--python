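"""Build and evaluate the basal-to-luminal transition (BLT) classifier.

LASSO selects ~28 of the 48 candidate marker genes; a linear discriminant
fit yields the BLT weights (negated LD1 coefficients, luminal-positive);
a 1000-point grid search places the cutoff; ROC analysis (against the
simulation truth, double-negatives removed) gives AUC and the optimal
operating point; stratified 5-fold cross-validation measures three-class
accuracy; and the (LD1, LD2) projection is written for plotting.
"""

import json
from pathlib import Path

from bltsub.blt import (
    blt_score,
    cv_accuracy,
    fit_blt,
    ld_projection,
    optimal_cutoff,
    roc,
    select_markers_lasso,
)
from bltsub.io import normalize_expression, read_expression, read_labels, read_panels

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    m = normalize_expression(read_expression(BASE / "synthetic" / "expression.tsv"))
    panels = {p.name: p for p in read_panels(BASE / "synthetic" / "panels.gmt")}
    labels = read_labels(BASE / "clustered_labels.csv", provenance="clustered")
    truth = read_labels(BASE / "synthetic" / "truth_labels.csv")
    candidates = panels["LUMINAL"].genes + panels["BASAL"].genes

    selected = select_markers_lasso(m, labels, candidates, target_nonzero=28)
    n_lum = sum(g in set(panels["LUMINAL"].genes) for g in selected)
    print(f"LASSO selected {len(selected)} genes ({n_lum} luminal + {len(selected) - n_lum} basal)")

    model = fit_blt(m, labels, selected)
    scores = blt_score(model, m)
    model.cutoff = optimal_cutoff(scores, labels)
    print(f"grid-searched BLT cutoff: {model.cutoff:.3f}")

    curve = roc(scores, truth)
    _, sens, spec = curve.optimal_point
    print(f"ROC vs truth: AUC {curve.auc:.3f}; optimal point sensitivity "
          f"{100 * sens:.1f}%, specificity {100 * spec:.1f}%")

    lum, bas = truth.of("luminal"), truth.of("basal")
    print(f"at the fitted cutoff: {100 * (scores.loc[lum] > model.cutoff).mean():.1f}% of "
          f"luminal score positive-side, "
          f"{100 * (scores.loc[bas] <= model.cutoff).mean():.1f}% of basal negative-side")

    accuracy = cv_accuracy(m, labels, selected, folds=5, seed=0)
    print(f"5-fold cross-validated three-class accuracy: {100 * accuracy:.1f}%")

    scores.rename("blt_score").to_csv(BASE / "blt_scores.csv", lineterminator="\n")
    ld_projection(model, m).to_csv(BASE / "ld_projection.csv", lineterminator="\n")
    (BASE / "blt_model.json").write_text(json.dumps({
        "selected_genes": model.selected_genes,
        "weights": model.weights.tolist(),
        "ld2_weights": model.ld2_weights.tolist(),
        "cutoff": model.cutoff,
        "metadata": model.metadata,
        "auc_vs_truth": curve.auc,
        "cv_accuracy": accuracy,
    }, indent=2) + "\n")
    print(f"wrote blt_model.json, blt_scores.csv, ld_projection.csv under {BASE}/")


if __name__ == "__main__":
    main()
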