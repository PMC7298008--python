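"""Quantify subtype-assignment confidence.

Computes pairwise cluster prediction strengths (50 random halvings each,
k-means with k=2 on the marker-gene space) and per-sample Bayes posterior
strengths under Gaussian class densities with a shared shrunk covariance;
a posterior >= 80% counts as a strong assignment.
"""

import json
from pathlib import Path

from bltsub.io import SUBTYPES, normalize_expression, read_expression, read_labels, read_panels
from bltsub.validity import PSConfig, fit_posterior_model, posterior_strengths, prediction_strength

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    m = normalize_expression(read_expression(BASE / "synthetic" / "expression.tsv"))
    panels = {p.name: p for p in read_panels(BASE / "synthetic" / "panels.gmt")}
    labels = read_labels(BASE / "clustered_labels.csv", provenance="clustered")
    markers = panels["LUMINAL"].genes + panels["BASAL"].genes
    counts = labels.counts()

    report: dict = {"prediction_strength": {}, "strong_posterior_fraction": {}}
    for pair in (("luminal", "basal"), ("luminal", "double_negative"),
                 ("basal", "double_negative")):
        if min(counts[pair[0]], counts[pair[1]]) < 4:
            continue
        res = prediction_strength(m, labels, pair, PSConfig(k=2, n_splits=50, seed=0),
                                  genes=markers)
        report["prediction_strength"][f"{pair[0]}_vs_{pair[1]}"] = res.ps_mean
        print(f"prediction strength {pair[0]} vs {pair[1]}: {100 * res.ps_mean:.1f}%")

    model = fit_posterior_model(m, labels, markers)
    table = posterior_strengths(model, m)
    table.probs.to_csv(BASE / "posteriors.csv", lineterminator="\n")
    for subtype in SUBTYPES:
        if counts[subtype] == 0:
            continue
        frac = table.strong_fraction(labels, subtype)
        report["strong_posterior_fraction"][subtype] = frac
        print(f"cases with >=80% posterior strength, {subtype}: {100 * frac:.1f}%")

    (BASE / "validity.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {BASE / 'validity.json'} and posteriors.csv")


if __name__ == "__main__":
    main()
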