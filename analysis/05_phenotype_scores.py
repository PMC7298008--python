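"""EMT and immune phenotype of the molecular subtypes.

Computes the correlation-weighted 76-gene EMT score (anchored on CDH1,
cohort-centered), the 128-gene immune score and the checkpoint-panel score
(per-sample panel median minus grand mean), and summarizes them per truth
subtype.  Expected pattern: double-negative tumors score lowest on EMT
(activated mesenchymal state) and highest on immune and checkpoint panels.
"""

import json
from pathlib import Path

from bltsub.io import SUBTYPES, normalize_expression, read_expression, read_labels, read_panels
from bltsub.scores import emt_score, emt_weights, median_signature_score

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    m = normalize_expression(read_expression(BASE / "synthetic" / "expression.tsv"))
    panels = {p.name: p for p in read_panels(BASE / "synthetic" / "panels.gmt")}
    truth = read_labels(BASE / "synthetic" / "truth_labels.csv")

    sig = emt_weights(m, panels["EMT76"].genes, anchor="CDH1")
    vectors = {
        "emt": emt_score(m, sig),
        "immune": median_signature_score(m, panels["IMMUNE128"]),
        "checkpoint": median_signature_score(m, panels["CHECKPOINT"]),
    }

    summary = {}
    for name, vec in vectors.items():
        vec.rename("score").to_csv(BASE / f"{name}_scores.csv", lineterminator="\n")
        summary[name] = {s: float(vec.loc[truth.of(s)].mean()) for s in SUBTYPES}
        means = "  ".join(f"{s}: {v:+.2f}" for s, v in summary[name].items())
        print(f"{name:>10} score group means   {means}")

    (BASE / "phenotype_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"wrote per-sample score CSVs and phenotype_summary.json under {BASE}/")


if __name__ == "__main__":
    main()
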