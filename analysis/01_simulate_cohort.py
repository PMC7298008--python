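"""Generate the study cohort: a 200-sample synthetic bladder-cancer cohort.

Draws the default cohort (100 luminal / 85 basal / 15 double-negative,
marker shift 2 log2 units, noise SD 1, seed 17) and writes its expression
matrix, truth labels, IHC table, and marker panels under results/synthetic/.
"""

from pathlib import Path

from bltsub.ihc import write_ihc
from bltsub.io import write_expression, write_gmt, write_labels
from bltsub.synthetic import SyntheticConfig, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    config = SyntheticConfig()
    cohort = generate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, OUT / "expression.tsv")
    write_labels(cohort.truth_labels, OUT / "truth_labels.csv")
    write_ihc(cohort.ihc_records, OUT / "ihc.csv")
    write_gmt(cohort.panels.values(), OUT / "panels.gmt")
    counts = cohort.truth_labels.counts()
    print(f"cohort: {config.n_total} samples "
          f"({counts['luminal']} luminal / {counts['basal']} basal / "
          f"{counts['double_negative']} double-negative), "
          f"{cohort.expression.data.shape[0]} genes, seed {config.seed}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
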