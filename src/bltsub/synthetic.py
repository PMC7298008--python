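"""Seeded synthetic bladder-cancer cohorts.

The generator emulates the statistical structure the subtyping analysis
assumes: three subtypes (luminal, basal, double-negative) with elevated
luminal-panel expression in luminal tumors, elevated basal-panel expression
in basal tumors (a minority of which co-express luminal markers), a
mesenchymal EMT shift in double-negative tumors (epithelial adhesion genes
down, EMT transcription factors up), graded immune- and checkpoint-panel
elevation luminal < basal < double-negative, and per-subtype Beta-distributed
immunohistochemistry staining proportions with the reciprocal GATA3 / KRT5-6
pattern.

Expression is drawn on the linear scale as ``2 ** Normal(mu_g + shift, sigma)``
so that all effect sizes are exact shifts in log2 units; per-gene baselines
``mu_g ~ Normal(6, 1)`` give a microarray-like dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bltsub.io import ExpressionMatrix, MarkerPanel, SubtypeLabelSet, SUBTYPES
from bltsub.ihc import IHCRecord

# Per-subtype Beta shape pairs for staining proportions; reproduces the
# reciprocal GATA3-positive / KRT5-6-positive pattern, with double-negative
# tumors negative for both.
DEFAULT_IHC_BETA = {
    "luminal": {"gata3": (8.0, 2.0), "krt5_6": (1.0, 19.0)},
    "basal": {"gata3": (1.0, 19.0), "krt5_6": (8.0, 2.0)},
    "double_negative": {"gata3": (1.0, 19.0), "krt5_6": (1.0, 19.0)},
}


@dataclass
class SyntheticConfig:
    """Cohort-generation parameters.

    Subtype counts default to the TCGA-like split (100 / 85 / 15, i.e.
    roughly 52/44/4% luminal/basal/double-negative at cohort size 200 with a
    somewhat enlarged double-negative group so that group-level statistics
    are estimable).  Effect sizes are shifts in log2 units; ``noise_sd`` is
    the within-group log2 standard deviation.
    """

    n_luminal: int = 100
    n_basal: int = 85
    n_double_negative: int = 15
    effect_size_markers: float = 2.0
    effect_size_emt: float = 1.0
    effect_size_immune: float = 1.0
    noise_sd: float = 1.0
    n_background_genes: int = 500
    frac_basal_coexpressing: float = 0.15
    seed: int = 17
    ihc_beta_params: dict = field(default_factory=lambda: {
        s: dict(m) for s, m in DEFAULT_IHC_BETA.items()
    })

    def __post_init__(self) -> None:
        for name in ("n_luminal", "n_basal", "n_double_negative", "n_background_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_luminal + self.n_basal + self.n_double_negative < 2:
            raise ValueError("total sample count must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.frac_basal_coexpressing <= 1.0:
            raise ValueError("frac_basal_coexpressing must be in [0, 1]")
        for subtype, markers in self.ihc_beta_params.items():
            if subtype not in SUBTYPES:
                raise ValueError(f"unknown subtype {subtype!r} in ihc_beta_params")
            for marker, (a, b) in markers.items():
                if a <= 0 or b <= 0:
                    raise ValueError(f"Beta shapes for {subtype}/{marker} must be positive")

    @property
    def n_total(self) -> int:
        return self.n_luminal + self.n_basal + self.n_double_negative


@dataclass
class SyntheticCohort:
    """A generated cohort: raw expression, truth labels, IHC table, panels."""

    expression: ExpressionMatrix
    truth_labels: SubtypeLabelSet
    ihc_records: list[IHCRecord]
    panels: dict[str, MarkerPanel]
    config: SyntheticConfig
    baseline_log2: pd.Series | None = None  # per-gene mu_g, stored for reproducibility

    def __post_init__(self) -> None:
        samples = set(self.expression.samples)
        if set(self.truth_labels.samples) != samples:
            raise ValueError("truth labels do not match expression columns")
        if {r.case for r in self.ihc_records} != samples:
            raise ValueError("IHC records do not match expression columns")
        gene_set = set(self.expression.genes)
        for panel in self.panels.values():
            missing = set(panel.genes) - gene_set
            if missing:
                raise ValueError(f"panel {panel.name} genes absent from matrix: {sorted(missing)[:5]}")


def default_panels() -> dict[str, MarkerPanel]:
    """The synthesized marker panels used by the generator.

    Gene names are synthetic placeholders sized like the real panels
    (28 luminal, 20 basal, 76 EMT, 128 immune, 12 checkpoint) so that panel
    files and real symbol lists are interchangeable.  The EMT panel keeps
    the literal epithelial anchors CDH1, CLDN1, TJP1 and the mesenchymal
    transcription factor ZEB2; its first 38 genes are epithelial (shifted
    down in double-negative tumors), the last 38 mesenchymal (shifted up).
    """
    luminal = [f"LUM{i:03d}" for i in range(1, 29)]
    basal = [f"BAS{i:03d}" for i in range(1, 21)]
    emt_epithelial = ["CDH1", "CLDN1", "TJP1"] + [f"EMTE{i:03d}" for i in range(1, 36)]
    emt_mesenchymal = ["ZEB2"] + [f"EMTT{i:03d}" for i in range(1, 38)]
    immune = [f"IMM{i:03d}" for i in range(1, 129)]
    checkpoint = [f"CPT{i:03d}" for i in range(1, 13)]
    return {
        "luminal": MarkerPanel("LUMINAL", luminal, role="luminal"),
        "basal": MarkerPanel("BASAL", basal, role="basal"),
        "emt": MarkerPanel("EMT76", emt_epithelial + emt_mesenchymal, role="emt"),
        "immune": MarkerPanel("IMMUNE128", immune, role="immune"),
        "checkpoint": MarkerPanel("CHECKPOINT", checkpoint, role="checkpoint"),
    }


EMT_N_EPITHELIAL = 38  # first genes of the EMT panel behave epithelially


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw a cohort under ``config``; identical config + seed reproduce it.

    Linear-scale expression is ``2 ** Normal(mu_g + shift_gs, noise_sd)``
    where ``shift_gs`` encodes the subtype structure:

    * luminal samples: +delta on the luminal panel;
    * basal samples: +delta on the basal panel, and a fraction
      ``frac_basal_coexpressing`` of them additionally +delta/2 on the
      luminal panel;
    * double-negative samples: both marker panels at baseline, epithelial
      EMT genes -delta_EMT, mesenchymal EMT transcription factors +delta_EMT;
    * immune and checkpoint panels: 0 / +delta_imm/2 / +delta_imm for
      luminal / basal / double-negative;
    * background genes: never shifted.

    IHC staining proportions are drawn per subtype and marker from the
    configured Beta distributions.
    """
    config = config or SyntheticConfig()
    panels = default_panels()
    for name, panel in panels.items():
        if not panel.genes:
            raise ValueError(f"empty panel {name}")

    rng = np.random.default_rng(config.seed)

    genes: list[str] = []
    for panel in panels.values():
        genes.extend(panel.genes)
    genes.extend(f"BG{i:04d}" for i in range(1, config.n_background_genes + 1))
    gene_index = pd.Index(genes, name="gene")
    gene_pos = {g: i for i, g in enumerate(genes)}

    n = config.n_total
    samples = pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="sample")
    subtype_of = (
        ["luminal"] * config.n_luminal
        + ["basal"] * config.n_basal
        + ["double_negative"] * config.n_double_negative
    )
    truth = SubtypeLabelSet(pd.Series(subtype_of, index=samples), provenance="truth")

    mu = rng.normal(6.0, 1.0, size=len(genes))

    shift = np.zeros((len(genes), n))
    lum_rows = [gene_pos[g] for g in panels["luminal"].genes]
    bas_rows = [gene_pos[g] for g in panels["basal"].genes]
    emt_genes = panels["emt"].genes
    emt_epi_rows = [gene_pos[g] for g in emt_genes[:EMT_N_EPITHELIAL]]
    emt_mes_rows = [gene_pos[g] for g in emt_genes[EMT_N_EPITHELIAL:]]
    imm_rows = [gene_pos[g] for g in panels["immune"].genes + panels["checkpoint"].genes]

    is_lum = np.array([s == "luminal" for s in subtype_of])
    is_bas = np.array([s == "basal" for s in subtype_of])
    is_dn = np.array([s == "double_negative" for s in subtype_of])

    delta, d_emt, d_imm = config.effect_size_markers, config.effect_size_emt, config.effect_size_immune
    shift[np.ix_(lum_rows, np.where(is_lum)[0])] += delta
    shift[np.ix_(bas_rows, np.where(is_bas)[0])] += delta

    basal_idx = np.where(is_bas)[0]
    n_coexpr = int(round(config.frac_basal_coexpressing * len(basal_idx)))
    if n_coexpr > 0:
        coexpr = rng.choice(basal_idx, size=n_coexpr, replace=False)
        shift[np.ix_(lum_rows, coexpr)] += delta / 2.0

    dn_cols = np.where(is_dn)[0]
    shift[np.ix_(emt_epi_rows, dn_cols)] -= d_emt
    shift[np.ix_(emt_mes_rows, dn_cols)] += d_emt

    shift[np.ix_(imm_rows, np.where(is_bas)[0])] += d_imm / 2.0
    shift[np.ix_(imm_rows, dn_cols)] += d_imm

    log2_values = rng.normal(mu[:, None] + shift, config.noise_sd)
    data = pd.DataFrame(np.exp2(log2_values), index=gene_index, columns=samples)
    expression = ExpressionMatrix(data, scale="linear")

    records = []
    for sample, subtype in zip(samples, subtype_of):
        props = {
            marker: float(rng.beta(a, b))
            for marker, (a, b) in config.ihc_beta_params[subtype].items()
        }
        records.append(IHCRecord(case=sample, proportions=props))

    return SyntheticCohort(expression, truth, records, panels, config,
                           baseline_log2=pd.Series(mu, index=gene_index, name="mu_g"))
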