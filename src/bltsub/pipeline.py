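"""End-to-end synthetic-recovery pipeline.

Glue that runs the full analysis on one generated cohort — simulate,
normalize, cluster, validate, fit the BLT classifier, compute phenotype
scores, classify by IHC — and collects every headline metric into one
manifest dict.  Used by the command-line ``run-all``, the numbered analysis
drivers, and the acceptance script.
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np

from bltsub.blt import (
    blt_score,
    cv_accuracy,
    fit_blt,
    ld_projection,
    optimal_cutoff,
    roc,
    select_markers_lasso,
)
from bltsub.ihc import contingency_summary, lr_loocv, rule_classify
from bltsub.io import SUBTYPES, normalize_expression
from bltsub.scores import emt_score, emt_weights, median_signature_score
from bltsub.subtyping import cluster_subtypes
from bltsub.synthetic import SyntheticConfig, generate_cohort
from bltsub.validity import PSConfig, fit_posterior_model, posterior_strengths, prediction_strength


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from one global seed."""
    return (zlib.crc32(stage.encode()) ^ int(global_seed)) % (2**31)


def run_pipeline(config: SyntheticConfig | None = None, *, seed: int | None = None,
                 dn_threshold: float = -0.5, ps_splits: int = 50,
                 cv_folds: int = 5, target_nonzero: int = 28) -> dict:
    """Run the whole subtyping analysis on one synthetic cohort.

    When ``seed`` is given it fans out into per-stage seeds (generator,
    prediction-strength splits, CV folds), overriding the config's own
    seed.  Returns a dict with the cohort artifacts under ``"artifacts"``
    and all scalar metrics under ``"metrics"``.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=derive_seed(seed, "simulate"))
    ps_seed = derive_seed(seed if seed is not None else config.seed, "prediction_strength")
    cv_seed = derive_seed(seed if seed is not None else config.seed, "cv_folds")

    cohort = generate_cohort(config)
    norm = normalize_expression(cohort.expression)
    panels = cohort.panels
    truth = cohort.truth_labels

    # --- subtype discovery -------------------------------------------------
    clustered = cluster_subtypes(norm, panels["luminal"], panels["basal"],
                                 dn_threshold=dn_threshold)
    agreement = clustered.agreement(truth)

    marker_union = panels["luminal"].genes + panels["basal"].genes

    # --- cluster validity --------------------------------------------------
    ps = {}
    pairs = [("luminal", "basal"), ("luminal", "double_negative"), ("basal", "double_negative")]
    for pair in pairs:
        counts = clustered.counts()
        if min(counts[pair[0]], counts[pair[1]]) < 4:
            continue
        res = prediction_strength(norm, clustered, pair,
                                  PSConfig(k=2, n_splits=ps_splits, seed=ps_seed),
                                  genes=marker_union)
        ps[f"{pair[0]}_vs_{pair[1]}"] = res.ps_mean

    post_model = fit_posterior_model(norm, clustered, marker_union)
    post = posterior_strengths(post_model, norm)
    strong_frac = {s: post.strong_fraction(clustered, s)
                   for s in SUBTYPES if len(clustered.of(s)) > 0}

    # --- BLT classifier ----------------------------------------------------
    selected = select_markers_lasso(norm, clustered, marker_union,
                                    target_nonzero=target_nonzero)
    n_lum_sel = sum(g in set(panels["luminal"].genes) for g in selected)
    model = fit_blt(norm, clustered, selected)
    scores = blt_score(model, norm)
    model.cutoff = optimal_cutoff(scores, clustered)
    curve = roc(scores, truth)
    accuracy = cv_accuracy(norm, clustered, selected, folds=cv_folds, seed=cv_seed)
    projection = ld_projection(model, norm)

    # recovery of truth labels at the fitted cutoff (luminal-positive rule)
    lum_truth = truth.of("luminal")
    bas_truth = truth.of("basal")
    sensitivity = float((scores.loc[lum_truth] > model.cutoff).mean())
    specificity = float((scores.loc[bas_truth] <= model.cutoff).mean())

    # --- phenotype scores --------------------------------------------------
    emt_sig = emt_weights(norm, panels["emt"].genes, anchor="CDH1")
    emt = emt_score(norm, emt_sig)
    immune = median_signature_score(norm, panels["immune"])
    checkpoint = median_signature_score(norm, panels["checkpoint"])
    group_means = {
        name: {s: float(vec.loc[truth.of(s)].mean()) for s in SUBTYPES if len(truth.of(s)) > 0}
        for name, vec in (("emt", emt), ("immune", immune), ("checkpoint", checkpoint))
    }

    # --- IHC surrogate classifier ------------------------------------------
    calls = [rule_classify(r) for r in cohort.ihc_records]
    contingency = contingency_summary(calls, truth)
    loocv_acc, _ = lr_loocv(cohort.ihc_records, truth)

    metrics = {
        "n_samples": config.n_total,
        "clustering_agreement": agreement,
        "prediction_strength": ps,
        "strong_posterior_fraction": strong_frac,
        "n_selected_genes": len(selected),
        "n_selected_luminal": n_lum_sel,
        "n_selected_basal": len(selected) - n_lum_sel,
        "blt_cutoff": model.cutoff,
        "blt_auc": curve.auc,
        "blt_sensitivity": sensitivity,
        "blt_specificity": specificity,
        "roc_optimal_sensitivity": curve.optimal_point[1],
        "roc_optimal_specificity": curve.optimal_point[2],
        "cv_accuracy": accuracy,
        "score_group_means": group_means,
        "ihc_overall_concordance": contingency["overall_concordance"],
        "ihc_loocv_accuracy": loocv_acc,
    }
    artifacts = {
        "cohort": cohort,
        "normalized": norm,
        "clustered_labels": clustered,
        "posterior": post,
        "blt_model": model,
        "blt_scores": scores,
        "roc": curve,
        "ld_projection": projection,
        "emt_signature": emt_sig,
        "emt_score": emt,
        "immune_score": immune,
        "checkpoint_score": checkpoint,
        "ihc_calls": calls,
        "ihc_contingency": contingency,
    }
    return {"metrics": metrics, "artifacts": artifacts,
            "seeds": {"simulate": config.seed, "prediction_strength": ps_seed,
                      "cv_folds": cv_seed}}
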