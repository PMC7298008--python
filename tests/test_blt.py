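import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay
from scipy.stats import mannwhitneyu

from bltsub.blt import (
    blt_score,
    cv_accuracy,
    fit_blt,
    ld_projection,
    optimal_cutoff,
    roc,
    select_markers_lasso,
)
from bltsub.io import ExpressionMatrix, SubtypeLabelSet, normalize_expression
from bltsub.synthetic import SyntheticConfig, generate_cohort

from conftest import make_labels, make_matrix


def _binary_cohort(n_per=75, n_signal=10, n_noise=38, delta=3.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    values = rng.normal(size=(n_signal + n_noise, n))
    values[:n_signal, :n_per] += delta
    genes = [f"SIG{i:02d}" for i in range(n_signal)] + [f"NOI{i:02d}" for i in range(n_noise)]
    m = make_matrix(values, genes=genes)
    labels = make_labels({f"S{i:03d}": ("luminal" if i < n_per else "basal")
                          for i in range(n)}, provenance="clustered")
    return m, labels, genes


class TestLassoSelection:
    def test_signal_genes_recovered(self):
        m, labels, genes = _binary_cohort()
        selected = select_markers_lasso(m, labels, genes, target_nonzero=10)
        assert set(selected) <= {f"SIG{i:02d}" for i in range(10)}
        assert len(selected) >= 8

    def test_constant_features_select_nothing(self):
        m = make_matrix(np.ones((6, 40)))
        labels = make_labels({f"S{i:03d}": ("luminal" if i < 20 else "basal")
                              for i in range(40)}, provenance="clustered")
        with pytest.raises(ValueError, match="no penalty"):
            select_markers_lasso(m, labels, list(m.genes), target_nonzero=4)

    def test_panel_order_invariance(self):
        m, labels, genes = _binary_cohort(n_per=40, n_noise=10)
        a = select_markers_lasso(m, labels, genes, target_nonzero=10)
        b = select_markers_lasso(m, labels, list(reversed(genes)), target_nonzero=10)
        assert set(a) == set(b)


class TestFitBLT:
    def _toy(self, seed=0, n=200):
        # two genes, two groups, known separation along gene 0
        rng = np.random.default_rng(seed)
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        L = np.linalg.cholesky(cov)
        a = (L @ rng.normal(size=(2, n))) + np.array([[3.0], [0.0]])
        b = L @ rng.normal(size=(2, n))
        m = make_matrix(np.hstack([a, b]), genes=["g0", "g1"])
        labels = make_labels({f"S{i:03d}": ("luminal" if i < n else "basal")
                              for i in range(2 * n)}, provenance="clustered")
        return m, labels

    def test_direction_matches_fisher_closed_form(self):
        m, labels = self._toy()
        model = fit_blt(m, labels, ["g0", "g1"], shrinkage=0.0)
        # closed-form Fisher discriminant: Sw^-1 (mu_L - mu_B) from the sample
        X = m.data.to_numpy().T
        y = labels.labels.to_numpy()
        mu_l = X[y == "luminal"].mean(axis=0)
        mu_b = X[y == "basal"].mean(axis=0)
        centered = X.copy()
        centered[y == "luminal"] -= mu_l
        centered[y == "basal"] -= mu_b
        Sw = centered.T @ centered / (len(y) - 2)
        d = np.linalg.solve(Sw, mu_l - mu_b)
        cos = model.weights @ d / (np.linalg.norm(model.weights) * np.linalg.norm(d))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_orientation_luminal_scores_higher(self, pipeline_result):
        art = pipeline_result["artifacts"]
        labels = art["clustered_labels"]
        scores = art["blt_scores"]
        assert scores.loc[labels.of("luminal")].mean() > scores.loc[labels.of("basal")].mean()

    def test_collinear_genes_still_finite(self):
        m, labels = self._toy(n=50)
        dup = m.data.copy()
        dup.loc["g2"] = dup.loc["g0"]  # exact copy -> singular pooled covariance
        model = fit_blt(ExpressionMatrix(dup, scale=m.scale), labels, ["g0", "g1", "g2"])
        assert np.isfinite(model.weights).all()

    def test_two_group_model_has_no_ld2(self):
        m, labels = self._toy(n=30)
        model = fit_blt(m, labels, ["g0", "g1"])
        assert model.ld2_weights is None
        with pytest.raises(ValueError, match="second discriminant"):
            ld_projection(model, m)


class TestBLTScore:
    def test_linearity(self, pipeline_result):
        art = pipeline_result["artifacts"]
        model, norm = art["blt_model"], art["normalized"]
        scores = art["blt_scores"]
        # zero expression on the model genes -> score 0
        zero = make_matrix(np.zeros((len(model.selected_genes), 3)),
                           genes=model.selected_genes)
        assert (blt_score(model, zero) == 0).all()
        # perturbing one gene by delta changes the score by exactly W_i * delta
        perturbed = norm.data.copy()
        gene = model.selected_genes[0]
        perturbed.loc[gene] += 2.5
        new = blt_score(model, ExpressionMatrix(perturbed, scale=norm.scale))
        np.testing.assert_allclose(new - scores, model.weights[0] * 2.5, atol=1e-9)

    def test_missing_model_gene_is_an_error(self, pipeline_result):
        model = pipeline_result["artifacts"]["blt_model"]
        m = make_matrix(np.zeros((2, 2)), genes=model.selected_genes[:2])
        with pytest.raises(ValueError, match="missing"):
            blt_score(model, m)

    def test_affine_equivariance(self, pipeline_result):
        art = pipeline_result["artifacts"]
        model, norm = art["blt_model"], art["normalized"]
        scaled = ExpressionMatrix(norm.data * 3.0, scale=norm.scale)
        np.testing.assert_allclose(blt_score(model, scaled).to_numpy(),
                                   3.0 * art["blt_scores"].to_numpy(), rtol=1e-10)

    def test_default_cohort_separation_at_cutoff(self, pipeline_result):
        # luminal tumors score above, basal below, the grid-searched cutoff
        art = pipeline_result["artifacts"]
        labels = art["clustered_labels"]
        scores, cutoff = art["blt_scores"], art["blt_model"].cutoff
        assert (scores.loc[labels.of("luminal")] > cutoff).mean() >= 0.90
        assert (scores.loc[labels.of("basal")] <= cutoff).mean() >= 0.85


def _brute_force_cutoff_misclass(lum, bas):
    """Minimum misclassification over all interval midpoints (oracle)."""
    points = np.sort(np.concatenate([lum, bas]))
    candidates = np.concatenate([[points[0] - 1],
                                 (points[:-1] + points[1:]) / 2,
                                 [points[-1] + 1]])
    return min((lum <= c).sum() + (bas > c).sum() for c in candidates)


class TestOptimalCutoff:
    def test_separated_scores(self):
        scores = pd.Series([2.0, 3.0, 4.0, -2.0, -3.0, -4.0],
                           index=[f"S{i}" for i in range(6)])
        labels = make_labels({f"S{i}": ("luminal" if i < 3 else "basal") for i in range(6)})
        c = optimal_cutoff(scores, labels)
        assert -2.0 < c < 2.0
        lum, bas = scores.iloc[:3], scores.iloc[3:]
        assert (lum <= c).sum() + (bas > c).sum() == 0

    def test_toy_matches_brute_force_oracle(self):
        lum = np.array([2.0, 3.0, 0.5])
        bas = np.array([-1.0, -2.0, 1.0])
        scores = pd.Series(np.concatenate([lum, bas]), index=[f"S{i}" for i in range(6)])
        labels = make_labels({f"S{i}": ("luminal" if i < 3 else "basal") for i in range(6)})
        c = optimal_cutoff(scores, labels)
        achieved = (lum <= c).sum() + (bas > c).sum()
        assert achieved == _brute_force_cutoff_misclass(lum, bas) == 1

    def test_negation_symmetry(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=30), index=[f"S{i:02d}" for i in range(30)])
        labels = make_labels({f"S{i:02d}": ("luminal" if i < 15 else "basal")
                              for i in range(30)})
        swapped = make_labels({f"S{i:02d}": ("basal" if i < 15 else "luminal")
                               for i in range(30)})
        grid_step = (scores.max() - scores.min()) / 999
        assert optimal_cutoff(-scores, swapped) == pytest.approx(-optimal_cutoff(scores, labels),
                                                                 abs=2 * grid_step)

    def test_single_class_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        labels = make_labels({"a": "luminal", "b": "luminal"})
        with pytest.raises(ValueError):
            optimal_cutoff(scores, labels)


class TestROC:
    def test_perfect_separation(self):
        scores = pd.Series([3.0, 2.0, -2.0, -3.0], index=list("abcd"))
        labels = make_labels({"a": "luminal", "b": "luminal", "c": "basal", "d": "basal"})
        curve = roc(scores, labels)
        assert curve.auc == 1.0
        _, sens, spec = curve.optimal_point
        assert sens == 1.0 and spec == 1.0

    def test_auc_equals_u_statistic_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n1, n2 = rng.integers(3, 20, size=2)
            pool = rng.integers(0, 8, size=n1 + n2).astype(float)  # heavy ties
            scores = pd.Series(pool, index=[f"S{i:02d}" for i in range(n1 + n2)])
            labels = make_labels({f"S{i:02d}": ("luminal" if i < n1 else "basal")
                                  for i in range(n1 + n2)})
            curve = roc(scores, labels)
            u = mannwhitneyu(pool[:n1], pool[n1:], alternative="two-sided").statistic
            assert curve.auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(10)
        n = 2000
        scores = pd.Series(rng.normal(size=n), index=[f"S{i:04d}" for i in range(n)])
        labels = make_labels({f"S{i:04d}": ("luminal" if i < n // 2 else "basal")
                              for i in range(n)})
        assert 0.47 < roc(scores, labels).auc < 0.53

    def test_sensitivity_monotone_in_threshold(self, pipeline_result):
        curve = pipeline_result["artifacts"]["roc"]
        assert (np.diff(curve.sensitivity) >= 0).all()  # thresholds descend


class TestCVAccuracy:
    def test_perfectly_separable_cohort(self):
        m, labels, genes = _binary_cohort(n_per=40, delta=8.0, n_noise=5, seed=11)
        assert cv_accuracy(m, labels, genes[:10], folds=5, seed=0) == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(12)
        m = make_matrix(rng.normal(size=(10, 300)))
        perm = rng.permutation(300)
        subtype = np.array(["luminal", "basal", "double_negative"])[perm % 3]
        labels = make_labels(dict(zip(m.samples, subtype)), provenance="clustered")
        acc = cv_accuracy(m, labels, list(m.genes), folds=5, seed=1)
        assert 0.25 <= acc <= 0.42

    def test_fold_reduction_warning(self, caplog):
        m, labels, genes = _binary_cohort(n_per=4, n_noise=2, n_signal=4, delta=6.0)
        with caplog.at_level("WARNING"):
            cv_accuracy(m, labels, genes[:4], folds=5, seed=0)
        assert any("reducing folds" in r.message for r in caplog.records)

    def test_default_cohort_accuracy(self, pipeline_result):
        assert pipeline_result["metrics"]["cv_accuracy"] >= 0.90


class TestLDProjection:
    def test_ld1_is_negated_blt_score(self, pipeline_result):
        art = pipeline_result["artifacts"]
        np.testing.assert_array_equal(art["ld_projection"]["LD1"].to_numpy(),
                                      -art["blt_scores"].to_numpy())

    def test_group_mean_projects_to_centroid(self, pipeline_result):
        art = pipeline_result["artifacts"]
        model, norm, labels = art["blt_model"], art["normalized"], art["clustered_labels"]
        lum = labels.of("luminal")
        mean_profile = norm.data.loc[model.selected_genes, lum].mean(axis=1)
        m_one = make_matrix(mean_profile.to_numpy()[:, None], genes=model.selected_genes,
                            samples=["mean"])
        proj_one = ld_projection(model, m_one)
        centroid = art["ld_projection"].loc[lum].mean(axis=0)
        np.testing.assert_allclose(proj_one.loc["mean"].to_numpy(),
                                   centroid.to_numpy(), atol=1e-9)

    def test_three_groups_separate_in_ld_plane(self):
        # strong effect sizes: few samples sit inside another group's hull
        cohort = generate_cohort(SyntheticConfig(n_luminal=60, n_basal=50,
                                                 n_double_negative=12,
                                                 effect_size_markers=3.0,
                                                 effect_size_emt=2.0,
                                                 n_background_genes=100, seed=21))
        norm = normalize_expression(cohort.expression)
        truth = cohort.truth_labels
        genes = cohort.panels["luminal"].genes + cohort.panels["basal"].genes
        selected = select_markers_lasso(norm, truth, genes, target_nonzero=28)
        model = fit_blt(norm, truth, selected)
        proj = ld_projection(model, norm)
        overlapping = 0
        for subtype in ("luminal", "basal", "double_negative"):
            hull = Delaunay(proj.loc[truth.of(subtype)].to_numpy())
            others = proj.drop(index=truth.of(subtype)).to_numpy()
            overlapping += int((hull.find_simplex(others) >= 0).sum())
        assert overlapping / len(proj) < 0.10
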