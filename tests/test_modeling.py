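"""Fold planning, classifiers, metrics, score significance, overlays."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_score
from sklearn.svm import SVC

from glandcraft.classifiers import MLPNet, train_mlp, train_svm_cascade
from glandcraft.crossval import make_fold_plan
from glandcraft.evaluation import (binary_metrics, evaluate, predict_overlay,
                                   score_significance)


def three_blobs(rng, n_per=60, sep=10.0, n_patients=6):
    centers = {"artefact": (0, 0), "benign": (sep, 0), "grade3": (0, sep)}
    X, y, g = [], [], []
    for lab, c in centers.items():
        X.append(rng.normal(0, 1, (n_per, 2)) + c)
        y += [lab] * n_per
        g += [f"p{i % n_patients}" for i in range(n_per)]
    return np.vstack(X), np.array(y), np.array(g)


class TestFoldPlan:
    def test_five_patients_one_per_fold(self):
        pats = np.repeat([f"p{i}" for i in range(5)], 10)
        labels = np.tile(["artefact", "benign", "grade3", "benign", "grade3"], 10)
        plan = make_fold_plan(pats, labels, k_outer=5, seed=0)
        assert sorted(plan.assignment.values()) == [1, 2, 3, 4, 5]

    def test_ten_equal_patients_two_per_fold(self):
        pats = np.repeat([f"p{i}" for i in range(10)], 6)
        labels = np.tile(["artefact", "benign", "grade3"], 20)
        plan = make_fold_plan(pats, labels, k_outer=5, seed=1)
        folds = list(plan.assignment.values())
        assert all(folds.count(f) == 2 for f in range(1, 6))

    def test_cohort_folds_are_class_balanced(self, study_table):
        plan = make_fold_plan(study_table.patient_ids, study_table.labels,
                              k_outer=5, seed=0)
        fold_of = plan.fold_of(study_table.patient_ids)
        global_frac = 1 / 3
        for f in range(1, 6):
            labels = study_table.labels[fold_of == f]
            for cls in ("artefact", "benign", "grade3"):
                frac = (labels == cls).mean()
                assert abs(frac - global_frac) / global_frac <= 0.15

    def test_patient_integrity(self, study_table):
        plan = make_fold_plan(study_table.patient_ids, study_table.labels,
                              k_outer=5, seed=0)
        for pat in np.unique(study_table.patient_ids):
            folds = {plan.assignment[pat]}
            assert len(folds) == 1

    def test_too_few_patients_is_an_error(self):
        with pytest.raises(ValueError):
            make_fold_plan(np.array(["a", "b"]), np.array(["x", "y"]), k_outer=5)


class TestSvmCascade:
    def test_separable_blobs_reach_perfect_training_accuracy(self, rng):
        X, y, g = three_blobs(rng)
        bundle = train_svm_cascade(X, y, g, budget=5, method="grid", seed=0)
        assert (bundle.predict(X) == y).mean() == 1.0
        proba = bundle.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_quadratic_kernel_solves_xor_where_linear_fails(self, rng):
        n = 200
        X = rng.uniform(-1, 1, (n, 2))
        y = ((X[:, 0] * X[:, 1]) > 0).astype(int)
        quad = cross_val_score(SVC(kernel="poly", degree=2, coef0=1.0, C=10),
                               X, y, cv=5).mean()
        lin = cross_val_score(SVC(kernel="linear", C=10), X, y, cv=5).mean()
        assert quad >= 0.95
        assert lin <= 0.7

    def test_cascade_handles_xor_gland_stage(self, rng):
        n = 240
        Xg = rng.uniform(-1, 1, (n, 2)) * 3
        yg = np.where(Xg[:, 0] * Xg[:, 1] > 0, "benign", "grade3")
        Xa = rng.normal(0, 0.3, (n // 2, 2)) + (12, 12)
        X = np.vstack([Xg, Xa])
        y = np.concatenate([yg, ["artefact"] * (n // 2)])
        g = np.array([f"p{i % 10}" for i in range(len(y))])
        bundle = train_svm_cascade(X, y, g, budget=8, seed=1)
        assert (bundle.predict(X) == y).mean() >= 0.95

    def test_tuning_is_deterministic(self, rng):
        X, y, g = three_blobs(rng, n_per=40)
        a = train_svm_cascade(X, y, g, budget=6, seed=3)
        b = train_svm_cascade(X, y, g, budget=6, seed=3)
        assert a.hyperparams == b.hyperparams

    def test_budget_below_five_rejected(self, rng):
        X, y, g = three_blobs(rng, n_per=20)
        with pytest.raises(ValueError):
            train_svm_cascade(X, y, g, budget=3)

    def test_missing_stage_class_rejected(self, rng):
        X, y, g = three_blobs(rng, n_per=20)
        keep = y != "grade3"
        with pytest.raises(ValueError, match="stage B"):
            train_svm_cascade(X[keep], y[keep], g[keep], budget=5)


class TestMLP:
    def test_well_separated_blobs_classified_perfectly(self, rng):
        X, y, _ = three_blobs(rng, n_per=80)
        bundle = train_mlp(X, y, seed=0)
        assert (bundle.predict(X) == y).mean() == 1.0

    def test_adaptive_rule_never_accepts_large_loss_increase(self, rng):
        X, y, _ = three_blobs(rng, n_per=40, sep=3.0)
        net = MLPNet(seed=0, max_epochs=200)
        net.fit(X, y)
        hist = np.array(net.loss_history_)
        assert np.isfinite(hist).all()
        assert (hist[1:] <= hist[:-1] * 1.04 + 1e-12).all()

    def test_fixed_seed_reproduces_weights(self, rng):
        X, y, _ = three_blobs(rng, n_per=30)
        a = MLPNet(seed=5, max_epochs=50).fit(X, y)
        b = MLPNet(seed=5, max_epochs=50).fit(X, y)
        assert all(np.array_equal(p, q) for p, q in zip(a.params_, b.params_))

    def test_needs_all_three_classes(self, rng):
        X, y, _ = three_blobs(rng, n_per=20)
        with pytest.raises(ValueError):
            train_mlp(X[y != "artefact"], y[y != "artefact"], seed=0)


class TestMetrics:
    def test_stated_confusion_matrix(self):
        # truth x prediction counts [[40, 10], [5, 45]], positive = second
        y_true = np.array([0] * 50 + [1] * 50)
        y_pred = np.array([0] * 40 + [1] * 10 + [0] * 5 + [1] * 45)
        m = binary_metrics(y_true, y_pred)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(45 / 55)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_metric_identities_from_confusion(self, rng):
        y_true = rng.integers(0, 2, 300)
        y_pred = rng.integers(0, 2, 300)
        m = binary_metrics(y_true, y_pred)
        tn, fp, fn, tp = m["confusion"]
        assert m["accuracy"] == pytest.approx((tp + tn) / 300)
        if m["ppv"] + m["sensitivity"] > 0:
            assert m["f_score"] == pytest.approx(
                2 * m["ppv"] * m["sensitivity"] / (m["ppv"] + m["sensitivity"]))

    def test_random_scores_give_half_auc(self, rng):
        y = rng.integers(0, 2, 1000)
        s = rng.random(1000)
        m = binary_metrics(y, (s > 0.5).astype(int), s)
        assert m["auc"] == pytest.approx(0.5, abs=0.05)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 500)
        s = rng.random(500)
        assert roc_auc_score(y, s) == pytest.approx(
            roc_auc_score(y, np.exp(3 * s - 1)))

    def test_perfect_bundle_scores_everything_one(self, rng):
        X, y, g = three_blobs(rng, n_per=40)
        bundle = train_svm_cascade(X, y, g, budget=5, method="grid", seed=0)
        rep = evaluate(bundle, X, y)
        assert rep.multiclass_accuracy == 1.0
        for problem in (rep.artefact_vs_gland, rep.benign_vs_grade3):
            for k in ("sensitivity", "specificity", "auc", "accuracy"):
                assert problem[k] == 1.0

    def test_empty_test_fold_rejected(self, rng):
        X, y, g = three_blobs(rng, n_per=20)
        bundle = train_svm_cascade(X, y, g, budget=5, method="grid", seed=0)
        with pytest.raises(ValueError):
            evaluate(bundle, X[:0], y[:0])


class TestScoreSignificance:
    def test_one_hot_scores_are_highly_significant(self, rng):
        labels = np.repeat(["artefact", "benign", "grade3"], 40)
        onehot = np.zeros((120, 3))
        onehot[np.arange(120), np.repeat([0, 1, 2], 40)] = 1.0
        scores = np.clip(onehot + rng.normal(0, 0.01, (120, 3)), 0, 1)
        ps = score_significance(scores, labels)
        assert all(p < 1e-10 for p in ps.values())

    def test_null_scores_give_uniform_p_values(self):
        from scipy import stats
        ps = []
        for seed in range(80):
            r = np.random.default_rng(seed)
            labels = np.repeat(["artefact", "benign", "grade3"], 100)
            scores = r.dirichlet(np.ones(3), size=300)
            ps.append(score_significance(scores, labels)["benign"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_column_reports_one(self):
        labels = np.repeat(["artefact", "benign", "grade3"], 10)
        scores = np.full((30, 3), 1 / 3)
        assert score_significance(scores, labels) == {
            "artefact": 1.0, "benign": 1.0, "grade3": 1.0}

    def test_deterministic(self, rng):
        labels = np.repeat(["artefact", "benign", "grade3"], 20)
        scores = rng.dirichlet(np.ones(3), size=60)
        assert score_significance(scores, labels) == score_significance(
            scores, labels)


class TestOverlay:
    def test_no_candidates_leaves_image_unchanged(self, rng):
        rgb = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        out = predict_overlay(rgb, [], [])
        assert np.array_equal(out, rgb)
        assert out is not rgb

    def test_truth_predictions_colour_contours_by_class(self, phantom_patch):
        labels = [c.label for c in phantom_patch.candidates]
        out = predict_overlay(phantom_patch.rgb, phantom_patch.candidates, labels)
        assert out.shape == phantom_patch.rgb.shape
        green = (out[..., 1] == 200) & (out[..., 0] == 0)
        red = (out[..., 0] == 220) & (out[..., 1] == 0)
        has_benign = any(lab == "benign" for lab in labels)
        has_grade3 = any(lab == "grade3" for lab in labels)
        assert green.any() == has_benign
        assert red.any() == has_grade3
        # artefact outlines are never drawn
        for cand, lab in zip(phantom_patch.candidates, labels):
            if lab == "artefact":
                r0, c0, r1, c1 = cand.bbox
                region = out[r0:r1, c0:c1]
                assert not ((region == (0, 200, 0)).all(-1)
                            | (region == (220, 0, 0)).all(-1)).any()
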