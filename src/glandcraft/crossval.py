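"""Patient-wise fold planning and nested cross-validation.

All candidates of one patient stay in the same outer fold.  The fold
planner is a greedy balanced bin-packer: patients are visited in
descending candidate count (seed-shuffled tie order) and each is assigned
to the fold that minimises the squared per-class count imbalance.  Nested
CV refits the feature-selection pipeline on every outer training split,
tunes the classifier on inner folds, and evaluates on the held-out fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classifiers import train_mlp, train_svm_cascade
from .evaluation import EvaluationReport, evaluate
from .selection import (FeatureTable, select_features, zscore_apply,
                        zscore_fit_transform)
from .utils import derive_seed

log = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Assignment of patients to outer folds (1..K)."""

    assignment: dict  # patient_id -> fold index
    k_outer: int
    k_inner: int
    seed: int

    def fold_of(self, patient_ids: np.ndarray) -> np.ndarray:
        return np.array([self.assignment[p] for p in patient_ids])

    def test_rows(self, patient_ids: np.ndarray, fold: int) -> np.ndarray:
        return self.fold_of(patient_ids) == fold


def make_fold_plan(patient_ids, labels, k_outer: int = 5, seed: int = 0,
                   k_inner: int = 10) -> FoldPlan:
    """Greedy class-balanced, patient-wise fold assignment."""
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels)
    patients = np.unique(patient_ids)
    if len(patients) < k_outer:
        raise ValueError(
            f"{len(patients)} patients cannot fill {k_outer} folds")
    classes = np.unique(labels)
    counts = {}
    for p in patients:
        rows = patient_ids == p
        counts[p] = np.array([(labels[rows] == c).sum() for c in classes])
    rng = np.random.default_rng(derive_seed(seed, "fold-plan"))
    order = list(rng.permutation(patients))
    order.sort(key=lambda p: -counts[p].sum())

    fold_counts = np.zeros((k_outer, len(classes)))
    assignment = {}
    for p in order:
        costs = [np.sum((fold_counts[f] + counts[p]) ** 2) for f in range(k_outer)]
        f = int(np.argmin(costs))
        assignment[p] = f + 1
        fold_counts[f] += counts[p]
    return FoldPlan(assignment=assignment, k_outer=k_outer, k_inner=k_inner,
                    seed=seed)


def nested_cv(table: FeatureTable, classifier: str = "svm",
              k_outer: int = 5, k_inner: int = 10, seed: int = 0,
              alpha: float = 1e-6, r_thresh: float = 0.95,
              global_selection: bool = False,
              svm_budget: int = 30, svm_method: str = "bayes",
              val_fraction: float = 0.1,
              fold_plan: FoldPlan | None = None) -> EvaluationReport:
    """Patient-wise nested cross-validation of the cascade SVM or the MLP.

    Selection is refit on each outer training split by default
    (``global_selection`` mimics a one-shot selection on the full table).
    """
    if classifier not in ("svm", "mlp"):
        raise ValueError("classifier must be 'svm' or 'mlp'")
    plan = fold_plan or make_fold_plan(table.patient_ids, table.labels,
                                       k_outer, seed, k_inner)
    global_sel = select_features(table, alpha, r_thresh) if global_selection else None

    folds = []
    for fold in range(1, plan.k_outer + 1):
        test_rows = plan.test_rows(table.patient_ids, fold)
        train = table.subset_rows(~test_rows)
        test = table.subset_rows(test_rows)
        if len(test.labels) == 0:
            log.warning("fold %d has no test rows; skipped", fold)
            continue
        sel = global_sel or select_features(train, alpha, r_thresh)
        train_sel = train.subset_features(sel.selected_names)
        norm_train, mu, sigma, _ = zscore_fit_transform(train_sel)
        X_test = zscore_apply(test.subset_features(sel.selected_names).X, mu, sigma)

        fold_seed = derive_seed(seed, "fold", fold)
        if classifier == "svm":
            bundle = train_svm_cascade(norm_train.X, norm_train.labels,
                                       norm_train.patient_ids,
                                       k_inner=plan.k_inner, budget=svm_budget,
                                       seed=fold_seed, method=svm_method)
        else:
            bundle = train_mlp(norm_train.X, norm_train.labels,
                               val_fraction=val_fraction, seed=fold_seed)
        bundle.selection = sel
        bundle.mu, bundle.sigma = mu, sigma
        bundle.feature_names = sel.selected_names
        folds.append(evaluate(bundle, X_test, test.labels, fold=fold))
    return EvaluationReport(folds=folds, classifier=classifier)
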