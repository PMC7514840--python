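"""Model/Results front-end for the gland-classification experiment.

``GlandClassificationModel`` wraps a feature table and the experiment
configuration; ``fit()`` runs feature selection and patient-wise nested
cross-validation and returns a ``GlandClassificationResults`` carrying the
per-problem metric estimates with their fold-to-fold spread, the
score-significance diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .crossval import nested_cv
from .evaluation import METRIC_NAMES
from .selection import FeatureTable


class GlandClassificationModel:
    """Three-class gland-candidate classification experiment.

    Parameters
    ----------
    table : FeatureTable
        Candidates x features matrix with class labels and patient ids.
    classifier : {"svm", "mlp"}
        Cascade of quadratic-kernel SVMs, or the 15-unit MLP.
    """

    def __init__(self, table: FeatureTable, classifier: str = "svm",
                 k_outer: int = 5, k_inner: int = 10,
                 alpha: float = 1e-6, r_thresh: float = 0.95,
                 svm_budget: int = 30, svm_method: str = "bayes",
                 global_selection: bool = False):
        self.table = table
        self.classifier = classifier
        self.k_outer = k_outer
        self.k_inner = k_inner
        self.alpha = alpha
        self.r_thresh = r_thresh
        self.svm_budget = svm_budget
        self.svm_method = svm_method
        self.global_selection = global_selection

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GlandClassificationModel":
        return cls(FeatureTable.from_dataframe(df), **kwargs)

    def fit(self, seed: int = 0) -> "GlandClassificationResults":
        report = nested_cv(self.table, classifier=self.classifier,
                           k_outer=self.k_outer, k_inner=self.k_inner,
                           seed=seed, alpha=self.alpha, r_thresh=self.r_thresh,
                           global_selection=self.global_selection,
                           svm_budget=self.svm_budget, svm_method=self.svm_method)
        return GlandClassificationResults(self, report, seed)


class GlandClassificationResults:
    """Fitted experiment: metric estimates, diagnostics and summary."""

    def __init__(self, model: GlandClassificationModel, report, seed: int):
        self.model = model
        self.report = report
        self.seed = seed
        mc = report.multiclass_accuracy
        self.multiclass_accuracy_ = mc[0]
        self.multiclass_accuracy_sd_ = mc[1]

    def metrics_frame(self) -> pd.DataFrame:
        return self.report.summary_frame()

    def score_significance(self) -> dict:
        return self.report.score_significance()

    def summary(self) -> str:
        lines = []
        lines.append("Gland candidate classification (patient-wise nested CV)")
        lines.append("=" * 62)
        lines.append(f"classifier: {self.model.classifier}    "
                     f"outer folds: {self.model.k_outer}    "
                     f"inner folds: {self.model.k_inner}    seed: {self.seed}")
        n = len(self.model.table.labels)
        n_pat = len(np.unique(self.model.table.patient_ids))
        lines.append(f"candidates: {n}    patients: {n_pat}    "
                     f"features offered: {len(self.model.table.feature_names)}")
        lines.append("-" * 62)
        lines.append(f"multi-class accuracy: {self.multiclass_accuracy_:.3f} "
                     f"+/- {self.multiclass_accuracy_sd_:.3f}")
        for problem in ("artefact_vs_gland", "benign_vs_grade3"):
            df = self.report.metric_table(problem)
            lines.append("")
            lines.append(problem.replace("_", " "))
            header = "  ".join(f"{m:>11s}" for m in METRIC_NAMES)
            lines.append("  " + header)
            means = "  ".join(f"{df[m].mean():11.3f}" for m in METRIC_NAMES)
            sds = "  ".join(f"{df[m].std(ddof=1):11.3f}" for m in METRIC_NAMES)
            lines.append("  " + means + "   (mean)")
            lines.append("  " + sds + "   (sd)")
        lines.append("-" * 62)
        sig = self.score_significance()
        lines.append("score-significance p-values: "
                     + "  ".join(f"{c}={p:.2e}" for c, p in sig.items()))
        return "\n".join(lines)
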