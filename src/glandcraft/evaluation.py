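"""Figures of merit, ROC analysis, score-significance tests and overlays.

Per fold, two binary problems are scored: artefact vs gland over all rows
(positive = gland) and benign vs grade3 over the rows whose true class is a
gland (positive = grade3), plus the three-class accuracy.  AUC is the
trapezoidal area under the score-ranked ROC.  The score-significance
analysis treats each class's predicted probability as a variable and tests
its dependence on the true class (KS normality gate, then ANOVA or
Kruskal–Wallis), averaging p-values over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.metrics import roc_auc_score, roc_curve

from .classifiers import CLASS_ORDER
from .selection import class_dependence_test, normality_test

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f_score",
                "auc", "accuracy")


def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                   scores: np.ndarray | None = None) -> dict:
    """Confusion-matrix figures of merit for one binary problem.

    ``y_true``/``y_pred`` are 0/1 with 1 the positive class; ``scores`` are
    positive-class scores for the AUC.  Zero-denominator ratios are 0.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())

    def ratio(a, b):
        return a / b if b else 0.0

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f = ratio(2 * ppv * sens, ppv + sens)
    if scores is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    else:
        auc = 0.0
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
            "f_score": f, "auc": auc, "accuracy": ratio(tp + tn, len(y_true)),
            "confusion": (tn, fp, fn, tp)}


@dataclass
class FoldReport:
    """Metrics of one outer fold."""

    fold: int
    artefact_vs_gland: dict
    benign_vs_grade3: dict
    multiclass_accuracy: float
    roc_points: dict  # problem -> (fpr, tpr)
    scores: np.ndarray  # n x 3 class probabilities
    y_true: np.ndarray
    y_pred: np.ndarray
    n_test: int


@dataclass
class EvaluationReport:
    """Aggregated nested-CV evaluation."""

    folds: list
    classifier: str = ""

    def metric_table(self, problem: str) -> pd.DataFrame:
        rows = [getattr(f, problem) for f in self.folds]
        df = pd.DataFrame(rows)[list(METRIC_NAMES)]
        return df

    def summary_frame(self) -> pd.DataFrame:
        out = {}
        for problem in ("artefact_vs_gland", "benign_vs_grade3"):
            df = self.metric_table(problem)
            out[(problem, "mean")] = df.mean()
            out[(problem, "sd")] = df.std(ddof=1)
        return pd.DataFrame(out)

    @property
    def multiclass_accuracy(self) -> tuple[float, float]:
        accs = np.array([f.multiclass_accuracy for f in self.folds])
        return float(accs.mean()), float(accs.std(ddof=1)) if len(accs) > 1 else 0.0

    def score_significance(self) -> dict:
        """Fold-averaged score-significance p-value per class.

        Folds too small for the test (fewer than 10 rows) are skipped; if
        no fold qualifies the p-values default to 1.
        """
        per_class = {c: [] for c in CLASS_ORDER}
        for f in self.folds:
            if f.n_test < 10:
                continue
            ps = score_significance(f.scores, f.y_true)
            for c in CLASS_ORDER:
                per_class[c].append(ps[c])
        return {c: float(np.mean(v)) if v else 1.0
                for c, v in per_class.items()}

    def to_json_dict(self) -> dict:
        mc_mean, mc_sd = self.multiclass_accuracy
        payload = {"classifier": self.classifier,
                   "multiclass_accuracy": {"mean": mc_mean, "sd": mc_sd},
                   "problems": {}}
        for problem in ("artefact_vs_gland", "benign_vs_grade3"):
            df = self.metric_table(problem)
            payload["problems"][problem] = {
                "mean": df.mean().to_dict(), "sd": df.std(ddof=1).to_dict()}
        payload["score_significance"] = self.score_significance()
        return payload


def evaluate(bundle, X: np.ndarray, y: np.ndarray, fold: int = 0) -> FoldReport:
    """Evaluate a trained bundle on one held-out fold."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty test fold")
    proba = bundle.predict_proba(X)
    y_pred = bundle.predict(X)

    t_a = (y != "artefact").astype(int)
    p_a = (y_pred != "artefact").astype(int)
    s_a = proba[:, 1] + proba[:, 2]
    m_a = binary_metrics(t_a, p_a, s_a)

    gland_rows = y != "artefact"
    t_b = (y[gland_rows] == "grade3").astype(int)
    p_b = (y_pred[gland_rows] == "grade3").astype(int)
    denom = proba[gland_rows, 1] + proba[gland_rows, 2]
    denom = np.where(denom == 0, 1.0, denom)
    s_b = proba[gland_rows, 2] / denom
    m_b = binary_metrics(t_b, p_b, s_b)

    roc_points = {}
    for name, (t, s) in (("artefact_vs_gland", (t_a, s_a)),
                         ("benign_vs_grade3", (t_b, s_b))):
        if len(np.unique(t)) == 2:
            fpr, tpr, _ = roc_curve(t, s)
            roc_points[name] = (fpr, tpr)
    return FoldReport(fold=fold, artefact_vs_gland=m_a, benign_vs_grade3=m_b,
                      multiclass_accuracy=float(np.mean(y_pred == y)),
                      roc_points=roc_points, scores=proba, y_true=y,
                      y_pred=np.asarray(y_pred), n_test=len(y))


def score_significance(scores: np.ndarray, labels: np.ndarray,
                       alpha_ks: float = 0.05) -> dict:
    """p-value of each class's score column against the true classes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape[0] < 10:
        raise ValueError("need at least 10 rows for the score-significance test")
    if scores.min() < -1e-9 or scores.max() > 1 + 1e-9:
        raise ValueError("scores must lie in [0, 1]")
    out = {}
    for i, cls in enumerate(CLASS_ORDER):
        col = scores[:, i]
        sd = col.std(ddof=1)
        if sd == 0:
            out[cls] = 1.0
            continue
        z = (col - col.mean()) / sd
        _, is_normal = normality_test(z, alpha_ks)
        out[cls] = class_dependence_test(z, labels, is_normal)
    return out


_OVERLAY_COLOURS = {"benign": (0, 200, 0), "grade3": (220, 0, 0)}


def predict_overlay(rgb: np.ndarray, candidates, predictions) -> np.ndarray:
    """Draw predicted gland contours on a patch (green benign, red grade3).

    ``candidates`` provide bbox + bbox-local gland masks; artefact
    predictions are left undrawn.  Returns a new image of the same size.
    """
    out = np.asarray(rgb).copy()
    for cand, pred in zip(candidates, predictions):
        colour = _OVERLAY_COLOURS.get(str(pred))
        if colour is None:
            continue
        mask = cand.gland_mask.astype(bool)
        boundary = mask & ~ndi.binary_erosion(mask)
        boundary = ndi.binary_dilation(boundary)  # 2-px contour for visibility
        r0, c0, r1, c1 = cand.bbox
        region = out[r0:r1, c0:c1]
        region[boundary] = colour
    return out
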