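"""Statistical feature selection.

Pipeline: z-score normalisation per feature; a one-sample
Kolmogorov–Smirnov test against N(0,1) decides whether the class-dependence
test is a one-way ANOVA (normal) or a Kruskal–Wallis test (non-normal);
features whose class-test p-value exceeds the significance level alpha are
dropped; finally, among the survivors, any pair with Pearson |r| >= 0.95
and correlation-test p <= alpha loses its less class-discriminant member
(larger class-test p, ties broken towards the later schema position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 1e-6
DEFAULT_R_THRESH = 0.95
DEFAULT_ALPHA_KS = 0.05


@dataclass
class FeatureTable:
    """Candidates x features matrix with labels and patient ids."""

    X: np.ndarray
    feature_names: tuple
    labels: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.patient_ids = np.asarray(self.patient_ids)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValueError("matrix width must match feature_names")
        if len(self.labels) != self.X.shape[0] or len(self.patient_ids) != self.X.shape[0]:
            raise ValueError("labels/patient_ids must match the number of rows")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        meta = [c for c in ("candidate_id", "patient_id", "label") if c in df.columns]
        feats = [c for c in df.columns if c not in meta]
        return cls(X=df[feats].to_numpy(float), feature_names=tuple(feats),
                   labels=df["label"].to_numpy(), patient_ids=df["patient_id"].to_numpy())

    def subset_rows(self, idx) -> "FeatureTable":
        return FeatureTable(self.X[idx], self.feature_names,
                            self.labels[idx], self.patient_ids[idx])

    def subset_features(self, names) -> "FeatureTable":
        pos = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.X[:, pos], tuple(names), self.labels, self.patient_ids)


@dataclass
class SelectionResult:
    """Audit trail of the selection pipeline."""

    selected_names: tuple
    records: pd.DataFrame  # one row per feature: mu, sigma, ks_p, normal, test, class_p, dropped_by
    alpha: float
    r_thresh: float
    mu: np.ndarray = None
    sigma: np.ndarray = None

    def to_json_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "r_thresh": self.r_thresh,
            "selected": list(self.selected_names),
            "records": self.records.to_dict(orient="records"),
        }


def zscore_fit_transform(table: FeatureTable):
    """Column-wise z-scoring; returns (normalised table, mu, sigma, const_mask).

    Constant columns (sigma = 0) become all-zero and are flagged.
    """
    mu = table.X.mean(axis=0)
    sigma = table.X.std(axis=0, ddof=1)
    const = sigma == 0
    safe = np.where(const, 1.0, sigma)
    Z = (table.X - mu) / safe
    Z[:, const] = 0.0
    out = FeatureTable(Z, table.feature_names, table.labels, table.patient_ids)
    return out, mu, sigma, const


def zscore_apply(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Apply stored z-scoring parameters to held-out data."""
    safe = np.where(sigma == 0, 1.0, sigma)
    Z = (np.asarray(X, float) - mu) / safe
    Z[:, sigma == 0] = 0.0
    return Z


def normality_test(column: np.ndarray, alpha_ks: float = DEFAULT_ALPHA_KS):
    """One-sample KS test of a z-scored column against N(0,1)."""
    col = np.asarray(column, dtype=float)
    if col.size < 8:
        raise ValueError("need at least 8 observations for the KS normality test")
    p = stats.kstest(col, "norm").pvalue
    return float(p), bool(p > alpha_ks)


def class_dependence_test(column: np.ndarray, labels: np.ndarray,
                          is_normal: bool) -> float:
    """ANOVA (normal) or Kruskal–Wallis (non-normal) p-value across classes."""
    col = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    groups = [col[labels == c] for c in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 classes with >= 2 members each")
    if np.all(col == col[0]):
        return 1.0
    if is_normal:
        return float(stats.f_oneway(*groups).pvalue)
    return float(stats.kruskal(*groups).pvalue)


def _correlation_pvalues(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r matrix and two-sided p-values of all column pairs."""
    n = Z.shape[0]
    sd = Z.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    W = (Z - Z.mean(axis=0)) / safe
    r = (W.T @ W) / n
    r = np.clip(r, -1.0, 1.0)
    r[:, sd == 0] = 0.0
    r[sd == 0, :] = 0.0
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def select_features(table: FeatureTable, alpha: float = DEFAULT_ALPHA,
                    r_thresh: float = DEFAULT_R_THRESH,
                    alpha_ks: float = DEFAULT_ALPHA_KS) -> SelectionResult:
    """Run the full selection pipeline; deterministic in its inputs."""
    norm, mu, sigma, const = zscore_fit_transform(table)
    names = list(table.feature_names)
    n_feat = len(names)

    ks_p = np.empty(n_feat)
    is_norm = np.zeros(n_feat, dtype=bool)
    class_p = np.ones(n_feat)
    for j in range(n_feat):
        if const[j]:
            ks_p[j] = 0.0
            class_p[j] = 1.0
            continue
        ks_p[j], is_norm[j] = normality_test(norm.X[:, j], alpha_ks)
        class_p[j] = class_dependence_test(norm.X[:, j], table.labels, is_norm[j])

    dropped_by = np.array(["none"] * n_feat, dtype=object)
    keep = class_p <= alpha
    dropped_by[~keep] = "class_independence"

    survivors = [j for j in range(n_feat) if keep[j]]
    if survivors:
        r, p = _correlation_pvalues(norm.X[:, survivors])
        alive = list(survivors)
        while True:
            offending = []
            for a in range(len(alive)):
                for b in range(a + 1, len(alive)):
                    ia = survivors.index(alive[a])
                    ib = survivors.index(alive[b])
                    if abs(r[ia, ib]) >= r_thresh and p[ia, ib] <= alpha:
                        offending.append((alive[a], alive[b]))
            if not offending:
                break
            ja, jb = offending[0]
            # drop the less class-discriminant member; tie -> later schema order
            if class_p[ja] > class_p[jb] or (class_p[ja] == class_p[jb] and ja > jb):
                loser, partner = ja, jb
            else:
                loser, partner = jb, ja
            dropped_by[loser] = f"correlation({names[partner]})"
            alive.remove(loser)
        selected = [names[j] for j in alive]
    else:
        selected = []

    if not selected:
        raise ValueError(
            "no features survive selection; consider relaxing alpha "
            f"(currently {alpha:g})")

    records = pd.DataFrame({
        "feature": names,
        "mu": mu,
        "sigma": sigma,
        "ks_p": ks_p,
        "normal": is_norm,
        "class_test": np.where(is_norm, "anova", "kruskal"),
        "class_p": class_p,
        "dropped_by": dropped_by,
    })
    return SelectionResult(selected_names=tuple(selected), records=records,
                           alpha=alpha, r_thresh=r_thresh, mu=mu, sigma=sigma)
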