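"""Classifiers: the two-stage quadratic-kernel SVM cascade and the MLP.

The three-class problem (artefact / benign / grade3) is split into a
cascade of two binary problems: stage A separates artefacts from glands and
stage B separates benign from grade-3 glands among the non-artefact rows.
Each stage is a degree-2 polynomial-kernel SVM whose box constraint C and
kernel scale gamma are tuned in [1e-2, 1e2] by minimising inner-CV error,
either with a Gaussian-process Bayesian optimiser (expected-improvement
acquisition, default) or a log-spaced grid.  Scores are calibrated to
probabilities with Platt scaling.

The MLP is a single-hidden-layer network (15 logistic units, 3 softmax
outputs) trained by full-batch gradient descent with momentum 0.9 and a
classic adaptive learning-rate rule: the rate grows by 1.5x after an
improving epoch and shrinks by 0.5x (with the update rejected) when the
loss ratio exceeds 1.04; training stops after 20 non-improving validation
epochs or 1000 epochs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.svm import SVC

log = logging.getLogger(__name__)

CLASS_ORDER = ("artefact", "benign", "grade3")
DEFAULT_RANGE = (1e-2, 1e2)


@dataclass
class ModelBundle:
    """A trained cascade (or MLP) with its preprocessing parameters."""

    kind: str  # svm_quadratic | mlp
    stage_a: object = None  # artefact vs gland
    stage_b: object = None  # benign vs grade3
    mlp: object = None
    selection: object = None
    mu: np.ndarray = None
    sigma: np.ndarray = None
    feature_names: tuple = ()
    hyperparams: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities ordered (artefact, benign, grade3)."""
        X = np.asarray(X, dtype=float)
        if self.kind == "mlp":
            return self.mlp.predict_proba(X)
        p_gland = _binary_proba(self.stage_a, X)
        p_grade3 = _binary_proba(self.stage_b, X)
        out = np.empty((X.shape[0], 3))
        out[:, 0] = 1.0 - p_gland
        out[:, 1] = p_gland * (1.0 - p_grade3)
        out[:, 2] = p_gland * p_grade3
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Cascade routing: stage A gates artefact vs gland (tie -> gland),
        stage B labels the predicted glands."""
        X = np.asarray(X, dtype=float)
        if self.kind == "mlp":
            proba = self.mlp.predict_proba(X)
            return np.array(CLASS_ORDER)[np.argmax(proba, axis=1)]
        p_gland = _binary_proba(self.stage_a, X)
        p_grade3 = _binary_proba(self.stage_b, X)
        labels = np.where(p_gland < 0.5, "artefact",
                          np.where(p_grade3 >= 0.5, "grade3", "benign"))
        return labels.astype(object)


def _binary_proba(clf, X: np.ndarray) -> np.ndarray:
    """P(positive class) of a fitted binary classifier."""
    proba = clf.predict_proba(X)
    return proba[:, list(clf.classes_).index(1)]


def _inner_splits(y: np.ndarray, groups: np.ndarray, k: int, seed: int):
    """Patient-wise inner folds when enough patients exist, else stratified."""
    n_groups = len(np.unique(groups))
    if n_groups >= k:
        cv = GroupKFold(n_splits=k)
        return list(cv.split(np.zeros(len(y)), y, groups))
    k_eff = min(k, np.bincount(y).min())
    if k_eff < 2:
        raise ValueError("not enough samples per class for inner CV")
    cv = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def _fit_calibrated(X, y, C, gamma, seed):
    """Quadratic-kernel SVM with Platt-calibrated probabilities."""
    svc = SVC(kernel="poly", degree=2, coef0=1.0, C=C, gamma=gamma,
              random_state=seed)
    cv = min(5, int(np.bincount(y).min()))
    clf = CalibratedClassifierCV(svc, method="sigmoid", cv=cv, ensemble=False)
    clf.fit(X, y)
    return clf


def _cv_error(X, y, splits, C, gamma, seed) -> float:
    errs = []
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2:
            continue
        clf = SVC(kernel="poly", degree=2, coef0=1.0, C=C, gamma=gamma,
                  random_state=seed)
        clf.fit(X[tr], y[tr])
        errs.append(np.mean(clf.predict(X[te]) != y[te]))
    return float(np.mean(errs)) if errs else 1.0


def _expected_improvement(mu, sd, best):
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return (best - mu) * stats.norm.cdf(z) + sd * stats.norm.pdf(z)


def bayes_minimise(objective, bounds, budget: int, seed: int) -> tuple[np.ndarray, float]:
    """Minimise a 2-D objective with a GP surrogate and EI acquisition.

    ``bounds`` is a (2, 2) array of [low, high] per dimension (already in
    the search scale).  Deterministic for a fixed seed and budget.
    """
    if budget < 5:
        raise ValueError("optimisation budget must be at least 5")
    rng = np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    dim = bounds.shape[0]
    n_init = min(max(dim * 3, 6), budget)
    Xs = rng.uniform(bounds[:, 0], bounds[:, 1], size=(n_init, dim))
    ys = np.array([objective(x) for x in Xs])
    kernel = ConstantKernel(1.0) * Matern(length_scale=np.ones(dim), nu=2.5)
    while len(ys) < budget:
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6,
                                      normalize_y=True, random_state=seed)
        with warnings.catch_warnings():
            # a flat objective drives the length scale to its bound; harmless
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(Xs, ys)
        cand = rng.uniform(bounds[:, 0], bounds[:, 1], size=(256, dim))
        mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, ys.min())
        x_next = cand[int(np.argmax(ei))]
        Xs = np.vstack([Xs, x_next])
        ys = np.append(ys, objective(x_next))
    best = int(np.argmin(ys))
    return Xs[best], float(ys[best])


def _tune_stage(X, y, groups, k_inner, c_range, gamma_range, budget, seed,
                method) -> tuple[float, float]:
    splits = _inner_splits(y, groups, k_inner, seed)
    lb = np.log10([c_range[0], gamma_range[0]])
    ub = np.log10([c_range[1], gamma_range[1]])

    def objective(logx):
        return _cv_error(X, y, splits, 10 ** logx[0], 10 ** logx[1], seed)

    if method == "grid":
        side = max(int(np.sqrt(budget)), 2)
        cs = np.linspace(lb[0], ub[0], side)
        gs = np.linspace(lb[1], ub[1], side)
        best, best_err = None, np.inf
        for c in cs:
            for g in gs:
                err = objective(np.array([c, g]))
                if err < best_err:
                    best, best_err = (c, g), err
        logc, logg = best
    else:
        x, _ = bayes_minimise(objective, np.stack([lb, ub], axis=1), budget, seed)
        logc, logg = x
    return float(10 ** logc), float(10 ** logg)


def train_svm_cascade(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                      k_inner: int = 10,
                      c_range=DEFAULT_RANGE, gamma_range=DEFAULT_RANGE,
                      budget: int = 30, seed: int = 0,
                      method: str = "bayes") -> ModelBundle:
    """Train the tuned two-stage quadratic SVM cascade.

    ``y`` holds string class labels; ``groups`` the patient ids used for
    the patient-wise inner folds.
    """
    if budget < 5:
        raise ValueError("budget must be >= 5")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)

    y_a = (y != "artefact").astype(int)
    if len(np.unique(y_a)) < 2:
        raise ValueError("stage A needs both artefacts and glands in training data")
    gland_rows = y != "artefact"
    y_b = (y[gland_rows] == "grade3").astype(int)
    if len(np.unique(y_b)) < 2:
        raise ValueError("stage B needs both benign and grade3 rows in training data")

    ca, ga = _tune_stage(X, y_a, groups, k_inner, c_range, gamma_range,
                         budget, seed, method)
    stage_a = _fit_calibrated(X, y_a, ca, ga, seed)

    Xb, gb_groups = X[gland_rows], groups[gland_rows]
    cb, gb = _tune_stage(Xb, y_b, gb_groups, k_inner, c_range, gamma_range,
                         budget, seed + 1, method)
    stage_b = _fit_calibrated(Xb, y_b, cb, gb, seed)

    return ModelBundle(kind="svm_quadratic", stage_a=stage_a, stage_b=stage_b,
                       hyperparams={"stage_a": {"C": ca, "gamma": ga},
                                    "stage_b": {"C": cb, "gamma": gb}},
                       metadata={"seed": seed, "budget": budget, "method": method})


class MLPNet:
    """Single-hidden-layer softmax network with adaptive learning rate."""

    def __init__(self, n_hidden: int = 15, eta0: float = 1e-3,
                 momentum: float = 0.9, mu_up: float = 1.5, mu_down: float = 0.5,
                 max_ratio: float = 1.04, max_epochs: int = 1000,
                 patience: int = 20, seed: int = 0):
        self.n_hidden = n_hidden
        self.eta0 = eta0
        self.momentum = momentum
        self.mu_up = mu_up
        self.mu_down = mu_down
        self.max_ratio = max_ratio
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.loss_history_: list = []

    @staticmethod
    def _softmax(z):
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _forward(self, X, params):
        W1, b1, W2, b2 = params
        hidden = 1.0 / (1.0 + np.exp(-(X @ W1 + b1)))
        proba = self._softmax(hidden @ W2 + b2)
        return hidden, proba

    @staticmethod
    def _loss(proba, Y):
        eps = 1e-12
        return float(-np.mean(np.sum(Y * np.log(proba + eps), axis=1)))

    def fit(self, X: np.ndarray, y: np.ndarray, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.array(CLASS_ORDER)
        class_idx = {c: i for i, c in enumerate(CLASS_ORDER)}
        Y = np.zeros((len(y), 3))
        for i, lab in enumerate(y):
            Y[i, class_idx[lab]] = 1.0
        use_val = X_val is not None and len(X_val) > 0
        if use_val:
            Y_val = np.zeros((len(y_val), 3))
            for i, lab in enumerate(np.asarray(y_val)):
                Y_val[i, class_idx[lab]] = 1.0

        rng = np.random.default_rng(self.seed)
        n_in = X.shape[1]
        params = [rng.normal(0, 0.1, (n_in, self.n_hidden)),
                  np.zeros(self.n_hidden),
                  rng.normal(0, 0.1, (self.n_hidden, 3)),
                  np.zeros(3)]
        velocity = [np.zeros_like(p) for p in params]
        eta = self.eta0
        _, proba = self._forward(X, params)
        loss = self._loss(proba, Y)
        best_val = np.inf
        best_params = [p.copy() for p in params]
        stall = 0
        self.loss_history_ = [loss]
        for _ in range(self.max_epochs):
            hidden, proba = self._forward(X, params)
            delta2 = (proba - Y) / len(X)
            gW2 = hidden.T @ delta2
            gb2 = delta2.sum(axis=0)
            dh = delta2 @ params[2].T * hidden * (1.0 - hidden)
            gW1 = X.T @ dh
            gb1 = dh.sum(axis=0)
            grads = [gW1, gb1, gW2, gb2]
            new_velocity = [self.momentum * v - eta * g
                            for v, g in zip(velocity, grads)]
            trial = [p + v for p, v in zip(params, new_velocity)]
            _, proba_t = self._forward(X, trial)
            new_loss = self._loss(proba_t, Y)
            if not np.isfinite(new_loss):
                log.error("MLP loss diverged; keeping last good parameters")
                params = best_params
                raise FloatingPointError("MLP training diverged (non-finite loss)")
            if new_loss > loss * self.max_ratio:
                # reject the update, damp the learning rate
                eta *= self.mu_down
                velocity = [np.zeros_like(p) for p in params]
            else:
                if new_loss < loss:
                    eta *= self.mu_up
                params = trial
                velocity = new_velocity
                loss = new_loss
            self.loss_history_.append(loss)

            if use_val:
                _, pv = self._forward(X_val, params)
                monitor = self._loss(pv, Y_val)
            else:
                monitor = loss
            if monitor < best_val - 1e-9:
                best_val = monitor
                best_params = [p.copy() for p in params]
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.params_ = best_params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        _, proba = self._forward(np.asarray(X, dtype=float), self.params_)
        return proba

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_mlp(X: np.ndarray, y: np.ndarray, val_fraction: float = 0.1,
              seed: int = 0, **mlp_kwargs) -> ModelBundle:
    """Train the MLP on a held-in split, monitoring a validation fraction."""
    y = np.asarray(y)
    if len(np.unique(y)) < 3:
        raise ValueError("MLP training expects all three classes present")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    n_val = max(int(round(val_fraction * n)), 1) if val_fraction > 0 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    net = MLPNet(seed=seed, **mlp_kwargs)
    net.fit(X[tr_idx], y[tr_idx],
            X[val_idx] if n_val else None, y[val_idx] if n_val else None)
    return ModelBundle(kind="mlp", mlp=net,
                       metadata={"seed": seed, "val_fraction": val_fraction})
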