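"""SMOTE-balanced multivariate logistic regression with leak-free outer CV.

Each outer stratified fold (default 10) re-runs the full feature-selection
procedure on its training portion only, balances the training classes with
SMOTE, standardizes, and fits a ridge-stabilized logistic model over the
selected connectivity/topology features plus age.  Models are scored by ROC
AUC on the fold's training and held-out portions, and the per-fold model
collection can be transported to the opposite-hemisphere cohort to test
whether the learned remodeling signature is hemisphere-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .feature_selection import (
    FeatureTable,
    SelectionConfig,
    pick_predictive,
    repeated_selection,
)

AGE_FEATURE = "age"


@dataclass
class MLRModel:
    """Standardized logistic model: feature ids, coefficients, scaler."""

    feature_ids: list[str]
    coefficients: np.ndarray  # per feature, on the standardized scale
    intercept: float
    standardization: tuple[np.ndarray, np.ndarray]  # (mean, sd) per feature

    def __post_init__(self) -> None:
        mean, sd = self.standardization
        k = len(self.feature_ids)
        if len(self.coefficients) != k or len(mean) != k or len(sd) != k:
            raise ValueError("coefficient/standardization length mismatch")
        if np.any(sd <= 0):
            raise ValueError("standardization SDs must be positive")

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        mean, sd = self.standardization
        z = (np.asarray(X, dtype=float) - mean) / sd
        return z @ self.coefficients + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_scores(X)))


@dataclass
class EvaluationResult:
    aucs: np.ndarray
    mean: float
    sd: float
    roc_points: list
    context: str

    @classmethod
    def from_aucs(cls, aucs: Sequence[float], roc_points: list, context: str) -> "EvaluationResult":
        a = np.asarray(aucs, dtype=float)
        if np.any((a < 0) | (a > 1)):
            raise ValueError("AUC values must lie in [0, 1]")
        sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
        return cls(aucs=a, mean=float(a.mean()), sd=sd, roc_points=roc_points, context=context)


class CVEvaluation(NamedTuple):
    train: EvaluationResult
    validation: EvaluationResult
    models: list[MLRModel]
    selected_features: list[list[str]]


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority interpolation (SMOTE).

    New minority points are x_i + u * (x_nn - x_i) with u ~ U(0, 1) and x_nn
    one of the k nearest minority neighbors; originals are kept unchanged
    and returned first.  k is reduced to minority size - 1 when necessary.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE expects exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min = int(counts.min())
    if n_min < 2:
        raise ValueError("minority class of 1 cannot be oversampled")
    n_new = int(counts.max() - counts.min())
    k = min(k_neighbors, n_min - 1)
    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random(size=n_new)
    x_base = X_min[base]
    x_nn = X_min[neigh[base, pick]]
    X_new = x_base + u[:, None] * (x_nn - x_base)
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, minority, dtype=np.int64)]),
    )


def fit_mlr(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    ridge: float = 1e-4,
    max_iter: int = 10_000,
) -> MLRModel:
    """Maximum-likelihood logistic fit with a small ridge penalty.

    Features are z-scored internally on the training data and the scaler is
    frozen in the model so it transports to new cohorts.  The penalty
    0.5 * ridge * ||w||^2 (intercept unpenalized) keeps coefficients finite
    on separable SMOTE-balanced data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.size != 2 or class_counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [feature_ids[i] for i in dead]
        raise ValueError(f"zero-variance features cannot be standardized: {names}")
    Z = (X - mean) / sd
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=1e-10)
    clf.fit(Z, y)
    if clf.n_iter_[0] >= max_iter:
        p = 1.0 / (1.0 + np.exp(-(Z @ clf.coef_[0] + clf.intercept_[0])))
        grad = Z.T @ (p - y) + ridge * clf.coef_[0]
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3e})"
        )
    return MLRModel(
        feature_ids=list(feature_ids),
        coefficients=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        standardization=(mean, sd),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[list, float]:
    """ROC points (FPR, TPR) by threshold sweep and the tie-corrected AUC."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(roc_auc_score(labels, scores))


def _model_matrix(table: FeatureTable, feature_ids: list[str], idx: np.ndarray) -> np.ndarray:
    col_of = {fid: k for k, fid in enumerate(table.feature_ids)}
    cols = []
    for fid in feature_ids:
        if fid == AGE_FEATURE:
            if table.age is None:
                raise ValueError("model requires age but the table carries none")
            cols.append(table.age[idx])
        elif fid in col_of:
            cols.append(table.X[idx, col_of[fid]])
        else:
            raise ValueError(f"feature {fid!r} missing from the table")
    return np.column_stack(cols)


def outer_cv_evaluate(
    table: FeatureTable,
    selection_cfg: SelectionConfig,
    cv_folds: int = 10,
    seed: int = 0,
    ridge: float = 1e-4,
    smote_k: int = 5,
    include_age: bool = True,
) -> CVEvaluation:
    """Stratified outer CV: selection, SMOTE and fitting inside each fold.

    Per fold: training portion -> repeated_selection -> pick_predictive ->
    SMOTE (training portion only) -> logistic fit on predictive features
    (+ age) -> AUC on the training portion and on the held-out portion.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    y = table.labels
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31 - 1))
    train_aucs, val_aucs = [], []
    train_rocs, val_rocs = [], []
    models: list[MLRModel] = []
    selected_sets: list[list[str]] = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(table.X, y)):
        fold_seed = (seed * 7919 + fold) % (2**31 - 1)
        cfg = replace(selection_cfg, seed=fold_seed)
        freq = repeated_selection(table.subset(tr_idx), cfg)
        feats = pick_predictive(freq, cfg.top_pct)
        if include_age:
            feats = feats + [AGE_FEATURE]
        if not feats:
            raise ValueError(f"fold {fold}: no features selected")
        X_tr = _model_matrix(table, feats, tr_idx)
        X_bal, y_bal = smote_oversample(X_tr, y[tr_idx], k_neighbors=smote_k, seed=fold_seed)
        model = fit_mlr(X_bal, y_bal, feats, ridge=ridge)
        models.append(model)
        selected_sets.append(feats)
        roc_tr, auc_tr = roc_auc(model.decision_scores(X_tr), y[tr_idx])
        X_va = _model_matrix(table, feats, va_idx)
        roc_va, auc_va = roc_auc(model.decision_scores(X_va), y[va_idx])
        train_aucs.append(auc_tr)
        val_aucs.append(auc_va)
        train_rocs.append(roc_tr)
        val_rocs.append(roc_va)
    return CVEvaluation(
        train=EvaluationResult.from_aucs(train_aucs, train_rocs, "train"),
        validation=EvaluationResult.from_aucs(val_aucs, val_rocs, "validation"),
        models=models,
        selected_features=selected_sets,
    )


def cross_hemisphere_validate(models: Sequence[MLRModel], other: FeatureTable) -> EvaluationResult:
    """Score every fold model on the entire opposite-hemisphere table."""
    aucs, rocs = [], []
    idx = np.arange(other.n_subjects)
    for model in models:
        X = _model_matrix(other, model.feature_ids, idx)
        roc, auc = roc_auc(model.decision_scores(X), other.labels)
        aucs.append(auc)
        rocs.append(roc)
    return EvaluationResult.from_aucs(aucs, rocs, "other_hemisphere")


def compare_auc_distributions(
    a: np.ndarray, b: np.ndarray, paired: bool = False
) -> tuple[float, float]:
    """Two-tailed Student t comparison of two AUC samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per sample")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal lengths")
        if np.all(a == b):
            return 0.0, 1.0
        res = stats.ttest_rel(a, b)
    else:
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            return 0.0, 1.0
        res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
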