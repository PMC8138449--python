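"""Logistic predictor models, backward feature selection and 10-fold
cross-validated diagnostic performance.

Each feature can serve as a univariate logistic predictor of AF; the
multivariate model starts from all ten features and removes the least
significant one (largest Wald p above the significance level, default
0.157) until every remaining feature is significant.  The intercept is
never a candidate for removal.  Performance is estimated by seeded
(stratified by default) k-fold cross-validation: per-fold AUC, sensitivity,
specificity, PPV, NPV and accuracy at the probability cutoff (default 0.5
for a balanced cohort) are averaged across folds, and the averaged ROC
curve is obtained by vertical averaging of per-fold TPR on a fixed
101-point FPR grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

log = logging.getLogger(__name__)

METRIC_NAMES = ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy")
FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class PredictorModel:
    """A fitted logistic model p(AF) = expit(b0 + Σ b_i x_i)."""

    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    cutoff: float = 0.5
    stderr: np.ndarray | None = None        # [intercept, features...]
    p_values: np.ndarray | None = None      # same layout
    converged: bool = True
    selection_trace: list = field(default_factory=list)  # (name, p) removals

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("one coefficient per feature required")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def summary(self) -> pd.DataFrame:
        """Estimate / SE / OR / two-sided Wald p, intercept first."""
        est = np.concatenate([[self.intercept], self.coefficients])
        rows = ["(Intercept)"] + list(self.feature_names)
        return pd.DataFrame(
            {
                "Estimate": est,
                "SE": self.stderr if self.stderr is not None else np.full(est.size, np.nan),
                "OR": np.exp(est),
                "p": self.p_values if self.p_values is not None else np.full(est.size, np.nan),
            },
            index=rows,
        )


@dataclass
class CvReport:
    """Cross-validation outcome: per-fold and averaged metrics, averaged
    ROC (vertical averaging on a fixed FPR grid) and the fold map."""

    per_fold: list
    averaged: dict
    roc: tuple  # (fpr_grid, mean_tpr)
    fold_assignment: np.ndarray
    seed: int

    def metric_table(self) -> pd.DataFrame:
        """Per-fold rows plus Mean/Min/Max summary rows."""
        df = pd.DataFrame(self.per_fold)
        df.insert(0, "fold", np.arange(1, len(self.per_fold) + 1))
        valid = df.dropna(subset=list(METRIC_NAMES))
        summary = pd.DataFrame(
            {
                "fold": ["Mean", "Min", "Max"],
                **{m: [valid[m].mean(), valid[m].min(), valid[m].max()]
                   for m in METRIC_NAMES},
            }
        )
        return pd.concat([df, summary], ignore_index=True)


def _design(features, feature_names=None):
    if isinstance(features, pd.DataFrame):
        names = list(feature_names) if feature_names is not None else list(features.columns)
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise ValueError(f"missing features: {missing}")
        X = features[names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = (list(feature_names) if feature_names is not None
                 else [f"x{i}" for i in range(X.shape[1])])
    return X, names


def fit_logistic(features, labels, feature_names=None, cutoff: float = 0.5,
                 max_iter: int = 100, tol: float = 1e-8) -> PredictorModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares (Newton–Raphson).

    Converges when the largest coefficient change falls below ``tol`` or
    after ``max_iter`` iterations; under perfect separation the iteration
    cap bounds the coefficients and the model is flagged (``converged``
    False) with a warning.  Rows must be complete (no NaN) and both classes
    present."""
    X, names = _design(features, feature_names)
    y = np.asarray(labels, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("NaN in design or labels: drop undefined rows first")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(A.shape[1])
    converged = False
    H = np.eye(A.shape[1])
    for _ in range(max_iter):
        p = expit(A @ beta)
        w = np.maximum(p * (1.0 - p), 1e-10)
        H = (A * w[:, None]).T @ A
        g = A.T @ (y - p)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("IRLS did not converge (possible perfect separation); "
                      "coefficients bounded by the iteration cap", stacklevel=2)
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * norm.sf(np.abs(z))
    return PredictorModel(
        intercept=float(beta[0]), coefficients=beta[1:], feature_names=names,
        cutoff=cutoff, stderr=se, p_values=pvals, converged=converged,
    )


def predict(model: PredictorModel, features):
    """Probabilities and hard calls (AF iff p >= cutoff) for a feature
    table covering ``model.feature_names``."""
    X, _ = _design(features, model.feature_names)
    p = expit(model.intercept + X @ model.coefficients)
    return p, (p >= model.cutoff).astype(int)


def backward_select(features, labels, alpha: float = 0.157,
                    cutoff: float = 0.5) -> PredictorModel:
    """Backward elimination of features by two-sided Wald p.

    Starting from the full model, the feature with the largest p exceeding
    ``alpha`` is removed (ties broken toward the lexically larger name) and
    the model refitted, until every remaining feature satisfies p <= alpha.
    The intercept is exempt from elimination.  Removing everything yields a
    flagged intercept-only model."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    X, names = _design(features, None)
    df = pd.DataFrame(X, columns=names)
    trace = []
    current = list(names)
    model = None
    while current:
        model = fit_logistic(df[current], labels, cutoff=cutoff)
        feat_p = model.p_values[1:]  # skip intercept
        feat_p = np.where(np.isnan(feat_p), 1.0, feat_p)
        order = sorted(range(len(current)),
                       key=lambda i: (feat_p[i], current[i]))
        worst = order[-1]
        if feat_p[worst] <= alpha:
            break
        trace.append((current[worst], float(feat_p[worst])))
        log.info("backward selection: removed %s (p=%.4f)",
                 current[worst], feat_p[worst])
        current.pop(worst)
        model = None
    if model is None:  # everything removed: intercept-only model
        y = np.asarray(labels, dtype=float)
        p1 = np.clip(y.mean(), 1e-10, 1 - 1e-10)
        model = PredictorModel(float(np.log(p1 / (1 - p1))), np.empty(0), [],
                               cutoff=cutoff, converged=False)
        warnings.warn("backward selection removed every feature; "
                      "returning intercept-only model", stacklevel=2)
    model.selection_trace = trace
    return model


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Sensitivity, specificity, PPV, NPV and accuracy (all x100);
    0/0 ratios are NaN and all-zero counts are invalid."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("all counts zero")

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": ratio(tp + tn, total),
    }


def roc_auc(probabilities, labels) -> dict:
    """ROC by threshold sweep and trapezoid AUC (equals the Mann–Whitney
    statistic with ties counted 1/2).  Requires both classes."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined for a single class")
    fpr, tpr, _ = roc_curve(y, p, drop_intermediate=False)
    return {"auc": float(_trapezoid_auc(fpr, tpr)), "fpr": fpr, "tpr": tpr}


def kfold_cv(features, labels, k: int = 10, seed: int = 0,
             feature_names=None, select_alpha: float | None = None,
             stratified: bool = True, cutoff: float = 0.5) -> CvReport:
    """Seeded k-fold cross-validation of a logistic predictor.

    ``feature_names`` restricts the model to the named columns (a single
    name gives a univariate model); ``select_alpha`` instead runs backward
    selection on each training split.  Folds lacking a class are excluded
    from the averages with a warning."""
    X, names = _design(features, feature_names)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < k:
        raise ValueError("need at least k samples")
    df = pd.DataFrame(X, columns=names)
    splitter = (StratifiedKFold(k, shuffle=True, random_state=seed) if stratified
                else KFold(k, shuffle=True, random_state=seed))
    fold_assignment = np.full(n, -1, dtype=int)
    per_fold, tprs = [], []
    for fi, (tr, va) in enumerate(splitter.split(X, y)):
        fold_assignment[va] = fi
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            log.warning("fold %d lacks a class: excluded from averages", fi)
            per_fold.append({m: float("nan") for m in METRIC_NAMES})
            continue
        if select_alpha is not None:
            model = backward_select(df.iloc[tr], y[tr], alpha=select_alpha,
                                    cutoff=cutoff)
        else:
            model = fit_logistic(df.iloc[tr], y[tr], cutoff=cutoff)
        if model.feature_names:
            p, pred = predict(model, df.iloc[va])
        else:  # degenerate intercept-only model
            p = np.full(len(va), expit(model.intercept))
            pred = (p >= cutoff).astype(int)
        yv = y[va]
        tp = int(np.sum((pred == 1) & (yv == 1)))
        fp = int(np.sum((pred == 1) & (yv == 0)))
        tn = int(np.sum((pred == 0) & (yv == 0)))
        fn = int(np.sum((pred == 0) & (yv == 1)))
        metrics = confusion_metrics(tp, fp, tn, fn)
        roc = roc_auc(p, yv)
        metrics["auc"] = roc["auc"]
        tprs.append(np.interp(FPR_GRID, roc["fpr"], roc["tpr"]))
        per_fold.append(metrics)
    valid = [f for f in per_fold if not np.isnan(f["auc"])]
    averaged = {m: float(np.mean([f[m] for f in valid])) if valid else float("nan")
                for m in METRIC_NAMES}
    mean_tpr = np.mean(tprs, axis=0) if tprs else np.full(FPR_GRID.size, np.nan)
    return CvReport(per_fold=per_fold, averaged=averaged,
                    roc=(FPR_GRID.copy(), mean_tpr),
                    fold_assignment=fold_assignment, seed=seed)
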