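"""Chronic-GVHD classifier: constrained logistic regression, Shapley
feature ranking, and repeated stratified cross-validation.

The model is multivariate logistic regression whose slope coefficients are
constrained to be nonnegative, encoding the biological prior that every
marker (cfDNA concentrations, liver enzymes) can only rise with disease
activity; the intercept is free. The likelihood is maximized under box
constraints with a weak L2 ridge that guarantees a unique optimum even under
complete separation. Because the log-odds are linear in the features,
interventional Shapley attributions have a closed form,
``phi_ij = beta_j * (x_ij - mean_background_j)``; an exhaustive coalition
enumeration is provided as a verification oracle. Features are ranked by
mean absolute attribution and nested feature sets are compared by repeated
stratified 5-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .synthetic import FEATURES_17

DEFAULT_RIDGE = 1e-4
DEFAULT_THRESHOLD = 0.5


# -- feature matrix ----------------------------------------------------------

def build_feature_matrix(
    cohort: pd.DataFrame,
    features: Sequence[str] = FEATURES_17,
    label_from: str = "group",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Model matrix and binary label from a cohort table.

    Keeps transplanted samples only (healthy controls are not part of the
    classification task), labels chronic GVHD as 1, and applies listwise
    deletion so only complete cases enter modeling.
    """
    hct = cohort[cohort[label_from].isin(["hct_no_gvhd", "hct_cgvhd"])]
    complete = hct.dropna(subset=list(features))
    X = complete[list(features)].astype(float)
    y = (complete[label_from] == "hct_cgvhd").to_numpy(dtype=int)
    X.index = complete["sample_id"] if "sample_id" in complete else complete.index
    return X, y


def zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and SDs for standardization (constant columns get SD 1)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


# -- constrained logistic regression -----------------------------------------

@dataclass
class ConstrainedLRFit:
    """A fitted (optionally sign-constrained) logistic regression."""

    feature_names: list[str]
    intercept: float
    coef: np.ndarray
    converged: bool
    log_likelihood: float
    nonneg: bool
    separation_flag: bool = False

    def decision_function(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coef

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        z = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(-z))


def fit_constrained_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    nonneg: bool = True,
    ridge: float = DEFAULT_RIDGE,
) -> ConstrainedLRFit:
    """Maximum-likelihood logistic regression with optional ``beta >= 0``.

    The convex negative log-likelihood plus a weak ridge (``ridge/2 ·
    ||beta||²``, intercept excluded) is minimized with L-BFGS-B; under the
    nonnegativity constraint, coefficients at the active bound are exactly
    zero. The ridge keeps the optimum finite under complete separation,
    which is reported via ``separation_flag``. Deterministic for fixed input.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least two samples per class")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        b0, beta = theta[0], theta[1:]
        z = b0 + X @ beta
        # log(1 + exp(-(2y-1) z)) computed stably
        s = 2 * y - 1
        nll = np.logaddexp(0.0, -s * z).sum()
        prob = 1.0 / (1.0 + np.exp(-z))
        resid = prob - y
        grad = np.empty(p + 1)
        grad[0] = resid.sum()
        grad[1:] = X.T @ resid + ridge * beta
        return nll + 0.5 * ridge * beta @ beta, grad

    bounds = [(None, None)] + ([(0.0, None)] * p if nonneg else [(None, None)] * p)
    res = minimize(
        objective,
        x0=np.zeros(p + 1),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
    )
    b0, beta = res.x[0], res.x[1:]
    if nonneg:
        beta = np.maximum(beta, 0.0)  # clamp numerical -0.0 / tiny violations
    z = b0 + X @ beta
    loglik = -(np.logaddexp(0.0, -(2 * y - 1) * z)).sum()
    # perfect in-sample classification with runaway coefficients (held finite
    # only by the ridge) indicates complete separation
    separated = bool(
        np.all((z > 0) == (y == 1)) and (np.abs(beta).max() if p else 0) > 20
    )
    return ConstrainedLRFit(
        feature_names=list(feature_names),
        intercept=float(b0),
        coef=beta,
        converged=bool(res.success),
        log_likelihood=float(loglik),
        nonneg=nonneg,
        separation_flag=separated,
    )


# -- Shapley attribution -----------------------------------------------------

@dataclass
class ShapleyReport:
    """Per-sample log-odds attributions and the derived feature ranking."""

    values: pd.DataFrame  # samples x features, log-odds scale
    mean_abs: pd.Series  # mean |phi| per feature, descending order not implied
    background_mean: pd.Series
    base_log_odds: float  # log-odds at the background mean


def shapley_values(
    fit: ConstrainedLRFit,
    X: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
) -> ShapleyReport:
    """Interventional Shapley attributions for the linear log-odds model.

    With an independent background summarized by its mean, the attribution
    of feature *j* for sample *i* is ``beta_j * (x_ij - mean_background_j)``,
    and per-sample attributions sum to the sample's log-odds minus the mean
    background log-odds (efficiency).
    """
    names = fit.feature_names
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Bv = (
        background.to_numpy(dtype=float)
        if isinstance(background, pd.DataFrame)
        else np.asarray(background, float)
    )
    if Bv.size == 0:
        raise ValueError("background set is empty")
    bg_mean = Bv.mean(axis=0)
    phi = fit.coef[None, :] * (Xv - bg_mean[None, :])
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xv))
    values = pd.DataFrame(phi, columns=names, index=index)
    return ShapleyReport(
        values=values,
        mean_abs=values.abs().mean(axis=0),
        background_mean=pd.Series(bg_mean, index=names),
        base_log_odds=float(fit.intercept + bg_mean @ fit.coef),
    )


def shapley_exact(
    fit: ConstrainedLRFit, x: np.ndarray, background_mean: np.ndarray
) -> np.ndarray:
    """Exhaustive-coalition Shapley values on the log-odds scale.

    Verification oracle for :func:`shapley_values` (feasible for <= ~12
    features). The value of a coalition S is the model log-odds with
    features in S taken from ``x`` and the rest from ``background_mean``.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(background_mean, dtype=float)
    p = len(x)
    if p > 16:
        raise ValueError("exhaustive enumeration is limited to 16 features")

    def value(subset: tuple[int, ...]) -> float:
        z = np.array(m, copy=True)
        z[list(subset)] = x[list(subset)]
        return fit.intercept + z @ fit.coef

    phi = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [i for i in others if i != j]
        for size in range(p):
            w = 1.0 / (p * comb(p - 1, size))
            for subset in combinations(rest, size):
                phi[j] += w * (value(subset + (j,)) - value(subset))
    return phi


def rank_features(report: ShapleyReport) -> tuple[list[str], bool]:
    """Features by descending mean |phi|; exact ties break lexicographically.

    Returns ``(ordered_features, tie_flag)``.
    """
    items = sorted(report.mean_abs.items(), key=lambda kv: (-kv[1], kv[0]))
    values = [v for _, v in items]
    ties = len(set(values)) < len(values)
    return [name for name, _ in items], ties


# -- metrics -----------------------------------------------------------------

def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Standard confusion-matrix metrics; undefined ratios are NaN.

    sensitivity (= recall) = TP/(TP+FN); specificity = TN/(TN+FP);
    PPV (= precision) = TP/(TP+FP); NPV = TN/(TN+FN);
    accuracy = (TP+TN)/N.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    metrics = {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }
    metrics["recall"] = metrics["sensitivity"]
    metrics["precision"] = metrics["ppv"]
    return metrics


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> ROCResult:
    """ROC curve over all thresholds and the trapezoidal AUC.

    The AUC equals the probability that a random positive outscores a random
    negative, ties counted one half.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = _roc_curve(y_true, scores)
    return ROCResult(fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr)))


# -- repeated stratified k-fold CV -------------------------------------------

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "precision", "recall", "auc")


@dataclass
class CVReport:
    """Per-fold metrics and their aggregate for one feature set."""

    feature_set: list[str]
    folds: pd.DataFrame  # one row per (repeat, fold) with all metrics
    summary: pd.DataFrame  # index metric, columns mean/sd
    oof: pd.DataFrame  # out-of-fold predictions: repeat, index, y, score
    refolded: bool = False

    def pooled_roc(self) -> ROCResult:
        """ROC over all out-of-fold predictions pooled across repeats."""
        return roc_auc(self.oof["y"].to_numpy(), self.oof["score"].to_numpy())


def repeated_kfold(
    X: pd.DataFrame,
    y: np.ndarray,
    feature_set: Sequence[str] | None = None,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    nonneg: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
    ridge: float = DEFAULT_RIDGE,
) -> CVReport:
    """Repeated stratified K-fold cross-validation of the constrained model.

    Within each training fold the features are z-scored with that fold's
    statistics only; the scaler is then applied to the held-out fold, the
    model is fitted on the training fold, and class-1 probabilities on the
    test fold give threshold metrics (at ``threshold``) and a fold AUC.
    Metrics are aggregated as mean and SD across all folds x repeats. A fold
    whose training half lacks a class triggers a refold with a shifted seed
    (flagged in the report).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(X) < k:
        raise ValueError("need at least k samples")
    features = list(feature_set) if feature_set is not None else list(X.columns)
    Xf = X[features].to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)

    rows = []
    oof_rows = []
    refolded = False
    for rep in range(repeats):
        fold_seed = seed * 100_003 + rep
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(fold_seed + attempt) % 2**31)
            splits = list(skf.split(Xf, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
                if attempt > 0:
                    refolded = True
                break
        else:
            raise ValueError("could not build folds with both classes in training")
        for fold_i, (tr, te) in enumerate(splits):
            mean, sd = zscore_fit(Xf[tr])
            Xtr = (Xf[tr] - mean) / sd
            Xte = (Xf[te] - mean) / sd
            fit = fit_constrained_logistic(Xtr, y[tr], features, nonneg=nonneg, ridge=ridge)
            score = fit.predict_proba(Xte)
            pred = (score >= threshold).astype(int)
            m = confusion_metrics(y[te], pred)
            m["auc"] = (
                roc_auc(y[te], score).auc if len(np.unique(y[te])) == 2 else float("nan")
            )
            m.update({"repeat": rep, "fold": fold_i})
            rows.append(m)
            for idx, yi, si in zip(te, y[te], score):
                oof_rows.append({"repeat": rep, "index": idx, "y": yi, "score": si})

    folds = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "mean": folds[list(METRIC_NAMES)].mean(),
            "sd": folds[list(METRIC_NAMES)].std(ddof=1),
        }
    )
    return CVReport(features, folds, summary, pd.DataFrame(oof_rows), refolded)


# -- Shapley-ranked feature sweep --------------------------------------------

@dataclass
class SweepReport:
    """Nested feature-set comparison along a Shapley ranking."""

    ranking: list[str]
    reports: dict[int, CVReport]
    table: pd.DataFrame  # one row per set size with mean/sd of each metric
    best_size: int

    @property
    def best_features(self) -> list[str]:
        return self.ranking[: self.best_size]


def rank_by_shapley(
    X: pd.DataFrame,
    y: np.ndarray,
    nonneg: bool = True,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[list[str], ShapleyReport, ConstrainedLRFit]:
    """Fit on the full (standardized) data and rank features by mean |phi|."""
    Xv = X.to_numpy(dtype=float)
    mean, sd = zscore_fit(Xv)
    Xs = pd.DataFrame((Xv - mean) / sd, columns=X.columns, index=X.index)
    fit = fit_constrained_logistic(Xs, y, list(X.columns), nonneg=nonneg, ridge=ridge)
    report = shapley_values(fit, Xs, Xs)
    ranking, _ = rank_features(report)
    return ranking, report, fit


def feature_sweep(
    X: pd.DataFrame,
    y: np.ndarray,
    ranking: Sequence[str],
    sizes: Sequence[int] | None = None,
    k: int = 5,
    repeats: int = 20,
    seed: int = 0,
    nonneg: bool = True,
    ridge: float = DEFAULT_RIDGE,
) -> SweepReport:
    """Cross-validate nested feature sets (top-1, top-2, ...) of a ranking.

    The best set maximizes mean AUC; exact ties go to the smaller set.
    Default sizes are 1..7 (capped at the number of ranked features).
    """
    ranking = list(ranking)
    if sizes is None:
        sizes = range(1, min(7, len(ranking)) + 1)
    reports: dict[int, CVReport] = {}
    rows = []
    for size in sizes:
        rep = repeated_kfold(
            X, y, ranking[:size], k=k, repeats=repeats, seed=seed, nonneg=nonneg, ridge=ridge
        )
        reports[size] = rep
        row = {"size": size}
        for metric in METRIC_NAMES:
            row[f"{metric}_mean"] = rep.summary.loc[metric, "mean"]
            row[f"{metric}_sd"] = rep.summary.loc[metric, "sd"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("size")
    best_size = int(table["auc_mean"].round(12).idxmax())  # idxmax takes first on ties
    return SweepReport(ranking, reports, table, best_size)
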