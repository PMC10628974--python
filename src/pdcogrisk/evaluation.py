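"""Evaluation of risk scores against cognitive-trajectory labels.

Covers the full published analysis surface: confusion metrics and
likelihood ratios at a fixed cutoff, ROC curves with the Mann–Whitney AUC
(ties counted 1/2) and DeLong confidence intervals, the DeLong
correlated-curves chi-square test for comparing several scores on the same
participants, and OLS linear models of CCS change on score totals or
per-factor indicators.

The DeLong computations follow the standard structural-components
formulation: for positive score X_i and negative score Y_j define
V10(X_i) = mean_j ψ(X_i, Y_j) and V01(Y_j) = mean_i ψ(X_i, Y_j) with
ψ = 1, 1/2, 0 for X>Y, X=Y, X<Y; the AUC is the mean of either set and its
variance estimate is S10/m + S01/n from the empirical covariances of the
components. Midranks give an O(N log N) implementation.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "decline"


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# confusion metrics and likelihood ratios

@dataclass
class ClassificationMetrics:
    """Confusion counts and the derived proportions at one score cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)
    lr_positive: float = field(init=False)
    lr_negative: float = field(init=False)

    def __post_init__(self):
        n_pos = self.tp + self.fn
        n_neg = self.tn + self.fp
        if n_pos == 0 or n_neg == 0:
            raise EvaluationError("both classes must be present to compute metrics")
        self.sensitivity = self.tp / n_pos
        self.specificity = self.tn / n_neg
        self.accuracy = (self.tp + self.tn) / (n_pos + n_neg)
        self.lr_positive, self.lr_negative = likelihood_ratios(
            self.sensitivity, self.specificity)


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """Positive and negative likelihood ratios.

    LR+ = sens/(1−spec) — infinite at perfect specificity;
    LR− = (1−sens)/spec — undefined (NaN) at zero specificity.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise EvaluationError("sensitivity and specificity must lie in [0, 1]")
    if specificity == 1.0:
        lr_pos = np.inf if sensitivity > 0 else np.nan
    else:
        lr_pos = sensitivity / (1.0 - specificity)
    if specificity == 0.0:
        lr_neg = np.nan
    else:
        lr_neg = (1.0 - sensitivity) / specificity
    return lr_pos, lr_neg


def _binarize(labels: Sequence, positive_label=POSITIVE_LABEL) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu" or arr.dtype.kind == "f":
        return arr.astype(bool)
    return arr == positive_label


def confusion_at_cutoff(scores: Sequence[float], labels: Sequence,
                        cutoff: float,
                        positive_label=POSITIVE_LABEL) -> ClassificationMetrics:
    """Classify score >= cutoff as predicted-positive and tabulate."""
    scores = np.asarray(scores, dtype=float)
    y = _binarize(labels, positive_label)
    if len(scores) != len(y):
        raise EvaluationError("scores and labels must be aligned")
    pred = scores >= cutoff
    return ClassificationMetrics(
        tp=int(np.sum(pred & y)), fp=int(np.sum(pred & ~y)),
        tn=int(np.sum(~pred & ~y)), fn=int(np.sum(~pred & y)),
    )


# ---------------------------------------------------------------------------
# DeLong machinery

def _delong_components(score_matrix: np.ndarray, y: np.ndarray):
    """AUCs and structural components for k score vectors on shared labels.

    Returns (aucs (k,), v10 (k, m), v01 (k, n)) with m positives, n negatives.
    """
    pos = score_matrix[:, y]
    neg = score_matrix[:, ~y]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise EvaluationError("both classes must be present")
    k = score_matrix.shape[0]
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for r in range(k):
        tx = stats.rankdata(pos[r])           # midranks within positives
        ty = stats.rankdata(neg[r])           # midranks within negatives
        tz = stats.rankdata(np.concatenate([pos[r], neg[r]]))  # joint midranks
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
        aucs[r] = tz[:m].sum() / (m * n) - (m + 1.0) / (2.0 * n)
    return aucs, v10, v01


def delong_auc_variance(scores: Sequence[float], labels: Sequence,
                        positive_label=POSITIVE_LABEL) -> tuple[float, float]:
    """Mann–Whitney AUC and its DeLong variance estimate."""
    y = _binarize(labels, positive_label)
    aucs, v10, v01 = _delong_components(
        np.asarray(scores, dtype=float)[None, :], y)
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.var(v10[0], ddof=1) if m > 1 else 0.0
    s01 = np.var(v01[0], ddof=1) if n > 1 else 0.0
    return float(aucs[0]), float(s10 / m + s01 / n)


def delong_covariance(score_sets: Sequence[Sequence[float]], labels: Sequence,
                      positive_label=POSITIVE_LABEL) -> tuple[np.ndarray, np.ndarray]:
    """AUC vector and DeLong covariance matrix for k correlated curves."""
    matrix = np.asarray(score_sets, dtype=float)
    if matrix.ndim != 2:
        raise EvaluationError("score_sets must be a k x N matrix")
    y = _binarize(labels, positive_label)
    if matrix.shape[1] != len(y):
        raise EvaluationError("score vectors and labels must be aligned")
    aucs, v10, v01 = _delong_components(matrix, y)
    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((len(aucs),) * 2)
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((len(aucs),) * 2)
    s10 = np.atleast_2d(s10)
    s01 = np.atleast_2d(s01)
    return aucs, s10 / m + s01 / n


# ---------------------------------------------------------------------------
# ROC

@dataclass
class RocResult:
    """ROC point set with AUC and its 95% confidence interval."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    degenerate: bool = False  # constant scores: AUC 0.5 with no spread
    ci_method: str = "delong"


def roc_auc(scores: Sequence[float], labels: Sequence,
            positive_label=POSITIVE_LABEL,
            ci_method: str = "delong",
            n_boot: int = 2000,
            seed: Optional[int] = None) -> RocResult:
    """ROC curve and Mann–Whitney AUC with a 95% CI.

    Higher scores must indicate higher decline risk. ``ci_method`` is
    ``"delong"`` (analytic) or ``"bootstrap"`` (stratified resampling of
    participants, ``n_boot`` replicates, percentile interval).
    """
    scores = np.asarray(scores, dtype=float)
    y = _binarize(labels, positive_label)
    auc, var = delong_auc_variance(scores, y)
    degenerate = np.ptp(scores) == 0
    fpr, tpr, thresholds = _sk_roc_curve(y.astype(int), scores)
    if ci_method == "delong":
        half = 1.959963984540054 * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y)
        neg_idx = np.flatnonzero(~y)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            ip = rng.choice(pos_idx, len(pos_idx), replace=True)
            im = rng.choice(neg_idx, len(neg_idx), replace=True)
            idx = np.concatenate([ip, im])
            boot[b], _ = delong_auc_variance(scores[idx], y[idx])
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     ci95=ci, n_pos=int(y.sum()), n_neg=int((~y).sum()),
                     degenerate=bool(degenerate), ci_method=ci_method)


def compare_aucs(score_sets: Sequence[Sequence[float]], labels: Sequence,
                 positive_label=POSITIVE_LABEL) -> tuple[float, int, float]:
    """DeLong chi-square test that k correlated AUCs are equal.

    All score vectors must be computed on the same participants. Returns
    ``(chi2, df, p)`` with df = k − 1; the statistic is the quadratic form
    of the AUC differences against their DeLong covariance.
    """
    try:
        matrix = np.asarray(score_sets, dtype=float)
    except ValueError as exc:
        raise EvaluationError("score vectors must have equal length") from exc
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise EvaluationError("need at least two aligned score vectors")
    aucs, cov = delong_covariance(matrix, labels, positive_label)
    k = len(aucs)
    contrast = np.hstack([-np.ones((k - 1, 1)), np.eye(k - 1)])  # diffs vs curve 0
    diffs = contrast @ aucs
    sigma = contrast @ cov @ contrast.T
    if np.allclose(diffs, 0.0):
        return 0.0, k - 1, 1.0
    chi2 = float(diffs @ np.linalg.pinv(sigma, hermitian=True) @ diffs)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, k - 1, p


# ---------------------------------------------------------------------------
# linear models of CCS change

@dataclass
class PredictorStats:
    coefficient: float
    ci95: tuple[float, float]
    p_value: float


@dataclass
class RegressionResult:
    """OLS summary: per-predictor coefficients with 95% CIs and p-values."""

    predictors: dict[str, PredictorStats]
    intercept: PredictorStats
    r_squared: float
    n: int
    dropped: list[str] = field(default_factory=list)


def fit_ccs_model(outcome: Sequence[float], predictors,
                  names: Optional[Sequence[str]] = None) -> RegressionResult:
    """OLS of CCS change on score totals or per-factor indicators.

    ``predictors`` is a 1-D vector (single total score), a 2-D array, or a
    DataFrame whose columns name the factors. Constant and collinear
    columns are dropped with a warning; an intercept is always included.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if isinstance(predictors, pd.DataFrame):
        X = predictors.copy()
    else:
        arr = np.asarray(predictors, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        X = pd.DataFrame(arr)
        X.columns = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    if len(X) != len(y):
        raise EvaluationError("outcome and predictors must be aligned")
    if len(y) <= X.shape[1] + 1:
        raise EvaluationError("need n > number of predictors + 1")

    dropped = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) == 0]
    for c in dropped:
        logger.warning("dropping constant predictor column %r", c)
    X = X.drop(columns=dropped)
    # greedy removal of collinear columns so the design has full rank
    kept: list[str] = []
    for c in X.columns:
        trial = X[kept + [c]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), trial])) == len(kept) + 2:
            kept.append(c)
        else:
            logger.warning("dropping collinear predictor column %r", c)
            dropped.append(c)
    X = X[kept]
    if X.shape[1] == 0:
        raise EvaluationError("no usable predictor columns remain")

    design = sm.add_constant(X.astype(float), has_constant="add")
    fit = sm.OLS(y, design).fit()
    conf = fit.conf_int(alpha=0.05)

    def _stats(name) -> PredictorStats:
        return PredictorStats(
            coefficient=float(fit.params[name]),
            ci95=(float(conf.loc[name, 0]), float(conf.loc[name, 1])),
            p_value=float(fit.pvalues[name]),
        )

    return RegressionResult(
        predictors={c: _stats(c) for c in X.columns},
        intercept=_stats("const"),
        r_squared=float(fit.rsquared),
        n=len(y),
        dropped=dropped,
    )
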