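"""qRT-PCR relative quantification and ROC biomarker evaluation.

Relative expression uses the 2^-ddCt method: technical replicates are
averaged, dCt = Ct_target - Ct_reference per sample, ddCt subtracts the
calibrator-group mean dCt (healthy controls by default), and relative
expression is 2^-ddCt. ROC analysis treats the AUC as the Mann-Whitney
probability that a random case outscores a random control, counting ties
half; the combined two-marker score is the linear predictor of an
internally fitted (IRLS) binomial logistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .clinical import pearson_with_p


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_case: int
    n_control: int
    flipped: bool = False  # scores were negated so AUC >= 0.5
    separation: bool = False  # combined fit fell back due to separation
    coef: np.ndarray | None = field(default=None, repr=False)


def ddct_relative_expression(
    cts: pd.DataFrame,
    target: str,
    reference_gene: str,
    group_labels: dict[str, str],
    calibrator_group: str = "control",
) -> pd.Series:
    """Per-sample 2^-ddCt relative expression of ``target``.

    ``cts`` columns: sample, gene, replicate, ct. Replicates are averaged
    arithmetically; ddCt is taken against the mean dCt of the calibrator
    group, so the calibrator group averages to relative expression ~1.
    """
    mean_ct = cts.groupby(["sample", "gene"])["ct"].mean().unstack()
    for g in (target, reference_gene):
        if g not in mean_ct.columns:
            raise ValueError(f"gene {g!r} missing from Ct table")
    dct = mean_ct[target] - mean_ct[reference_gene]
    calib = [s for s in dct.index if group_labels.get(s) == calibrator_group]
    if not calib:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    ddct = dct - dct.loc[calib].mean()
    rel = np.power(2.0, -ddct)
    rel.name = target
    return rel


def _mann_whitney_auc(scores: np.ndarray, is_case: np.ndarray) -> float:
    # U / (n1*n0) with midranks (ties counted half)
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    n1 = int(is_case.sum())
    n0 = len(scores) - n1
    u = ranks[is_case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and tie-aware AUC for case-vs-control scores.

    The AUC is the Mann-Whitney U statistic (ties counted half) divided by
    n_case * n_control. Orientation is automatic: when cases score lower,
    scores are negated so the reported AUC >= 0.5 and ``flipped`` records
    the reversal.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == "case" else 0 for l in labels])
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    auc = _mann_whitney_auc(scores, y.astype(bool))
    flipped = auc < 0.5
    if flipped:
        scores = -scores
        auc = 1.0 - auc
    fpr, tpr, thr = roc_curve(y, scores)
    return RocResult(auc, thr, tpr, fpr, n1, n0, flipped=flipped)


def _irls_logistic(
    x: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, bool]:
    """Unpenalized binomial logistic fit by iteratively reweighted least
    squares. Returns (coefficients incl. intercept, separated flag)."""
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.zeros(X.shape[1])
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if w.max() < 1e-10 or np.abs(beta).max() > 1e6:
            separated = True
            break
        wX = X * w[:, None]
        try:
            delta = np.linalg.solve(X.T @ wX, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + delta
        if np.abs(delta).max() < tol:
            break
    else:
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
    # perfect separation: fitted probabilities pile at 0/1 while the
    # likelihood keeps improving with ||beta|| -> inf
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    if not separated:
        resid = np.abs(y - mu)
        separated = bool(resid.max() < 1e-6) and np.abs(beta).max() > 50
    return beta, separated


def combined_roc(marker_a, marker_b, labels) -> RocResult:
    """ROC of the two-marker logistic score.

    Markers are standardized, a binomial logistic model (intercept + two
    features) is fitted by IRLS, and the linear predictor serves as the
    combined score. Under perfect separation the model is not identified;
    the fall-back ranks by the better single marker and flags it.
    """
    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("markers must cover the same samples")
    y = np.asarray([1 if l == "case" else 0 for l in labels], dtype=float)

    feats = [v for v in (a, b) if v.std() > 0]
    if not feats:
        return roc_auc(np.zeros_like(a), labels)
    X = np.column_stack([(v - v.mean()) / v.std() for v in feats])
    beta, separated = _irls_logistic(X, y)
    if separated:
        warnings.warn("perfect separation; falling back to best single marker",
                      stacklevel=2)
        best = max((roc_auc(a, labels), roc_auc(b, labels)), key=lambda r: r.auc)
        best.separation = True
        return best
    score = X @ beta[1:] + beta[0]
    res = roc_auc(score, labels)
    res.coef = beta
    return res


def marker_clinical_correlation(
    rel_expr: pd.Series, clinical_variable: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of marker expression with a clinical variable
    over the samples present in both (patients only, typically)."""
    common = rel_expr.index.intersection(clinical_variable.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples")
    return pearson_with_p(
        rel_expr.loc[common].to_numpy(), clinical_variable.loc[common].to_numpy()
    )


__all__ = [
    "RocResult",
    "combined_roc",
    "ddct_relative_expression",
    "marker_clinical_correlation",
    "roc_auc",
]
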