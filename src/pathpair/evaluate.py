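"""Threshold-free classifier evaluation: rank AUC, DeLong intervals, CV.

AUC is the Mann-Whitney probability that a random case outscores a random
control, with half credit for ties.  Its 95% confidence interval uses
DeLong's structural-components estimator (deterministic, no resampling).
Thresholded metrics (recall/precision/F1) use the Youden-optimal threshold
estimated on the training scores of each fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = ["ROCResult", "CVReport", "auc", "youden_threshold", "cross_validate"]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Per-observation placement values of the DeLong decomposition."""
    all_scores = np.concatenate([pos, neg])
    mid_all = stats.rankdata(all_scores, method="average")
    mid_pos = stats.rankdata(pos, method="average")
    mid_neg = stats.rankdata(neg, method="average")
    m, n = len(pos), len(neg)
    v10 = (mid_all[:m] - mid_pos) / n          # placement of each case
    v01 = 1.0 - (mid_all[m:] - mid_neg) / m    # placement of each control
    return v10, v01


def auc(scores, labels, positive=1) -> ROCResult:
    """Rank AUC of ``scores`` against binary ``labels`` with a DeLong 95% CI.

    ``labels`` may be any binary labelling; ``positive`` names the case
    class.  Both classes must be present.
    """
    s = np.asarray(pd.Series(scores), dtype=float)
    y = np.asarray(pd.Series(labels) == positive)
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute AUC")
    v10, v01 = _delong_components(pos, neg)
    a = float(v10.mean())
    var = 0.0
    if len(pos) > 1:
        var += v10.var(ddof=1) / len(pos)
    if len(neg) > 1:
        var += v01.var(ddof=1) / len(neg)
    half = 1.959963984540054 * np.sqrt(var)
    return ROCResult(
        auc=a,
        ci_low=float(max(0.0, a - half)),
        ci_high=float(min(1.0, a + half)),
        n_pos=len(pos),
        n_neg=len(neg),
    )


def youden_threshold(scores, labels, positive=1) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on the given data."""
    s = np.asarray(pd.Series(scores), dtype=float)
    y = np.asarray(pd.Series(labels) == positive)
    candidates = np.unique(s)
    best_t, best_j = candidates[0], -np.inf
    n_pos, n_neg = y.sum(), (~y).sum()
    for t in candidates:
        pred = s >= t
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        j = sens + spec - 1
        if j > best_j:
            best_t, best_j = t, j
    return float(best_t)


class _QuietL1LogisticCV(LogisticRegressionCV):
    """Cross-validated L1 logistic regression, FutureWarning-free fit."""

    def fit(self, X, y, **kwargs):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            return super().fit(X, y, **kwargs)


def _default_classifier():
    return _QuietL1LogisticCV(
        Cs=10, cv=5, penalty="l1", solver="liblinear",
        scoring="neg_log_loss", max_iter=2000, random_state=0,
    )


@dataclass
class CVReport:
    """Stratified k-fold cross-validation results."""

    per_fold: pd.DataFrame
    aggregate: dict
    fold_assignments: pd.DataFrame
    seed: int
    threshold_metrics: dict = field(default_factory=dict)


def cross_validate(
    mpp,
    groups: pd.Series,
    classifier_factory=None,
    k: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    representation: str = "continuous",
    positive: str = "AD",
) -> CVReport:
    """Stratified k-fold CV of a classifier on pair signatures.

    ``classifier_factory`` returns a fresh sklearn-style estimator (fit /
    predict_proba or decision_function); the default is cross-validated
    L1-penalized logistic regression.  Scores are pooled per repeat; AUC is
    computed on the pooled held-out scores, and thresholded metrics use the
    Youden threshold fit on each fold's training scores.
    """
    factory = classifier_factory or _default_classifier
    values = mpp.values_for(representation) if hasattr(mpp, "values_for") else mpp
    # canonical sample order makes folds invariant to input column order
    values = values[sorted(values.columns)]
    groups = pd.Series(groups).loc[values.columns]
    y = (groups == positive).to_numpy(dtype=int)
    if min(np.bincount(y)) < k:
        raise ValueError(
            f"k={k} exceeds the minority class size {min(np.bincount(y))}"
        )
    X = values.to_numpy(dtype=float).T
    sample_ids = np.asarray(values.columns)

    rows = []
    assignments = []
    for rep in range(n_repeats):
        rep_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(rep,)).generate_state(1)[0]
            % (2**31)
        )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        pooled_scores = np.empty(len(y))
        pooled_pred = np.empty(len(y), dtype=bool)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            clf = factory()
            clf.fit(X[tr], y[tr])
            if hasattr(clf, "predict_proba"):
                s_tr = clf.predict_proba(X[tr])[:, 1]
                s_te = clf.predict_proba(X[te])[:, 1]
            else:
                s_tr = clf.decision_function(X[tr])
                s_te = clf.decision_function(X[te])
            thr = youden_threshold(s_tr, y[tr])
            pooled_scores[te] = s_te
            pooled_pred[te] = s_te >= thr
            fold_auc = auc(s_te, y[te]).auc if len(np.unique(y[te])) == 2 else np.nan
            rows.append({"repeat": rep, "fold": fold, "auc": fold_auc, "threshold": thr})
            assignments.extend(
                {"repeat": rep, "fold": fold, "sample": s} for s in sample_ids[te]
            )
        tp = (pooled_pred & (y == 1)).sum()
        fp = (pooled_pred & (y == 0)).sum()
        fn = (~pooled_pred & (y == 1)).sum()
        recall = tp / max(tp + fn, 1)
        precision = tp / max(tp + fp, 1)
        f1 = 2 * precision * recall / max(precision + recall, 1e-12)
        rows.append(
            {
                "repeat": rep,
                "fold": -1,  # pooled row
                "auc": auc(pooled_scores, y).auc,
                "recall": recall,
                "precision": precision,
                "f1": f1,
            }
        )

    per_fold = pd.DataFrame(rows)
    pooled = per_fold[per_fold["fold"] == -1]
    aggregate = {
        "auc": float(pooled["auc"].mean()),
        "recall": float(pooled["recall"].mean()),
        "precision": float(pooled["precision"].mean()),
        "f1": float(pooled["f1"].mean()),
    }
    return CVReport(
        per_fold=per_fold,
        aggregate=aggregate,
        fold_assignments=pd.DataFrame(assignments),
        seed=seed,
    )
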