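"""The pathway-pairwise scoring system: a linear risk score over pair signatures.

A model is a sparse list of (pair id, coefficient) entries plus an optional
intercept:

    risk_k = intercept + sum_i coef_i * value_i(sample k)

where value_i is either the continuous activity difference or the ±1
ordering indicator of pair i, per the model's ``representation`` flag.
Published formulations carry no intercept; training here fits one but keeps
it a separate field so the intercept-free printed form stays reproducible
(rank metrics such as AUC are intercept-invariant anyway).

Training mirrors the repeated-selection recipe: stratified 70/30 split,
then many bootstrap resamples of the training split, each fit with
L1-penalized logistic regression whose penalty strength is chosen by
internal cross-validation at minimum CV deviance; pairs whose coefficient
is nonzero in at least ``freq_threshold`` of the resamples form the final
feature set, and one last cross-validated L1 fit on the full training split
restricted to that set yields the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

__all__ = ["MPPSSModel", "TrainConfig", "TrainingReport", "risk_score", "train_mppss"]


@dataclass
class MPPSSModel:
    """Sparse linear scorer over pair signatures."""

    entries: list[tuple[str, float]]
    intercept: float = 0.0
    representation: str = "continuous"
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pair ids in model entries")
        if not all(np.isfinite(c) for _, c in self.entries):
            raise ValueError("model coefficients must be finite")
        if self.representation not in ("continuous", "discrete"):
            raise ValueError(f"unknown representation {self.representation!r}")

    @property
    def pair_ids(self) -> list[str]:
        return [p for p, _ in self.entries]


def _resolve_pair_values(values: pd.DataFrame, pair_id: str, discrete: bool) -> np.ndarray:
    """Look up one pair's row, accepting the reversed orientation with
    negation (for the discrete representation the negation maps +1/-1 onto
    -1/+1; exact ties cannot be distinguished from the reversed row)."""
    if pair_id in values.index:
        return values.loc[pair_id].to_numpy(dtype=float)
    a, b = pair_id.split("-", 1) if "-" in pair_id else (pair_id, "")
    reversed_id = f"{b}-{a}"
    if reversed_id in values.index:
        return -values.loc[reversed_id].to_numpy(dtype=float)
    raise KeyError(pair_id)


def risk_score(model: MPPSSModel, mpp) -> pd.Series:
    """Score every sample of an MPP matrix (or a pairs x samples DataFrame
    on the model's own representation scale) with the model.

    Pair ids are orientation-normalized: a model pair stored as "B-A" while
    the matrix holds "A-B" resolves to the negated row.
    """
    if hasattr(mpp, "values_for"):
        values = mpp.values_for(model.representation)
    else:
        values = mpp
    scores = np.full(values.shape[1], float(model.intercept))
    missing = []
    for pair_id, coef in model.entries:
        try:
            scores = scores + coef * _resolve_pair_values(
                values, pair_id, model.representation == "discrete"
            )
        except KeyError:
            missing.append(pair_id)
    if missing:
        raise KeyError(f"model pairs not resolvable in the MPP matrix: {missing}")
    return pd.Series(scores, index=values.columns, name="risk_score")


@dataclass
class TrainConfig:
    """Knobs of the repeated-selection training loop."""

    train_frac: float = 0.7
    n_iter: int = 1000
    cv_folds: int = 10
    freq_threshold: float = 0.8
    Cs: int = 10
    representation: str = "continuous"
    positive: str = "AD"
    max_redraws: int = 10


@dataclass
class TrainingReport:
    """Everything the training loop observed, plus the final model."""

    frequencies: pd.Series
    selected: list[str]
    model: MPPSSModel
    train_samples: list[str]
    test_samples: list[str]
    metrics: dict = field(default_factory=dict)
    seed: int = 0


def _cv_l1_logistic(X: np.ndarray, y: np.ndarray, cfg: TrainConfig, seed: int):
    folds = min(cfg.cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=cfg.Cs,
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=2000,
        random_state=0,
    )
    import warnings

    with warnings.catch_warnings():
        # sklearn >=1.8 warns about the penalty= spelling; the l1 path is intended
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(X, y)
    return clf


def train_mppss(mpp, groups: pd.Series, config: TrainConfig | None = None, seed: int = 0) -> TrainingReport:
    """Fit the scoring system on an MPP matrix with two-group labels.

    Deterministic under (config, seed).  A bootstrap draw that loses a class
    is redrawn (logged), up to ``max_redraws`` times.
    """
    cfg = config or TrainConfig()
    values = mpp.values_for(cfg.representation)
    groups = pd.Series(groups).loc[values.columns]
    labels = groups.unique().tolist()
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    y_all = (groups == cfg.positive).to_numpy(dtype=int)
    if min(np.bincount(y_all)) < 10:
        raise ValueError("need at least 10 samples per group to train")
    X_all = values.to_numpy(dtype=float).T
    sample_ids = np.asarray(values.columns)

    idx_train, idx_test = train_test_split(
        np.arange(len(sample_ids)),
        train_size=cfg.train_frac,
        stratify=y_all,
        random_state=seed,
    )
    X_tr, y_tr = X_all[idx_train], y_all[idx_train]

    rng = np.random.default_rng(seed)
    counts = np.zeros(values.shape[0])
    n_tr = len(idx_train)
    for it in range(cfg.n_iter):
        for attempt in range(cfg.max_redraws + 1):
            boot = rng.integers(0, n_tr, size=n_tr)
            if len(np.unique(y_tr[boot])) == 2:
                break
            logger.info("iteration %d: bootstrap draw lost a class, redrawing", it)
        else:
            raise RuntimeError("could not draw a two-class bootstrap sample")
        clf = _cv_l1_logistic(X_tr[boot], y_tr[boot], cfg, seed=int(rng.integers(2**31)))
        counts += np.abs(clf.coef_[0]) > 1e-8

    freqs = pd.Series(counts / max(cfg.n_iter, 1), index=values.index, name="selection_frequency")
    selected = freqs.index[freqs >= cfg.freq_threshold].tolist()
    logger.info("%d/%d pairs selected at frequency >= %g", len(selected), len(freqs), cfg.freq_threshold)

    if selected:
        sel_idx = [values.index.get_loc(p) for p in selected]
        final = _cv_l1_logistic(X_tr[:, sel_idx], y_tr, cfg, seed=seed)
        entries = [
            (p, float(c)) for p, c in zip(selected, final.coef_[0]) if abs(c) > 1e-8
        ]
        intercept = float(final.intercept_[0])
    else:
        # nothing survived selection: a null model scoring every sample 0
        entries, intercept = [], 0.0
    model = MPPSSModel(
        entries=entries,
        intercept=intercept,
        representation=cfg.representation,
        provenance=f"train_mppss(seed={seed}, n_iter={cfg.n_iter})",
    )

    from .evaluate import auc  # local import to avoid a cycle

    metrics: dict = {}
    if entries:
        scores = risk_score(model, values)
        metrics["train_auc"] = auc(scores.iloc[idx_train], y_all[idx_train]).auc
        metrics["test_auc"] = auc(scores.iloc[idx_test], y_all[idx_test]).auc
    return TrainingReport(
        frequencies=freqs,
        selected=selected,
        model=model,
        train_samples=sample_ids[idx_train].tolist(),
        test_samples=sample_ids[idx_test].tolist(),
        metrics=metrics,
        seed=seed,
    )
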