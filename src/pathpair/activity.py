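"""Single-sample gene-set enrichment (ssGSEA) pathway activity.

For one sample, genes are ordered by decreasing expression (ties broken by
stable input order) and a running sum walks down that list, stepping up by
the weighted in-set empirical distribution and down by the out-of-set ECDF:

    score = sum_p [ P_in(p) - P_out(p) ]
    P_in(p)  = sum_{g in set, pos(g) <= p} rho_g^alpha / sum_{g in set} rho_g^alpha
    P_out(p) = #{g not in set, pos(g) <= p} / #{g not in set}

with rank weight rho_g = N + 1 - pos(g).  The statistic depends only on the
within-sample ranks, so it is invariant under any strictly increasing
per-sample transformation — which is what makes the downstream pairwise
ordering signatures robust to between-dataset scale differences.

alpha defaults to 0.25 and matrix-level range normalization (divide every
score by the global max-min) defaults to on, matching the common single-
sample enrichment defaults; both are configurable.  Normalization is one
global positive scale factor, so it can never flip the sign of a
within-sample difference between two pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCatalog

logger = logging.getLogger(__name__)

__all__ = ["PathwayActivityMatrix", "ssgsea_sample", "ssgsea_matrix"]


@dataclass
class PathwayActivityMatrix:
    """Pathways x samples matrix of ssGSEA scores.

    Row order is catalog order; column order is expression sample order.
    """

    scores: pd.DataFrame
    alpha: float
    normalized: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("pathway activity scores must be finite")

    @property
    def pathway_ids(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.columns.tolist()


def ssgsea_sample(
    expression: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    alpha: float = 0.25,
) -> float:
    """Score one gene set in one sample.

    ``expression`` maps gene id to expression value; ``gene_set`` is the set
    of member genes (genes absent from the expression vector are ignored by
    the caller's responsibility — here membership is taken literally).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    series = pd.Series(expression, dtype=float)
    genes = series.index.to_numpy()
    values = series.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    if not in_set.any():
        raise ValueError("gene set has no overlap with the expression vector")
    if in_set.all():
        raise ValueError("gene set covers every expression row; complement is empty")
    return float(_score_sorted(values, in_set[np.newaxis, :], alpha)[0])


def _score_sorted(values: np.ndarray, set_masks: np.ndarray, alpha: float) -> np.ndarray:
    """Core running-sum, vectorized over sets.

    ``values``: (N,) one sample's expression in gene order.
    ``set_masks``: (n_sets, N) boolean membership in gene order.
    Returns an (n_sets,) array of scores.
    """
    n = values.shape[0]
    # decreasing expression, stable in input gene order for ties
    order = np.argsort(-values, kind="stable")
    rho = np.arange(n, 0, -1, dtype=float)  # N+1-position for positions 1..N
    masks = set_masks[:, order]
    w = np.where(masks, rho[np.newaxis, :] ** alpha, 0.0)
    p_in = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
    out = ~masks
    n_out = out.sum(axis=1, keepdims=True)
    p_out = np.cumsum(out, axis=1) / n_out
    return (p_in - p_out).sum(axis=1)


def ssgsea_matrix(
    expr: ExpressionMatrix,
    catalog: GeneSetCatalog,
    alpha: float = 0.25,
    normalize: bool = True,
    min_genes: int = 2,
) -> PathwayActivityMatrix:
    """Score every catalog pathway in every sample.

    Genes in a set but absent from the expression matrix are dropped (and
    logged); a pathway retaining fewer than ``min_genes`` genes is an error
    so the caller can decide to drop it explicitly.
    """
    genes = np.asarray(expr.gene_ids)
    masks = np.zeros((len(catalog), len(genes)), dtype=bool)
    for i, pathway in enumerate(catalog):
        mask = np.isin(genes, list(pathway.genes))
        n_hit = int(mask.sum())
        if n_hit < len(pathway.genes):
            logger.info(
                "pathway %s: %d/%d genes present in the expression matrix",
                pathway.id, n_hit, len(pathway.genes),
            )
        if n_hit < min_genes:
            raise ValueError(
                f"pathway {pathway.id!r} has only {n_hit} genes in the expression "
                f"matrix (min_genes={min_genes}); drop it from the catalog first"
            )
        if mask.all():
            raise ValueError(
                f"pathway {pathway.id!r} covers every expression row; "
                "the out-of-set complement is empty"
            )
        masks[i] = mask

    values = expr.values.to_numpy(dtype=float)
    scores = np.empty((len(catalog), values.shape[1]))
    for k in range(values.shape[1]):
        scores[:, k] = _score_sorted(values[:, k], masks, alpha)

    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return PathwayActivityMatrix(
        scores=pd.DataFrame(scores, index=catalog.ids, columns=expr.sample_ids),
        alpha=alpha,
        normalized=normalize,
    )
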