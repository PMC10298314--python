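"""Consensus NMF subtyping of case samples from their pair signatures.

The signature matrix (pairs x samples) contains negative values, so it is
first mapped through elementwise e^x, which is strictly positive and
order-preserving.  Factorization uses the classic multiplicative-update NMF
minimizing generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

whose updates guarantee a non-increasing objective.  Stability comes from
consensus over ``nrun`` random restarts: each run assigns samples to the
argmax row of H, runs are averaged into an n x n consensus matrix, and
per-rank quality is summarized by the cophenetic correlation, the
dispersion coefficient (1/n^2) sum 4 (c - 1/2)^2, and the mean silhouette
on the 1 - consensus distance.  The chosen rank is the smallest one
attaining the maximum cophenetic coefficient (ties: higher dispersion, then
higher silhouette).

Final assignments cut the average-linkage tree of 1 - consensus into k
clusters; labels are canonicalized by decreasing cluster size (cluster 1 is
the largest), so "S1" is always the bigger subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "NMFRun",
    "ConsensusResult",
    "exp_transform",
    "nmf_factorize",
    "summarize_consensus",
    "consensus_cluster",
    "select_rank",
    "metrics_frame",
]

_EPS = 1e-12


def exp_transform(values) -> np.ndarray:
    """Elementwise e^x: strictly positive, order-preserving."""
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("input to exp_transform must be finite")
    return np.exp(arr)


@dataclass
class NMFRun:
    """One factorization: V ~ W @ H with the KL objective per iteration."""

    W: np.ndarray
    H: np.ndarray
    trace: np.ndarray
    seed: int

    @property
    def assignments(self) -> np.ndarray:
        """Per-sample cluster = argmax of its H column."""
        return self.H.argmax(axis=0)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(V > 0, V * np.log(V / WH) - V, 0.0)
    return float((term + WH).sum())


def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFRun:
    """Multiplicative-update KL-divergence NMF at rank ``k``.

    W and H start i.i.d. Uniform(0,1) scaled by mean(V) and are floored at
    1e-12 throughout.  Iteration stops when the relative objective change
    drops below ``tol`` or after ``max_iter`` updates.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError(
            "NMF input must be nonnegative; apply exp_transform to signed "
            "signature matrices first"
        )
    if (V.sum(axis=1) == 0).any():
        raise ValueError("NMF input has an all-zero row")
    m, n = V.shape
    if not 2 <= k < min(m, n):
        raise ValueError(f"rank k={k} outside valid range [2, {min(m, n) - 1}]")

    rng = np.random.default_rng(seed)
    scale = V.mean()
    W = np.maximum(rng.uniform(size=(m, k)) * scale, _EPS)
    H = np.maximum(rng.uniform(size=(k, n)) * scale, _EPS)

    trace = []
    prev = None
    for _ in range(max_iter):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        H = np.maximum(H, _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        W = np.maximum(W, _EPS)
        obj = _kl_divergence(V, W @ H + _EPS)
        trace.append(obj)
        if prev is not None and abs(prev - obj) <= tol * max(abs(prev), 1.0):
            break
        prev = obj
    return NMFRun(W=W, H=H, trace=np.asarray(trace), seed=seed)


@dataclass
class ConsensusResult:
    """Consensus over restarts at one rank, with its quality metrics."""

    k: int
    consensus: pd.DataFrame
    assignments: pd.Series
    cophenetic: float
    dispersion: float
    silhouette: float

    def metrics(self) -> dict:
        return {
            "k": self.k,
            "cophenetic": self.cophenetic,
            "dispersion": self.dispersion,
            "silhouette": self.silhouette,
        }


def _canonicalize_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size (stable on ties)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.asarray([mapping[v] for v in labels])


def summarize_consensus(
    consensus: np.ndarray, k: int
) -> tuple[float, float, float, np.ndarray]:
    """Quality metrics and final assignments for one consensus matrix.

    Returns (cophenetic, dispersion, silhouette, labels).  Assignments cut
    the average-linkage tree of 1 - consensus into ``k`` clusters, labels
    canonicalized by decreasing size.  Silhouette is NaN when the cut
    collapses to one cluster.
    """
    consensus = np.asarray(consensus, dtype=float)
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    if condensed.std() == 0:
        coph = 1.0  # all distances equal: the tree reproduces them exactly
    else:
        coph = float(cophenet(Z, condensed)[0])
    dispersion = float((4.0 * (consensus - 0.5) ** 2).mean())
    labels = _canonicalize_by_size(fcluster(Z, t=k, criterion="maxclust"))
    if len(np.unique(labels)) > 1:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = float("nan")
    return coph, dispersion, sil, labels


def consensus_cluster(
    V,
    k_range=range(2, 7),
    nrun: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> dict[int, ConsensusResult]:
    """Consensus NMF clustering of the columns of ``V`` for each rank.

    ``V`` may be a DataFrame (columns = sample ids) or an array.  Runs are
    seeded deterministically from (seed, k, run index).
    """
    if nrun < 2:
        raise ValueError("nrun must be >= 2")
    if isinstance(V, pd.DataFrame):
        sample_ids = V.columns
        arr = V.to_numpy(dtype=float)
    else:
        arr = np.asarray(V, dtype=float)
        sample_ids = pd.RangeIndex(arr.shape[1])
    n = arr.shape[1]

    results: dict[int, ConsensusResult] = {}
    for k in k_range:
        if not 2 <= k < min(arr.shape):
            raise ValueError(f"rank k={k} outside valid range for shape {arr.shape}")
        connectivity = np.zeros((n, n))
        for r in range(nrun):
            run_seed = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(k, r)).generate_state(1)[0]
            )
            run = nmf_factorize(arr, k, seed=run_seed, max_iter=max_iter, tol=tol)
            labels = run.assignments
            connectivity += (labels[:, None] == labels[None, :]).astype(float)
        consensus = connectivity / nrun
        np.fill_diagonal(consensus, 1.0)

        coph, dispersion, sil, labels = summarize_consensus(consensus, k)
        results[k] = ConsensusResult(
            k=k,
            consensus=pd.DataFrame(consensus, index=sample_ids, columns=sample_ids),
            assignments=pd.Series(labels, index=sample_ids, name="subtype"),
            cophenetic=coph,
            dispersion=dispersion,
            silhouette=sil,
        )
        logger.info(
            "k=%d: cophenetic=%.4f dispersion=%.4f silhouette=%.4f",
            k, coph, dispersion, sil,
        )
    return results


def select_rank(results: dict[int, ConsensusResult]) -> int:
    """Smallest rank attaining the maximum cophenetic coefficient; ties are
    broken by higher dispersion, then higher silhouette, then smaller k."""
    if len(results) < 2:
        raise ValueError("need metrics for at least two candidate ranks")

    def key(k: int):
        r = results[k]
        sil = r.silhouette if np.isfinite(r.silhouette) else -np.inf
        return (-r.cophenetic, -r.dispersion, -sil, k)

    return min(results, key=key)


def metrics_frame(results: dict[int, ConsensusResult]) -> pd.DataFrame:
    return pd.DataFrame([results[k].metrics() for k in sorted(results)]).set_index("k")
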