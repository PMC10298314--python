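"""Pathway-pairwise (MPP) signatures and the cross-sample differential screen.

Within each sample, every unordered pathway pair (i, j) with i < j in
catalog order yields a continuous signature (the activity difference
MP_i - MP_j) and a discrete one, the ordering indicator

    r_ij = +1 if MP_i >= MP_j else -1.

Ties map to +1 by convention.  Because the indicator is computed within one
sample, it is immune to any monotone per-sample rescaling — the property
that lets signatures be compared across heterogeneous cohorts.

The cross-sample screen compares, per pair, how often each ordering occurs
in the two groups via a 2x2 contingency table

              MP_i >= MP_j   MP_i < MP_j
    control        a              b
    case           c              d

tested by Pearson's chi-square (1 df, no continuity correction) with Holm's
step-down familywise correction across all testable pairs.  Pairs whose
ordering is constant across every sample have a zero column margin, carry
no test, and are excluded from the Holm family rather than assigned p = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import PathwayActivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MPPMatrix",
    "PairTestResult",
    "ScreenResult",
    "pair_ids",
    "build_mpp",
    "chi_square_2x2",
    "holm_adjust",
    "differential_screen",
]


def pair_ids(pathway_ids: list[str]) -> list[str]:
    """Enumerate ``"idA-idB"`` pair labels for catalog indices i < j,
    lexicographic in (i, j)."""
    m = len(pathway_ids)
    return [
        f"{pathway_ids[i]}-{pathway_ids[j]}"
        for i in range(m)
        for j in range(i + 1, m)
    ]


def split_pair_id(pair_id: str) -> tuple[str, str]:
    parts = pair_id.split("-")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"malformed pair id {pair_id!r}; expected 'idA-idB'")
    return parts[0], parts[1]


@dataclass
class MPPMatrix:
    """C(m,2) pairs x n samples, in both representations.

    ``delta`` holds MP_i - MP_j; ``indicator`` holds the ±1 ordering.
    Both are kept because published models are ambiguous about which they
    consume.
    """

    delta: pd.DataFrame
    indicator: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.delta.index.equals(self.indicator.index):
            raise ValueError("delta and indicator must share the same pair index")
        expected = np.where(self.delta.to_numpy() >= 0, 1, -1)
        if not np.array_equal(self.indicator.to_numpy(), expected):
            raise ValueError("indicator must equal sign(delta) with ties -> +1")

    @property
    def pair_index(self) -> pd.Index:
        return self.delta.index

    @property
    def sample_ids(self) -> list[str]:
        return self.delta.columns.tolist()

    def values_for(self, representation: str) -> pd.DataFrame:
        if representation == "continuous":
            return self.delta
        if representation == "discrete":
            return self.indicator
        raise ValueError(f"unknown representation {representation!r}")


def build_mpp(activity: PathwayActivityMatrix) -> MPPMatrix:
    """Expand an m-pathway activity matrix into its C(m,2) pair signatures."""
    ids = activity.pathway_ids
    m = len(ids)
    if m < 2:
        raise ValueError(f"need at least 2 pathways to form pairs, got {m}")
    scores = activity.scores.to_numpy()
    ii, jj = np.triu_indices(m, k=1)
    delta = scores[ii] - scores[jj]
    indicator = np.where(delta >= 0, 1, -1)
    index = pd.Index(pair_ids(ids), name="pair")
    cols = activity.scores.columns
    return MPPMatrix(
        delta=pd.DataFrame(delta, index=index, columns=cols),
        indicator=pd.DataFrame(indicator, index=index, columns=cols),
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    Rows are groups, columns the two orderings.  Any zero row or column
    margin makes the table degenerate (no association is testable).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: a zero row or column margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class PairTestResult:
    """One pair's contingency counts and test outcome."""

    pair_id: str
    a: int
    b: int
    c: int
    d: int
    chi2: float
    p: float
    p_adj: float

    def flagged(self, alpha_adj: float) -> bool:
        return self.p_adj < alpha_adj


@dataclass
class ScreenResult:
    """Full screen output: every tested pair, the flagged subset, and the
    pairs skipped as degenerate."""

    results: list[PairTestResult]
    flagged: list[PairTestResult]
    skipped: dict[str, str] = field(default_factory=dict)
    alpha_adj: float = 0.01

    @property
    def flagged_pair_ids(self) -> list[str]:
        return [r.pair_id for r in self.flagged]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "pair_id": r.pair_id,
                    "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                    "chi2": r.chi2, "p": r.p, "p_adj": r.p_adj,
                    "flagged": r.flagged(self.alpha_adj),
                }
                for r in self.results
            ]
        )
        return df


def differential_screen(
    mpp: MPPMatrix,
    groups: pd.Series,
    alpha_adj: float = 0.01,
    positive: str = "AD",
) -> ScreenResult:
    """Chi-square screen of every pair's ordering indicator between two groups.

    ``groups`` maps sample id to label; exactly two labels must be present
    and ``positive`` names the case group (table rows are control then
    case).  Holm's correction runs across all non-degenerate pairs; flagged
    pairs are those with adjusted p below ``alpha_adj``.
    """
    groups = pd.Series(groups).loc[mpp.sample_ids]
    labels = groups.unique().tolist()
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    if positive not in labels:
        raise ValueError(f"positive label {positive!r} not among groups {labels}")
    control = labels[0] if labels[1] == positive else labels[1]

    ind = mpp.indicator.to_numpy()
    case_mask = (groups == positive).to_numpy()
    plus = ind == 1
    a = plus[:, ~case_mask].sum(axis=1)
    b = (~plus)[:, ~case_mask].sum(axis=1)
    c = plus[:, case_mask].sum(axis=1)
    d = (~plus)[:, case_mask].sum(axis=1)

    results_raw: list[tuple[str, int, int, int, int, float, float]] = []
    skipped: dict[str, str] = {}
    for row, pid in enumerate(mpp.pair_index):
        if a[row] + c[row] == 0 or b[row] + d[row] == 0:
            skipped[pid] = "constant ordering across all samples (zero column margin)"
            logger.info("pair %s skipped: %s", pid, skipped[pid])
            continue
        chi2, p = chi_square_2x2(int(a[row]), int(b[row]), int(c[row]), int(d[row]))
        results_raw.append((pid, int(a[row]), int(b[row]), int(c[row]), int(d[row]), chi2, p))

    p_adj = holm_adjust([r[6] for r in results_raw])
    results = [
        PairTestResult(pid, ra, rb, rc, rd, chi2, p, float(padj))
        for (pid, ra, rb, rc, rd, chi2, p), padj in zip(results_raw, p_adj)
    ]
    flagged = [r for r in results if r.flagged(alpha_adj)]
    logger.info(
        "screen (%s vs %s): %d pairs tested, %d skipped, %d flagged at adjusted p < %g",
        control, positive, len(results), len(skipped), len(flagged), alpha_adj,
    )
    return ScreenResult(results=results, flagged=flagged, skipped=skipped, alpha_adj=alpha_adj)
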