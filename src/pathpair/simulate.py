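"""Synthetic expression cohorts with planted pathway-pair ground truth.

The generator emulates the structure of a merged case/control blood
microarray cohort on the log scale with an additive Gaussian model:

    x_gs = mu_g + sum_{p : g in p} delta(p, arm(s)) + batch_s + eps_gs

with gene baselines mu_g ~ Normal(mu0, sigma0^2), noise eps ~ Normal(0,
sigma^2) and group/subtype shifts delta taken from an effect table.  The
case group ("AD") splits into two planted subtypes S1 and S2; effects can
target the whole case group, one subtype, or the control group ("non-AD" —
needed to plant a genuine ordering *flip*, where pathway A ranks above B in
controls and below it in cases).  Pathways occupy disjoint gene blocks; the
remaining genes are unassigned background.

Defaults are sized for seconds-scale testing (10 pathways x 30 genes, 300
background genes, 60 controls and 40 + 30 cases) with log2-microarray-like
levels (mu0 = 6, sigma0 = 1) and noise sigma = 0.5.  All randomness flows
from a single integer seed; identical (config, seed) gives byte-identical
output.

Ground truth: a pair (i, j) is a truth pair when its planted ordering
contrast

    [Delta_case(i) - Delta_case(j)] - [Delta_control(i) - Delta_control(j)]

is nonzero, where Delta_arm(p) is the expected shift of pathway p in that
arm (cases average the two subtypes by size).  Subtype truth pairs are
defined the same way between S1 and S2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionMatrix, GeneSet, GeneSetCatalog
from .activity import ssgsea_matrix
from .pairs import build_mpp, differential_screen, holm_adjust, pair_ids

__all__ = [
    "Effect",
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
    "null_screen_calibration",
    "NullCalibration",
    "null_config",
    "flip_config",
    "subtype_config",
    "classification_config",
]

_ARMS = ("AD", "S1", "S2", "non-AD")


@dataclass(frozen=True)
class Effect:
    """Additive shift (log-expression units) for one pathway in one arm."""

    pathway: str
    group: str  # one of AD (both subtypes), S1, S2, non-AD
    delta: float

    def __post_init__(self) -> None:
        if self.group not in _ARMS:
            raise ValueError(f"effect group must be one of {_ARMS}, got {self.group!r}")


@dataclass
class SimulationConfig:
    n_background_genes: int = 300
    m_pathways: int = 10
    genes_per_pathway: tuple[int, int] = (30, 30)  # inclusive range
    n_nonAD: int = 60
    n_S1: int = 40
    n_S2: int = 30
    mu0: float = 6.0
    sigma0: float = 1.0
    sigma: float = 0.5
    effects: list[Effect] = field(default_factory=list)
    n_batches: int = 1
    batch_sd: float = 0.0
    n_total_genes: int | None = None  # optional hard cap on the gene pool
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background_genes", "m_pathways", "n_nonAD", "n_S1", "n_S2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma < 0 or self.sigma0 < 0 or self.batch_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        lo, hi = self.genes_per_pathway
        if not 1 <= lo <= hi:
            raise ValueError("genes_per_pathway must be a nonempty positive range")
        self.effects = [e if isinstance(e, Effect) else Effect(**e) for e in self.effects]
        valid = {f"P{i + 1:02d}" for i in range(self.m_pathways)}
        for e in self.effects:
            if e.pathway not in valid:
                raise ValueError(f"effect pathway {e.pathway!r} not among {sorted(valid)}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "genes_per_pathway" in raw:
            raw["genes_per_pathway"] = tuple(raw["genes_per_pathway"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """What was planted: labels, per-pathway shifts and the pair-level truth."""

    groups: pd.Series
    subtypes: pd.Series
    shifts: pd.DataFrame          # pathway x arm expected shift
    truth_pairs: set[str]         # ordering contrast AD vs non-AD nonzero
    subtype_truth_pairs: set[str]  # ordering contrast S1 vs S2 nonzero

    def to_dict(self) -> dict:
        return {
            "groups": self.groups.to_dict(),
            "subtypes": self.subtypes.dropna().to_dict(),
            "shifts": {c: self.shifts[c].to_dict() for c in self.shifts.columns},
            "truth_pairs": sorted(self.truth_pairs),
            "subtype_truth_pairs": sorted(self.subtype_truth_pairs),
        }


def _arm_shifts(config: SimulationConfig, path_ids: list[str]) -> pd.DataFrame:
    """Expected shift of each pathway in each arm (non-AD, S1, S2, AD-mix)."""
    shifts = pd.DataFrame(0.0, index=path_ids, columns=["non-AD", "S1", "S2"])
    for e in config.effects:
        if e.group == "AD":
            shifts.loc[e.pathway, ["S1", "S2"]] += e.delta
        else:
            shifts.loc[e.pathway, e.group] += e.delta
    w1 = config.n_S1 / (config.n_S1 + config.n_S2)
    shifts["AD"] = w1 * shifts["S1"] + (1 - w1) * shifts["S2"]
    return shifts


def _contrast_pairs(shifts: pd.DataFrame, arm_a: str, arm_b: str) -> set[str]:
    ids = shifts.index.tolist()
    d = (shifts[arm_a] - shifts[arm_b]).to_numpy()
    out = set()
    for pid in pair_ids(ids):
        a, b = pid.split("-")
        if d[ids.index(a)] - d[ids.index(b)] != 0:
            out.add(pid)
    return out


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneSetCatalog, GroundTruth]:
    """Draw one cohort from the additive model.  Deterministic in the config."""
    rng = np.random.default_rng(config.seed)

    sizes = rng.integers(
        config.genes_per_pathway[0], config.genes_per_pathway[1] + 1,
        size=config.m_pathways,
    )
    n_pathway_genes = int(sizes.sum())
    n_genes = n_pathway_genes + config.n_background_genes
    if config.n_total_genes is not None:
        if config.n_total_genes < n_pathway_genes:
            raise ValueError(
                f"gene pool too small: {config.n_total_genes} genes cannot host "
                f"{n_pathway_genes} pathway genes"
            )
        n_genes = config.n_total_genes
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]

    path_ids = [f"P{i + 1:02d}" for i in range(config.m_pathways)]
    catalog_sets = []
    membership = np.zeros((config.m_pathways, n_genes), dtype=bool)
    start = 0
    for i, (pid, size) in enumerate(zip(path_ids, sizes)):
        block = genes[start : start + size]
        membership[i, start : start + size] = True
        catalog_sets.append(GeneSet(pid, f"synthetic pathway {pid}", frozenset(block)))
        start += size
    catalog = GeneSetCatalog(catalog_sets)

    n_samples = config.n_nonAD + config.n_S1 + config.n_S2
    sample_ids = (
        [f"N{i + 1:03d}" for i in range(config.n_nonAD)]
        + [f"A{i + 1:03d}" for i in range(config.n_S1 + config.n_S2)]
    )
    groups = pd.Series(
        ["non-AD"] * config.n_nonAD + ["AD"] * (config.n_S1 + config.n_S2),
        index=sample_ids, name="group",
    )
    subtypes = pd.Series(
        [None] * config.n_nonAD + ["S1"] * config.n_S1 + ["S2"] * config.n_S2,
        index=sample_ids, name="subtype", dtype=object,
    )
    arm = np.array(
        ["non-AD"] * config.n_nonAD + ["S1"] * config.n_S1 + ["S2"] * config.n_S2
    )

    shifts = _arm_shifts(config, path_ids)
    # per-sample pathway shift -> per-sample gene shift through membership
    sample_path_shift = shifts[["non-AD", "S1", "S2"]].to_numpy()[
        :, [["non-AD", "S1", "S2"].index(a) for a in arm]
    ]  # m_pathways x n_samples
    gene_shift = membership.T.astype(float) @ sample_path_shift  # genes x samples

    mu = rng.normal(config.mu0, config.sigma0, size=n_genes)
    eps = rng.normal(0.0, config.sigma, size=(n_genes, n_samples))
    values = mu[:, None] + gene_shift + eps

    batch = pd.Series(
        [f"B{(i % config.n_batches) + 1}" for i in range(n_samples)],
        index=sample_ids, name="batch",
    )
    if config.n_batches > 1 and config.batch_sd > 0:
        offsets = rng.normal(0.0, config.batch_sd, size=config.n_batches)
        values = values + offsets[[i % config.n_batches for i in range(n_samples)]]

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        metadata=pd.DataFrame({"group": groups, "subtype": subtypes, "batch": batch}),
    )
    truth = GroundTruth(
        groups=groups,
        subtypes=subtypes,
        shifts=shifts,
        truth_pairs=_contrast_pairs(shifts, "AD", "non-AD"),
        subtype_truth_pairs=_contrast_pairs(shifts, "S1", "S2"),
    )
    return expr, catalog, truth


@dataclass(frozen=True)
class NullCalibration:
    """Monte-Carlo type-I error of the screen under a null generator."""

    raw_fraction: float   # pooled fraction of pairs with raw p < alpha
    fwer: float           # fraction of replicates with any Holm-adjusted p < alpha_holm
    n_pairs_tested: int
    n_replicates: int


def null_screen_calibration(
    config: SimulationConfig,
    n_replicates: int = 50,
    alpha: float = 0.05,
    alpha_holm: float = 0.01,
    ssgsea_alpha: float = 0.25,
) -> NullCalibration:
    """Run the full activity -> pair -> screen chain on null replicates.

    Requires an all-zero effect table.  Returns the pooled fraction of raw
    p-values below ``alpha`` (per-test type-I error) and the fraction of
    replicates with at least one Holm-adjusted p below ``alpha_holm``
    (familywise error).
    """
    if any(e.delta != 0 for e in config.effects):
        raise ValueError("null calibration requires all effect deltas to be zero")
    hits = 0
    tested = 0
    family_hits = 0
    for rep in range(n_replicates):
        rep_seed = int(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(rep,)).generate_state(1)[0]
            % (2**31)
        )
        expr, catalog, _ = generate_dataset(replace(config, seed=rep_seed))
        activity = ssgsea_matrix(expr, catalog, alpha=ssgsea_alpha)
        mpp = build_mpp(activity)
        screen = differential_screen(mpp, expr.groups, alpha_adj=alpha_holm)
        raw = np.array([r.p for r in screen.results])
        # standard rejection rule p <= alpha: discrete tables can sit exactly
        # on a p-value (e.g. p = 1 for identical rows), so strict < would
        # undercount at the boundary
        hits += int((raw <= alpha).sum())
        tested += len(raw)
        if len(raw) and holm_adjust(raw).min() < alpha_holm:
            family_hits += 1
    return NullCalibration(
        raw_fraction=hits / max(tested, 1),
        fwer=family_hits / n_replicates,
        n_pairs_tested=tested,
        n_replicates=n_replicates,
    )


# --- stated-world presets -------------------------------------------------
# Frozen scenario configurations used throughout the test suite.  Effect
# sizes are stated once here, in units of the noise sd (sigma = 0.5):
# flips are 2*sigma per arm, subtype separations 3*sigma, case-only
# classification effects 2*sigma.


def null_config(seed: int = 0) -> SimulationConfig:
    """No planted effects."""
    return SimulationConfig(seed=seed)


def flip_config(seed: int = 0) -> SimulationConfig:
    """One pathway flipped: above its peers in controls, below them in cases.

    P01 gets +1.0 in non-AD and -1.0 in AD, so every (P01, X) ordering
    reverses between the arms; the nine P01 pairs are the truth pairs.
    """
    return SimulationConfig(
        effects=[Effect("P01", "non-AD", 1.0), Effect("P01", "AD", -1.0)],
        seed=seed,
    )


def subtype_config(seed: int = 0) -> SimulationConfig:
    """Two case subtypes with opposing pathway orderings (3-sigma shifts)."""
    return SimulationConfig(
        effects=[
            Effect("P02", "S1", 1.5), Effect("P03", "S1", -1.5),
            Effect("P02", "S2", -1.5), Effect("P03", "S2", 1.5),
        ],
        seed=seed,
    )


def classification_config(seed: int = 0) -> SimulationConfig:
    """Case-only 2-sigma shifts on five pathways, for risk-score recovery."""
    return SimulationConfig(
        effects=[Effect(f"P{i:02d}", "AD", 1.0) for i in range(1, 6)],
        seed=seed,
    )
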