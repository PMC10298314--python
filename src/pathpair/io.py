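"""Readers and writers for the formats the pipeline touches.

Gene sets travel as GMT (one tab-separated set per line), expression and
sample metadata as delimited tables (TSV by default, CSV when the file
extension says so), and pair-scoring models as JSON.  All readers reject
structural defects (duplicate identifiers, missing metadata, non-numeric
cells) instead of repairing them silently: downstream statistics assume the
containers are clean.

Gene identifiers are treated as case-sensitive opaque symbols; no alias or
probe mapping is attempted.  Expression is assumed to arrive on a log-like
scale and is not transformed at read time.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import MPPSSModel

__all__ = [
    "GeneSet",
    "GeneSetCatalog",
    "ExpressionMatrix",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_model",
    "write_model",
    "load_published_model",
]


@dataclass(frozen=True)
class GeneSet:
    """One pathway: a short identifier, a display name and its member genes."""

    id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} is empty")
        if "-" in self.id:
            raise ValueError(
                f"gene set id {self.id!r} contains '-', which is reserved as the "
                "pair-id separator"
            )


@dataclass
class GeneSetCatalog:
    """Ordered collection of pathways.

    Order is load order and is stable: it defines the pair enumeration order
    used by every downstream pairwise statistic, so two runs over the same
    catalog produce identically ordered pair matrices.
    """

    pathways: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate pathway ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, int):
            return self.pathways[key]
        for p in self.pathways:
            if p.id == key:
                return p
        raise KeyError(key)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with aligned per-sample metadata.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns; ``metadata`` is indexed by sample id and must cover every
    sample.  A ``group`` column is expected for two-group analyses;
    ``subtype`` and ``batch`` columns are optional.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        # keep metadata aligned and restricted to the expression samples
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]


def read_gmt(path: str | os.PathLike) -> GeneSetCatalog:
    """Parse a GMT file into a catalog, preserving file order.

    Each line must carry at least three tab-separated fields: id,
    description, and one or more genes.  Duplicate genes within one set are
    deduplicated; a duplicate set id or a set with no genes is an error.
    """
    pathways: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(need id, description and >=1 gene, got {len(fields)} fields)"
                )
            set_id, name, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {set_id!r} has no genes")
            if set_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene set id {set_id!r}")
            seen.add(set_id)
            pathways.append(GeneSet(set_id, name, frozenset(genes)))
    return GeneSetCatalog(pathways)


def write_gmt(catalog: GeneSetCatalog, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in catalog:
            fh.write("\t".join([p.id, p.name, *sorted(p.genes)]) + "\n")


def _delimiter(path: str | os.PathLike) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    return df


def read_expression(
    path: str | os.PathLike, metadata_path: str | os.PathLike
) -> ExpressionMatrix:
    """Read an expression table (genes in rows, first column gene id) plus a
    metadata table keyed by sample id."""
    values = _read_table(path)
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric expression value at gene {gene!r}, "
                f"sample {col!r}"
            )
    metadata = _read_table(metadata_path)
    return ExpressionMatrix(values.astype(float), metadata)


def write_expression(
    expr: ExpressionMatrix,
    path: str | os.PathLike,
    metadata_path: str | os.PathLike | None = None,
) -> None:
    expr.values.to_csv(path, sep=_delimiter(path), index_label="gene")
    if metadata_path is not None:
        expr.metadata.to_csv(
            metadata_path, sep=_delimiter(metadata_path), index_label="sample"
        )


_REPRESENTATIONS = ("continuous", "discrete")


def read_model(path: str | os.PathLike) -> MPPSSModel:
    """Read a pair-scoring model from JSON.

    The file is an object with ``entries`` (list of ``{"pair": .., "coef": ..}``),
    optional ``intercept`` (default 0), ``representation`` (``continuous`` —
    signed activity differences — or ``discrete`` — the ±1 ordering
    indicator) and free-text ``provenance``.
    """
    with open(path) as fh:
        obj = json.load(fh)
    rep = obj.get("representation", "continuous")
    if rep not in _REPRESENTATIONS:
        raise ValueError(
            f"{path}: unknown representation {rep!r}; expected one of {_REPRESENTATIONS}"
        )
    entries = [(e["pair"], float(e["coef"])) for e in obj["entries"]]
    return MPPSSModel(
        entries=entries,
        intercept=float(obj.get("intercept", 0.0)),
        representation=rep,
        provenance=obj.get("provenance", ""),
    )


def write_model(model: MPPSSModel, path: str | os.PathLike) -> None:
    obj = {
        "entries": [{"pair": p, "coef": c} for p, c in model.entries],
        "intercept": model.intercept,
        "representation": model.representation,
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def load_published_model() -> MPPSSModel:
    """Load the bundled published 13-pair blood diagnostic model."""
    path = os.path.join(os.path.dirname(__file__), "data", "mppss_published.json")
    return read_model(path)
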