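"""Readers, writers and normalization for the tabular formats used throughout.

Expression matrices are genes x samples on a log scale (the package assumes
log-transformed intensities or log counts; readers do not transform). Gene
identifiers are opaque, case-sensitive strings — any symbol/RefSeq mapping is
the caller's responsibility. Missing values are rejected: every cell must be
a finite number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id. All
        entries must be finite floats (log-scale expression).
    annotations
        DataFrame indexed by sample id; one column per annotation key
        (e.g. ``cell_line``, ``cd133_status``). May be empty but its index
        must match the sample ids of ``values``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.values.columns)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if vals.columns.duplicated().any():
            dups = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = vals.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {vals.index[bad[0]]!r}, "
                f"sample {vals.columns[bad[1]]!r}"
            )
        if not self.annotations.index.equals(vals.columns):
            raise ValueError("annotation index must equal sample ids")

    # -- convenience --------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_where(self, key: str, value: object) -> list[str]:
        """Sample ids whose annotation ``key`` equals ``value``."""
        if key not in self.annotations.columns:
            raise KeyError(f"annotation key {key!r} not present")
        mask = self.annotations[key] == value
        return list(self.annotations.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.annotations.loc[list(sample_ids)]
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (the GMT model)."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("gene set names must be unique")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls([GeneSet(k, "", tuple(dict.fromkeys(v))) for k, v in d.items()])


@dataclass
class CohortClinical:
    """Per-sample clinical covariates with optional survival columns.

    ``table`` is indexed by sample id. ``feature_types`` maps feature name to
    ``"categorical"`` or ``"continuous"``; types are inferred from dtypes at
    construction and may be overridden.
    """

    table: pd.DataFrame
    time_col: str | None = None
    event_col: str | None = None
    feature_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if self.time_col is not None:
            t = pd.to_numeric(self.table[self.time_col], errors="coerce")
            if t.isna().any():
                raise ValueError(f"non-numeric survival time in {self.time_col!r}")
            if (t < 0).any():
                raise ValueError("negative survival time")
        if self.event_col is not None:
            ev = self.table[self.event_col]
            bad = ~ev.isin([0, 1])
            if bad.any():
                raise ValueError(
                    "event column must be coded 0/1 (0 = censored, 1 = event); "
                    f"found {sorted(ev[bad].unique().tolist())[:4]} — recode it"
                )
        inferred = {
            c: ("continuous" if pd.api.types.is_numeric_dtype(self.table[c]) else "categorical")
            for c in self.table.columns
            if c not in (self.time_col, self.event_col)
        }
        inferred.update(self.feature_types)
        self.feature_types = inferred

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def feature(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"unknown clinical feature {name!r}")
        return self.table[name]


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(df: pd.DataFrame, how: str = "max_variance") -> pd.DataFrame:
    dup_mask = df.index.duplicated(keep=False)
    if not dup_mask.any():
        return df
    dups = df.index[dup_mask].unique().tolist()
    warnings.warn(
        f"{len(dups)} gene id(s) duplicated ({dups[:3]}...); "
        f"keeping the {how.replace('_', '-')} row per gene",
        stacklevel=3,
    )
    if how != "max_variance":
        raise ValueError(f"unknown duplicate policy {how!r}")
    variances = df.var(axis=1, ddof=1).fillna(0.0).to_numpy()
    keep = np.zeros(len(df), dtype=bool)
    order = pd.Series(np.arange(len(df)), index=df.index)
    for g in df.index.unique():
        rows = np.atleast_1d(order[g])
        keep[rows[np.argmax(variances[rows])]] = True
    return df.loc[keep]


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().to_numpy().any():
        na = np.argwhere(out.isna().to_numpy())[0]
        raise FormatError(
            f"non-numeric or missing value at gene {df.index[na[0]]!r}, "
            f"sample {df.columns[na[1]]!r}"
        )
    return out.astype(float)


def read_expression_table(
    path: str | Path,
    format: str = "tsv",
    duplicate_policy: str = "max_variance",
) -> ExpressionMatrix:
    """Read a genes x samples table from TSV or GCT 1.2.

    Duplicate gene rows are collapsed to the maximum-variance row with a
    warning; duplicate sample ids are an error.
    """
    path = Path(path)

    def _check_header(line: str) -> None:
        # pandas mangles duplicate column names, so inspect the raw header
        names = line.rstrip("\n").split("\t")[1:]
        dups = [s for i, s in enumerate(names) if s in names[:i]]
        if dups:
            raise FormatError(f"duplicate sample ids: {sorted(set(dups))[:5]}")

    if format == "tsv":
        with open(path) as fh:
            _check_header(fh.readline())
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise FormatError(f"unsupported GCT version line: {version!r}")
            fh.readline()  # size row; trusted but not required
            df = pd.read_csv(fh, sep="\t", index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
    else:
        raise ValueError(f"unknown format {format!r}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dups[:5]}")
    df.index = df.index.astype(str)
    df = _coerce_numeric(df)
    df = _collapse_duplicate_genes(df, duplicate_policy)
    return ExpressionMatrix(df)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = matrix.values.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_annotations(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.annotations.to_csv(path, sep="\t", index_label="sample_id")


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Genes are deduplicated within a set (first occurrence wins); line order
    is preserved.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} field(s) found)"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name, desc, tuple(dict.fromkeys(genes))))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------


def read_clinical_table(
    path: str | Path,
    sample_col: str = "sample_id",
    time_col: str | None = None,
    event_col: str | None = None,
    feature_types: Mapping[str, str] | None = None,
) -> CohortClinical:
    """Read a clinical TSV keyed by sample id.

    ``time_col``/``event_col`` default to ``time``/``event`` when those
    columns exist. Event must be coded 0/1 and times must be non-negative.
    """
    df = pd.read_csv(path, sep="\t")
    if sample_col not in df.columns:
        raise FormatError(f"clinical table lacks sample column {sample_col!r}")
    df = df.set_index(sample_col)
    if time_col is None and "time" in df.columns:
        time_col = "time"
    if event_col is None and "event" in df.columns:
        event_col = "event"
    return CohortClinical(
        df, time_col=time_col, event_col=event_col,
        feature_types=dict(feature_types or {}),
    )


def write_clinical_table(clinical: CohortClinical, path: str | Path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common empirical distribution.

    The target distribution is the row-wise mean of the column-sorted values;
    within-column ranks are preserved and ties receive the average of the
    tied target quantiles. Idempotent, and a no-op for a single sample whose
    distribution is already the target.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        v = X[:, j]
        order = np.argsort(v, kind="mergesort")
        assigned = np.empty(n_genes)
        assigned[order] = target
        # tied values share the mean of the target quantiles they occupy,
        # which preserves column sums
        out[:, j] = pd.Series(assigned).groupby(pd.Series(v)).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.annotations.copy())
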