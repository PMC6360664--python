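"""Signal-to-noise differential expression and signature construction.

The SNR statistic for a gene between groups A and B is

    snr(g) = (mean_A - mean_B) / (sd_A + sd_B)

with sample standard deviations (n-1 denominator) and each sd floored at
``max(0.2 * |group mean|, 1e-8)`` — the convention of the desktop GSEA tool
from which the metric originates. The floor is switchable.

A marker signature ("up"/"down" pair) takes genes whose pooled SNR passes the
threshold AND whose mean difference has a consistent sign in every cell line
("commonly" up/down-regulated across lines); both conjuncts are independently
switchable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io import ExpressionMatrix

__all__ = [
    "compute_snr",
    "derive_signature",
    "select_top_variable",
    "build_core_signature",
    "hierarchical_cluster",
    "SignaturePair",
    "Dendrogram",
]


@dataclass
class SignaturePair:
    """Named up/down gene lists with the thresholds that produced them."""

    name: str
    up_genes: list[str]
    down_genes: list[str]
    up_threshold: float = 1.0
    down_threshold: float = -1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene lists must be disjoint")
        if not self.up_threshold > self.down_threshold:
            raise ValueError("up_threshold must exceed down_threshold")


def _group_stats(
    X: np.ndarray, idx: np.ndarray, sd_floor: bool
) -> tuple[np.ndarray, np.ndarray]:
    sub = X[:, idx]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    if sd_floor:
        sd = np.maximum(sd, np.maximum(0.2 * np.abs(mean), 1e-8))
    else:
        sd = np.maximum(sd, 1e-8)
    return mean, sd


def compute_snr(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    sd_floor: bool = True,
) -> pd.DataFrame:
    """Per-gene SNR of group A versus group B.

    Returns a DataFrame indexed by gene with columns ``snr``, ``mean_a``,
    ``mean_b``. Antisymmetric under group swap: ``snr(A,B) == -snr(B,A)``
    exactly, because the denominator is symmetric.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples (sd undefined otherwise)")
    cols = matrix.values.columns
    unknown = [s for s in group_a + group_b if s not in cols]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown[:5]}")
    X = matrix.values.to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(cols)}
    ia = np.array([pos[s] for s in group_a])
    ib = np.array([pos[s] for s in group_b])
    mean_a, sd_a = _group_stats(X, ia, sd_floor)
    mean_b, sd_b = _group_stats(X, ib, sd_floor)
    snr = (mean_a - mean_b) / (sd_a + sd_b)
    return pd.DataFrame(
        {"snr": snr, "mean_a": mean_a, "mean_b": mean_b}, index=matrix.values.index
    )


def derive_signature(
    matrix: ExpressionMatrix,
    status_key: str = "cd133_status",
    cell_line_key: str = "cell_line",
    up_threshold: float = 1.0,
    down_threshold: float = -1.0,
    positive_label: str = "pos",
    negative_label: str = "neg",
    require_sign_consistency: bool = True,
    sd_floor: bool = True,
    name: str = "signature",
) -> SignaturePair:
    """Derive an up/down signature from a multi-cell-line sorted experiment.

    The pooled SNR contrasts all positive-status samples against all
    negative-status samples; with ``require_sign_consistency`` a gene must
    additionally show a mean difference of the matching sign within every
    cell line.
    """
    ann = matrix.annotations
    for key in (status_key, cell_line_key):
        if key not in ann.columns:
            raise KeyError(f"annotation key {key!r} not present")
    lines = list(dict.fromkeys(ann[cell_line_key]))
    pos_all, neg_all = [], []
    per_line_diff = {}
    X = matrix.values
    for line in lines:
        in_line = ann.index[ann[cell_line_key] == line]
        pos = [s for s in in_line if ann.loc[s, status_key] == positive_label]
        neg = [s for s in in_line if ann.loc[s, status_key] == negative_label]
        if not pos or not neg:
            raise ValueError(
                f"cell line {line!r} is missing a {'positive' if not pos else 'negative'} arm"
            )
        pos_all += pos
        neg_all += neg
        per_line_diff[line] = (
            X[pos].to_numpy().mean(axis=1) - X[neg].to_numpy().mean(axis=1)
        )
    snr = compute_snr(matrix, pos_all, neg_all, sd_floor=sd_floor)["snr"].to_numpy()

    diffs = np.column_stack([per_line_diff[line] for line in lines])
    all_pos = (diffs > 0).all(axis=1)
    all_neg = (diffs < 0).all(axis=1)
    up_mask = snr > up_threshold
    down_mask = snr < down_threshold
    if require_sign_consistency:
        up_mask &= all_pos
        down_mask &= all_neg
    genes = matrix.values.index
    return SignaturePair(
        name=name,
        up_genes=list(genes[up_mask]),
        down_genes=list(genes[down_mask]),
        up_threshold=up_threshold,
        down_threshold=down_threshold,
        provenance=(
            f"pooled SNR {positive_label} vs {negative_label} over "
            f"{len(lines)} cell line(s); sign consistency="
            f"{require_sign_consistency}; sd floor={sd_floor}"
        ),
    )


def select_top_variable(
    matrix: ExpressionMatrix, n: int, statistic: str = "mad"
) -> list[str]:
    """The ``n`` genes with the largest MAD or variance across samples.

    Ties break lexicographically on gene id, which makes the selection
    deterministic and makes the top-n list a prefix of the top-(n+1) list.
    """
    if n > matrix.n_genes:
        raise ValueError(f"n={n} exceeds gene count {matrix.n_genes}")
    X = matrix.values
    if statistic == "mad":
        stat = (X.sub(X.median(axis=1), axis=0)).abs().median(axis=1)
    elif statistic == "variance":
        stat = X.var(axis=1, ddof=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    order = sorted(zip(-stat.to_numpy(), X.index.astype(str)))
    return [g for _, g in order[:n]]


def build_core_signature(
    signatures: Sequence[Sequence[str]], min_count: int = 2
) -> list[str]:
    """Genes appearing in at least ``min_count`` of the input gene lists.

    Each list counts a gene at most once (set semantics); the result is
    sorted lexicographically.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 input gene lists")
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    if min_count > len(signatures):
        raise ValueError(
            f"min_count={min_count} exceeds number of lists {len(signatures)}"
        )
    counts: dict[str, int] = {}
    for sig in signatures:
        for g in set(sig):
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= min_count)


@dataclass
class Dendrogram:
    """A hierarchical clustering result over named items."""

    items: list[str]
    linkage_matrix: np.ndarray
    distance: str
    linkage: str

    def cut(self, k: int) -> pd.Series:
        """Labels (1..k) from cutting the tree into ``k`` clusters."""
        labels = sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.items, name="cluster")

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hierarchical_cluster(
    data: pd.DataFrame,
    distance: str = "correlation",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of the rows of ``data``.

    Correlation distance is 1 - Pearson r; rows with zero variance are
    rejected under it (r undefined). Deterministic for fixed input.
    """
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if distance == "correlation":
        sds = data.std(axis=1, ddof=0)
        flat = sds[sds == 0].index.tolist()
        if flat:
            raise ValueError(
                f"zero-variance item(s) under correlation distance: {flat[:5]}"
            )
        d = ssd.pdist(data.to_numpy(dtype=float), metric="correlation")
    elif distance == "euclidean":
        d = ssd.pdist(data.to_numpy(dtype=float), metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    Z = sch.linkage(d, method=linkage)
    return Dendrogram(
        items=list(data.index.astype(str)),
        linkage_matrix=Z,
        distance=distance,
        linkage=linkage,
    )
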