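"""Single-sample gene-set enrichment (ssGSEA) scoring.

For one sample, genes are ordered by expression (descending; ties get the
average rank for weighting and break by gene id for the walk order). The
score is the summed difference between two cumulative distribution
functions walked down that ordering: the in-set CDF weighted by
``rank ** alpha`` (rank N for the top gene, normalized to total weight 1)
and the unweighted out-of-set empirical CDF:

    ES = sum_i [ P_in(i) - P_out(i) ]

With ``alpha = 0`` and a singleton set at the very top of a 4-gene sample
the walk gives 1 + 2/3 + 1/3 + 0 = 2; a singleton at the very bottom gives
-2 by symmetry. Scores depend only on within-sample ranks, so any strictly
increasing per-sample transform of the expression leaves them unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection

__all__ = ["ssgsea_score", "score_collection", "ScoreMatrix"]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25  # published ssGSEA default rank-weight exponent


@dataclass
class ScoreMatrix:
    """Signatures x samples enrichment scores."""

    scores: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    normalized: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise ValueError("scores must be finite")

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def row(self, name: str) -> pd.Series:
        return self.scores.loc[name]


def _sample_score(
    values: np.ndarray,
    gene_ids: np.ndarray,
    in_set: np.ndarray,
    alpha: float,
) -> float:
    n = len(values)
    # weight ranks: ascending rank so the top gene gets n; ties averaged
    weight_rank = rankdata(values, method="average")
    weights = weight_rank ** alpha
    # walk order: descending value, residual ties by gene id (stable)
    order = np.lexsort((gene_ids, -values))
    w_in = np.where(in_set, weights, 0.0)[order]
    out = (~in_set).astype(float)[order]
    cum_in = np.cumsum(w_in) / w_in.sum()
    cum_out = np.cumsum(out) / out.sum()
    return float(np.sum(cum_in - cum_out))


def ssgsea_score(
    matrix: ExpressionMatrix,
    gene_set: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """Per-sample enrichment score of one gene set.

    Requires a non-empty overlap with the measured genes and a non-empty
    complement (a set covering every gene has no out-of-set CDF).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = matrix.values.index.to_numpy(dtype=object)
    in_set = np.isin(genes, np.asarray(list(gene_set), dtype=object))
    n_overlap = int(in_set.sum())
    if n_overlap == 0:
        raise ValueError("gene set has no overlap with the expression matrix")
    if n_overlap == len(genes):
        raise ValueError("gene set covers every measured gene (empty complement)")
    logger.debug(
        "ssgsea overlap %d/%d genes (%.1f%%)",
        n_overlap, len(set(gene_set)), 100.0 * n_overlap / len(set(gene_set)),
    )
    X = matrix.values.to_numpy(dtype=float)
    scores = [
        _sample_score(X[:, j], genes, in_set, alpha) for j in range(X.shape[1])
    ]
    return pd.Series(scores, index=matrix.values.columns, name="es")


def score_collection(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: str = "none",
) -> ScoreMatrix:
    """Score every set of a collection; sets with no measured genes are
    skipped with a warning.

    ``normalize='minmax'`` divides the whole score table by its range
    (max - min over all signatures and samples in this run), the usual
    cross-cohort scale contract. Within-cohort correlations and rank splits
    are invariant to it.
    """
    if normalize not in ("none", "minmax"):
        raise ValueError(f"unknown normalization {normalize!r}")
    rows = {}
    for s in collection:
        try:
            rows[s.name] = ssgsea_score(matrix, s.genes, alpha=alpha)
        except ValueError as exc:
            if "no overlap" in str(exc):
                warnings.warn(f"gene set {s.name!r} skipped: {exc}", stacklevel=2)
                continue
            raise
    if not rows:
        raise ValueError("every gene set was skipped (no overlap with matrix)")
    scores = pd.DataFrame(rows).T
    normalized = False
    if normalize == "minmax":
        rng = scores.to_numpy().max() - scores.to_numpy().min()
        if rng > 0:
            scores = scores / rng
        normalized = True
    return ScoreMatrix(scores=scores, alpha=alpha, normalized=normalized)
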