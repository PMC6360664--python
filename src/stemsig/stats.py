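"""Cohort-level statistics: signature correlation structure, gene-overlap
accounting, signature/clinical-feature association and kNN-LOOCV prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CohortClinical, ExpressionMatrix
from .signatures import Dendrogram, hierarchical_cluster
from .ssgsea import ScoreMatrix

__all__ = [
    "correlate_scores",
    "signature_gene_overlap",
    "associate_feature",
    "knn_loocv",
    "AssociationResult",
]


def correlate_scores(
    scores: ScoreMatrix, method: str = "pearson"
) -> tuple[pd.DataFrame, Dendrogram]:
    """Pairwise signature-by-signature correlation over samples, with a
    hierarchical clustering of the signatures at correlation distance.

    Returns (correlation matrix, dendrogram). Symmetric with unit diagonal.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    S = scores.scores
    if S.shape[0] < 2:
        raise ValueError("need >= 2 signatures")
    if S.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    flat = S.index[S.std(axis=1, ddof=0) == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance signature row(s): {flat}")
    corr = S.T.corr(method=method)
    # exact unit diagonal / symmetry regardless of float noise
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr.to_numpy(), 1.0)
    dend = hierarchical_cluster(S, distance="correlation", linkage="average")
    return corr, dend


def signature_gene_overlap(
    sig_a: list[str], sig_b: list[str]
) -> tuple[int, float]:
    """Set intersection size and Jaccard index of two gene lists."""
    if not sig_a or not sig_b:
        raise ValueError("gene lists must be non-empty")
    a, b = set(sig_a), set(sig_b)
    inter = len(a & b)
    return inter, inter / len(a | b)


@dataclass
class AssociationResult:
    feature_name: str
    test_name: str
    statistic: float
    p_value: float
    n: int
    n_missing: int
    group_summaries: pd.DataFrame | None = None


def associate_feature(
    scores: pd.Series,
    clinical: CohortClinical,
    feature: str,
    test: str | None = None,
) -> AssociationResult:
    """Test association between a per-sample score and a clinical feature.

    Dispatch by feature type: 2-level categorical -> Welch t-test;
    >=3-level categorical -> one-way ANOVA; continuous -> Pearson
    correlation test. ``test`` overrides the dispatch
    (``welch_t``/``pooled_t``/``anova``/``kruskal``/``pearson``/``spearman``).
    Samples with a missing feature value are dropped and counted.
    """
    feat = clinical.feature(feature)
    common = scores.index.intersection(feat.index)
    x = scores.loc[common]
    f = feat.loc[common]
    keep = f.notna() & x.notna()
    n_missing = int((~keep).sum())
    x, f = x[keep], f[keep]
    if len(x) < 3:
        raise ValueError(f"fewer than 3 paired observations for {feature!r}")
    ftype = clinical.feature_types.get(feature, "categorical")

    if ftype == "categorical":
        levels = sorted(f.unique().tolist(), key=str)
        if len(levels) < 2:
            raise ValueError(f"feature {feature!r} is constant")
        sizes = f.value_counts()
        small = sizes[sizes < 2].index.tolist()
        if small:
            raise ValueError(f"level(s) with <2 samples for {feature!r}: {small}")
        groups = [x[f == lv].to_numpy() for lv in levels]
        summaries = pd.DataFrame(
            {
                "n": [len(g) for g in groups],
                "mean": [g.mean() for g in groups],
                "median": [float(np.median(g)) for g in groups],
            },
            index=pd.Index(levels, name=feature),
        )
        if test is None:
            test = "welch_t" if len(levels) == 2 else "anova"
        if test in ("welch_t", "pooled_t"):
            if len(levels) != 2:
                raise ValueError("t-test requires exactly 2 levels")
            stat, p = sps.ttest_ind(*groups, equal_var=(test == "pooled_t"))
            name = "two-group location test (Welch t)" if test == "welch_t" else (
                "two-group location test (pooled t)"
            )
        elif test == "anova":
            stat, p = sps.f_oneway(*groups)
            name = "multi-group location test (one-way ANOVA)"
        elif test == "kruskal":
            stat, p = sps.kruskal(*groups)
            name = "multi-group location test (Kruskal-Wallis)"
        else:
            raise ValueError(f"unknown test {test!r} for categorical feature")
        return AssociationResult(feature, name, float(stat), float(p), len(x), n_missing, summaries)

    # continuous
    fv = pd.to_numeric(f)
    if fv.nunique() < 2:
        raise ValueError(f"feature {feature!r} is constant")
    if test in (None, "pearson"):
        r, p = sps.pearsonr(x.to_numpy(dtype=float), fv.to_numpy(dtype=float))
        name = "correlation test (Pearson)"
    elif test == "spearman":
        r, p = sps.spearmanr(x.to_numpy(dtype=float), fv.to_numpy(dtype=float))
        name = "correlation test (Spearman)"
    else:
        raise ValueError(f"unknown test {test!r} for continuous feature")
    return AssociationResult(feature, name, float(r), float(p), len(x), n_missing, None)


def knn_loocv(
    matrix: ExpressionMatrix,
    label_key: str,
    k: int = 3,
    distance: str = "euclidean-zscored",
    genes: list[str] | None = None,
) -> tuple[float, pd.Series]:
    """Leave-one-out k-nearest-neighbor prediction of a two-class label.

    Each sample is predicted from the majority label of its k nearest
    neighbors among the remaining samples. Deterministic tie-breaks:
    equidistant neighbors prefer the smaller sample index; a tied vote falls
    back to the label of the single nearest neighbor. Returns
    (accuracy, per-sample predictions).
    """
    labels = matrix.annotations[label_key]
    classes = labels.unique().tolist()
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, found {len(classes)}")
    n = matrix.n_samples
    if n < 3:
        raise ValueError("need >= 3 samples")
    if k >= n:
        raise ValueError(f"k={k} must be < n={n} (LOOCV training size)")
    X = matrix.values
    if genes is not None:
        X = X.loc[genes]
    A = X.to_numpy(dtype=float).T  # samples x genes
    if distance == "euclidean-zscored":
        sd = A.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        A = (A - A.mean(axis=0)) / sd
        D = np.sqrt(((A[:, None, :] - A[None, :, :]) ** 2).sum(axis=2))
    elif distance == "correlation":
        C = np.corrcoef(A)
        D = 1.0 - C
    else:
        raise ValueError(f"unknown distance {distance!r}")

    y = labels.to_numpy()
    preds = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        # sort by (distance, index): equidistant -> smaller index first
        order = sorted(others, key=lambda j: (D[i, j], j))
        nearest = order[:k]
        votes = pd.Series([y[j] for j in nearest]).value_counts()
        if len(votes) > 1 and votes.iloc[0] == votes.iloc[1]:
            preds.append(y[order[0]])  # vote tie -> single nearest neighbor
        else:
            preds.append(votes.index[0])
    preds = pd.Series(preds, index=matrix.values.columns, name="predicted")
    accuracy = float((preds.to_numpy() == y).mean())
    return accuracy, preds
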