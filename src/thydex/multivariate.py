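"""PCA, most-variable-feature selection, and hierarchical clustering.

PCA treats samples as observations and features as variables, centers and
(by default) scales each variable to unit variance, and extracts components
by singular value decomposition of the standardized observation matrix --
numerically stabler than eigendecomposition of the covariance.  Signs are
fixed deterministically: each loading vector's largest-magnitude entry is
made positive.

Hierarchical clustering uses complete-linkage agglomeration over Euclidean
distances (the only options anchored to the analysis this package
reproduces; other linkages are accepted but untested).  Rows can be scaled
to mean 0 / sd 1 first, as heatmap drawing conventionally does.  Leaf
orders are made reproducible and interpretable by optimal leaf ordering
(minimizing the sum of adjacent leaf distances subject to the tree), the
counterpart of the weighted-mean dendrogram reordering heatmap functions
apply.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger("thydex")


@dataclasses.dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components
    variance_explained: np.ndarray  # per-component fraction
    n_dropped_features: int


@dataclasses.dataclass
class Dendrogram:
    linkage: np.ndarray          # scipy merge history (pairs + heights)
    leaf_order: list[str]        # item labels in display order
    labels: list[str]            # clustered item labels, input order


def pca(matrix: ExpressionMatrix, center: bool = True, scale: bool = True,
        n_components: int | None = None) -> PCAResult:
    """PCA of sample transcriptomes (observations = samples, variables = features)."""
    X = matrix.values.to_numpy(dtype=float).T  # samples x features
    n_obs, n_feat = X.shape
    if n_obs < 2:
        raise ValidationError("PCA requires at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("pca: dropped %d zero-variance features", n_dropped)
    if keep.sum() == 0:
        raise ValidationError("all features have zero variance")
    X = X[:, keep]
    feature_ids = matrix.values.index[keep]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / sd[keep]

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = n_components or min(n_obs - 1 if center else n_obs, X.shape[1])
    k = min(k, S.size)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]

    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0

    scores = U * S
    total_var = (X ** 2).sum()
    var_explained = S ** 2 / total_var if total_var > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.columns, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=feature_ids, columns=comp_names),
        variance_explained=var_explained,
        n_dropped_features=n_dropped,
    )


def select_most_variable(matrix: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k features with the largest across-sample variance.

    Original feature order is preserved within the selection; exact variance
    ties break lexicographically by feature id.  ``k`` beyond the feature
    count returns the full matrix with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    v = matrix.values
    if k >= v.shape[0]:
        if k > v.shape[0]:
            logger.warning("select_most_variable: k=%d exceeds %d features; "
                           "returning full matrix", k, v.shape[0])
        return ExpressionMatrix(v.copy(), level=matrix.level)
    variances = v.var(axis=1, ddof=1)
    ranking = pd.DataFrame({"var": variances, "fid": v.index.astype(str)})
    ranking = ranking.sort_values(["var", "fid"], ascending=[False, True],
                                  kind="mergesort")
    chosen = set(ranking.index[:k])
    keep = [f for f in v.index if f in chosen]
    return ExpressionMatrix(v.loc[keep].copy(), level=matrix.level)


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    row_scale: bool = False,
    method: str = "complete",
    metric: str = "euclidean",
    optimal_order: bool = True,
) -> Dendrogram:
    """Agglomerative clustering of samples (columns) or features (rows).

    With ``row_scale`` every feature row is transformed to mean 0 / sd 1
    before distances (zero-sd rows dropped, count logged), mirroring
    row-scaled heatmaps.
    """
    if axis not in ("samples", "features"):
        raise ValueError(f"unknown axis {axis!r}")
    v = matrix.values
    if row_scale:
        sd = v.std(axis=1, ddof=1)
        keep = sd > 0
        if (~keep).any():
            logger.info("hierarchical_cluster: dropped %d zero-sd rows",
                        int((~keep).sum()))
        v = v.loc[keep].sub(v.loc[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    data = v.to_numpy(dtype=float).T if axis == "samples" else v.to_numpy(dtype=float)
    labels = list(v.columns) if axis == "samples" else list(v.index)
    if data.shape[0] < 2:
        raise ValidationError("clustering requires at least 2 items")
    dist = pdist(data, metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    if optimal_order:
        Z = hierarchy.optimal_leaf_ordering(Z, dist)
    order = hierarchy.leaves_list(Z)
    return Dendrogram(linkage=Z, leaf_order=[labels[i] for i in order], labels=labels)
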