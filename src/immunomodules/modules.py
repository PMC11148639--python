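"""Immune-module discovery.

Features are correlated pairwise with Spearman's rank coefficient, the
matrix is mapped to the dissimilarity d_ij = 1 - rho_ij^4 (sign-free, so
anticorrelated features co-cluster, and moderate correlations are pushed
toward distance 1), Ward agglomeration is run on those dissimilarities, and
the tree is cut at the cluster count maximizing the mean silhouette. Each
module is then summarized per subject by the first principal component of
its Z-scored member features.

The Ward step operates on the given dissimilarities directly via the
Lance-Williams update ("Ward on dissimilarities"); the custom distance is
not embedded in a Euclidean space first.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .containers import (
    CorrelationMatrix,
    DistanceMatrix,
    FeatureTable,
    ModuleAssignment,
    ModuleScores,
)

DEFAULT_K_MAX = 100


def _values(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    return table.values if isinstance(table, FeatureTable) else table


def spearman_matrix(table: FeatureTable | pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman correlation of all features.

    Ranks use mid-rank averaging for ties. Constant columns have no defined
    rank correlation; their coefficients are set to 0 (diagonal 1) and the
    features are flagged.
    """
    values = _values(table)
    if values.shape[0] < 3:
        raise ValueError("at least 3 subjects are required for rank correlation")
    if values.isna().any().any():
        raise ValueError("feature table must be fully imputed")

    constant = list(values.columns[values.nunique() <= 1])
    with warnings.catch_warnings():
        # constant columns have no defined rank correlation; they are
        # zeroed below, so scipy's warning is redundant
        warnings.simplefilter("ignore")
        if values.shape[1] == 1:
            rho = np.ones((1, 1))
        elif values.shape[1] == 2:
            r = stats.spearmanr(values.iloc[:, 0], values.iloc[:, 1]).statistic
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = stats.spearmanr(values.to_numpy()).statistic
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    frame = pd.DataFrame(rho, index=values.columns, columns=values.columns)
    return CorrelationMatrix(rho=frame, constant_features=constant)


def correlation_to_distance(corr: CorrelationMatrix) -> DistanceMatrix:
    """Map correlations to dissimilarities d = 1 - rho^4."""
    rho = corr.rho.to_numpy()
    if np.max(np.abs(rho)) > 1 + 1e-10:
        raise ValueError("correlations outside [-1, 1]")
    d = 1.0 - np.clip(rho, -1.0, 1.0) ** 4
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=pd.DataFrame(d, index=corr.rho.index, columns=corr.rho.columns))


def cluster_modules(
    dist: DistanceMatrix,
    k_range: range | None = None,
) -> ModuleAssignment:
    """Ward-cluster features on the module distance; pick k by silhouette.

    The linkage tree is cut at every k in ``k_range`` (default
    2..min(n_features - 1, 100)); the mean silhouette on the same distance
    matrix is recorded per k, with singleton clusters contributing 0. The
    selected k maximizes mean silhouette, ties broken toward smaller k.
    """
    d = dist.d.to_numpy()
    n = d.shape[0]
    if n < 3:
        raise ValueError("at least 3 features are required for clustering")
    if np.allclose(d, 0.0):
        raise ValueError("degenerate distance matrix: all distances zero")
    if k_range is None:
        k_range = range(2, min(n - 1, DEFAULT_K_MAX) + 1)
    if k_range.start < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")

    condensed = squareform(d, checks=False)
    link = linkage(condensed, method="ward")

    silhouette_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    best_k, best_sil = None, -np.inf
    for k in k_range:
        labels = fcluster(link, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        if len(np.unique(labels)) < 2:
            # tree could not be cut into k distinct groups; silhouette undefined
            silhouette_by_k[k] = float("nan")
            continue
        sil = float(silhouette_score(d, labels, metric="precomputed"))
        silhouette_by_k[k] = sil
        if sil > best_sil + 1e-12:  # strict: ties keep the smaller k
            best_k, best_sil = k, sil
    if best_k is None:
        raise ValueError("no valid clustering found over k_range")

    assignment = pd.Series(labels_by_k[best_k], index=dist.d.index, name="module")
    return ModuleAssignment(
        module_of_feature=assignment,
        k_selected=best_k,
        silhouette_by_k=silhouette_by_k,
        linkage=link,
    )


def _zscore(values: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Z-scores with sample SD; constant columns map to 0."""
    sd = values.std(ddof=1)
    z = (values - values.mean()) / sd.replace(0.0, np.nan)
    return z.fillna(0.0)


def summarize_modules(
    table: FeatureTable | pd.DataFrame,
    assignment: ModuleAssignment,
) -> ModuleScores:
    """PC1 summary of each module's Z-scored member features.

    The PC1 sign is oriented so the score correlates non-negatively with
    the mean member Z-score (falling back to a non-negative loading sum when
    that mean is flat), making the summaries deterministic. Variance
    explained is PC1's share of the total variance of the Z-scored block.
    """
    values = _values(table)
    if values.shape[0] < 2:
        raise ValueError("at least 2 subjects are required")
    missing = assignment.module_of_feature.index.difference(values.columns)
    if len(missing):
        raise ValueError(f"assigned features absent from table: {list(missing)}")

    scores = {}
    loadings: dict[int, pd.Series] = {}
    var_explained: dict[int, float] = {}
    orientation: dict[int, int] = {}
    for module_id in assignment.module_ids:
        members = assignment.members(module_id)
        z = _zscore(values[members])
        if (z.to_numpy() == 0).all():
            raise ValueError(f"module {module_id} has no non-constant features")
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        pc1 = u[:, 0] * s[0]
        load = vt[0]
        mean_z = z.mean(axis=1).to_numpy()
        align = float(pc1 @ mean_z)
        if align == 0.0:
            align = float(load.sum())
        sign = 1 if align >= 0 else -1
        scores[module_id] = pc1 * sign
        loadings[module_id] = pd.Series(load * sign, index=members)
        total_var = float(np.sum(s**2))
        var_explained[module_id] = float(s[0] ** 2 / total_var)
        orientation[module_id] = sign

    score_frame = pd.DataFrame(scores, index=values.index)
    score_frame.columns.name = "module"
    return ModuleScores(
        scores=score_frame,
        loadings=loadings,
        variance_explained=var_explained,
        orientation=orientation,
    )
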