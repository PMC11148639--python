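"""Companion differential statistics.

Distribution comparisons use the Wilcoxon rank-sum test (unpaired) or
Wilcoxon signed-rank test (paired), count data use Fisher's exact test,
and p-values are Benjamini-Hochberg corrected. A feature is called
significant when q < 0.1, or when p < 0.05 and the absolute standardized
effect size exceeds 1. The module also provides Z-score stratification
(column-wise Z-scores with Ward clustering of subjects) and per-feature
Mahalanobis outlier attribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable

Q_THRESHOLD = 0.1
P_THRESHOLD = 0.05
ES_THRESHOLD = 1.0
Z_CHANGE_THRESHOLD = 0.5
MAHALANOBIS_DELTA = 0.3

EXACT_MAX_N = 20  # exact Wilcoxon p-values up to this combined sample size


def bh_adjust(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def significance_rule(
    p: np.ndarray,
    q: np.ndarray,
    es: np.ndarray,
    q_threshold: float = Q_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    es_threshold: float = ES_THRESHOLD,
) -> np.ndarray:
    """q < 0.1, or (p < 0.05 and |ES| > 1)."""
    return (q < q_threshold) | ((p < p_threshold) & (np.abs(es) > es_threshold))


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact for small tie-free samples."""
    combined = np.concatenate([a, b])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (not ties and len(combined) <= EXACT_MAX_N) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def _signedrank_p(diff: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p on paired differences."""
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        return 1.0
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (not ties and len(nonzero) <= EXACT_MAX_N) else "approx"
    return float(stats.wilcoxon(nonzero, alternative="two-sided", method=method).pvalue)


def differential_distribution(
    table: FeatureTable | pd.DataFrame,
    groups: pd.Series,
    paired: bool = False,
    q_threshold: float = Q_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    es_threshold: float = ES_THRESHOLD,
) -> pd.DataFrame:
    """Per-feature two-group distribution comparison.

    Unpaired: Wilcoxon rank-sum with Cohen's d (pooled-SD standardized mean
    difference). Paired: Wilcoxon signed-rank on subject-matched
    differences, with ES = mean difference / SD of differences; ``groups``
    then distinguishes the two conditions of the same subjects, matched by
    position. Constant features get p = 1, ES = 0 and a flag. BH correction
    runs over all tested features.
    """
    values = table.values if isinstance(table, FeatureTable) else table
    g = groups.reindex(values.index) if isinstance(groups, pd.Series) else pd.Series(
        np.asarray(groups), index=values.index
    )
    levels = sorted(pd.unique(g.dropna()))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    mask_a, mask_b = (g == levels[0]).to_numpy(), (g == levels[1]).to_numpy()
    if paired and mask_a.sum() != mask_b.sum():
        raise ValueError("paired comparison requires matched sample counts")
    if min(mask_a.sum(), mask_b.sum()) < 2:
        raise ValueError("need at least 2 samples per group")

    rows = []
    for feature in values.columns:
        x = values[feature].to_numpy(dtype=float)
        a, b = x[mask_a], x[mask_b]
        constant = len(np.unique(np.concatenate([a, b]))) <= 1
        if constant:
            p, es = 1.0, 0.0
        elif paired:
            diff = a - b
            p = _signedrank_p(diff)
            sd = np.std(diff, ddof=1)
            es = float(diff.mean() / sd) if sd > 0 else 0.0
        else:
            p = _ranksum_p(a, b)
            es = _cohens_d(a, b)
        rows.append(
            {
                "feature": feature,
                "test": "signed-rank" if paired else "rank-sum",
                "p": p,
                "effect_size": es,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "constant": constant,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = significance_rule(
        out["p"].to_numpy(), out["q"].to_numpy(), out["effect_size"].to_numpy(),
        q_threshold, p_threshold, es_threshold,
    )
    return out


def differential_counts(
    tables: Sequence[np.ndarray] | dict[str, np.ndarray],
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Two-sided Fisher's exact test per 2x2 count table, BH over units."""
    if isinstance(tables, dict):
        names, mats = list(tables), list(tables.values())
    else:
        mats = list(tables)
        names = list(range(len(mats)))
    pvals = []
    for name, mat in zip(names, mats):
        arr = np.asarray(mat)
        if arr.shape != (2, 2):
            raise ValueError(f"unit {name!r}: expected a 2x2 table")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"unit {name!r}: cells must be non-negative integers")
        if arr.sum() == 0:
            raise ValueError(f"unit {name!r}: empty table")
        pvals.append(stats.fisher_exact(arr, alternative="two-sided").pvalue)
    q = bh_adjust(pvals)
    return pd.DataFrame(
        {"test": "fisher", "p": pvals, "q": q, "significant": q < q_threshold},
        index=pd.Index(names, name="unit"),
    )


def zscore(values: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Z-scores (sample SD); constant columns map to 0."""
    sd = values.std(ddof=1)
    return ((values - values.mean()) / sd.replace(0.0, np.nan)).fillna(0.0)


@dataclass
class ZMatrix:
    """Z-scored subjects x features matrix with subject dendrogram order."""

    z: pd.DataFrame
    subject_order: list
    group_mean_z: pd.DataFrame  # groups x features
    linkage: np.ndarray | None = None


def zscore_stratify(
    table: FeatureTable | pd.DataFrame,
    features: Sequence[str],
    labels: pd.Series,
) -> ZMatrix:
    """Z-score selected features and hierarchically order subjects.

    Subjects are Ward-clustered on the Euclidean distance between their
    Z-score rows; the dendrogram leaf order and the per-group mean Z per
    feature are returned for heatmap stratification.
    """
    values = table.values if isinstance(table, FeatureTable) else table
    if len(features) == 0:
        raise ValueError("empty feature list")
    missing = [f for f in features if f not in values.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")

    z = zscore(values[list(features)])
    link = linkage(z.to_numpy(), method="ward") if len(z) > 1 else None
    order = list(z.index[leaves_list(link)]) if link is not None else list(z.index)
    g = labels.reindex(z.index)
    group_mean = z.groupby(g).mean()
    return ZMatrix(z=z, subject_order=order, group_mean_z=group_mean, linkage=link)


def flag_substantial_change(
    mean_z_before: pd.Series,
    mean_z_after: pd.Series,
    threshold: float = Z_CHANGE_THRESHOLD,
) -> pd.DataFrame:
    """Flag features whose mean Z-score moves by more than the threshold.

    A substantial change between timepoints is |mean Z after - mean Z
    before| > 0.5 by default.
    """
    diff = mean_z_after - mean_z_before
    return pd.DataFrame(
        {"mean_z_difference": diff, "substantial": diff.abs() > threshold}
    )


def mahalanobis_attribution(
    table: FeatureTable | pd.DataFrame,
    outlier: object,
    group_a: Sequence,
    group_b: Sequence,
    threshold: float = MAHALANOBIS_DELTA,
) -> pd.DataFrame:
    """Attribute an outlying subject's resemblance feature by feature.

    For each feature, the univariate Mahalanobis distance of the outlier to
    each group is d_G = |x - mean_G| / sd_G (outlier excluded from both
    groups). Delta = d_A - d_B; features with Delta above the threshold
    mark where the outlier sits closer to group B than to its nominal
    group A. Zero-SD features are skipped and flagged.
    """
    values = table.values if isinstance(table, FeatureTable) else table
    group_a = [s for s in group_a if s != outlier]
    group_b = [s for s in group_b if s != outlier]
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 subjects besides the outlier")
    if outlier not in values.index:
        raise ValueError(f"outlier {outlier!r} absent from table")

    x = values.loc[outlier]
    a, b = values.loc[group_a], values.loc[group_b]
    sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
    d_a = (x - a.mean()).abs() / sd_a.replace(0.0, np.nan)
    d_b = (x - b.mean()).abs() / sd_b.replace(0.0, np.nan)
    delta = d_a - d_b
    skipped = d_a.isna() | d_b.isna()
    return pd.DataFrame(
        {
            "d_group_a": d_a,
            "d_group_b": d_b,
            "delta": delta,
            "attributed": (delta > threshold).fillna(False) & ~skipped,
            "skipped_zero_sd": skipped,
        }
    )
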