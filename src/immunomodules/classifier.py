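"""Random-forest patient stratification with seed-stability selection.

Two patient groups (e.g. responders vs non-responders) are classified from
module scores. Hyperparameters are tuned by minimizing out-of-bag (OOB)
error over a small grid; the tuned model is rerun across ten random seeds;
each seed's top-ten features by Gini importance are weighted by rank
(weight 11 - rank) and summed into a consensus ranking; the seed whose
top-ten list overlaps that consensus most is chosen as representative, and
modules whose representative-seed Gini importance exceeds a threshold are
selected for downstream analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .containers import FeatureTable, ModuleScores
from .modules import cluster_modules, correlation_to_distance, spearman_matrix, summarize_modules

DEFAULT_N_TREES = 500
DEFAULT_SEEDS = tuple(range(10))
TOP_K = 10


@dataclass
class TunedConfig:
    """Outcome of the OOB-error grid search."""

    grid: list[dict]
    oob_errors: list[float]
    max_features: int
    min_samples_leaf: int
    n_trees: int
    oob_error: float


@dataclass
class ClassifierResult:
    """Ten-seed stability run: per-seed errors and importances, consensus."""

    seeds: list[int]
    oob_error_by_seed: dict[int, float]
    gini_by_seed: pd.DataFrame  # seeds x features
    top_features_by_seed: dict[int, list[str]]
    consensus: pd.Series  # feature -> summed rank weight
    representative_seed: int
    gini_importance: pd.Series  # representative seed's Gini vector
    imbalance_flag: bool = False
    selected_modules: list[str] = field(default_factory=list)
    threshold: float | None = None


def _scores_frame(scores: ModuleScores | pd.DataFrame) -> pd.DataFrame:
    frame = scores.scores if isinstance(scores, ModuleScores) else scores
    if frame.isna().any().any():
        raise ValueError("missing values in module scores")
    return frame


def _check_labels(labels: pd.Series, index: pd.Index) -> np.ndarray:
    y = np.asarray(labels.reindex(index) if isinstance(labels, pd.Series) else labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got classes {classes}")
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    return y


def default_grid(n_features: int, n_trees: int = DEFAULT_N_TREES) -> list[dict]:
    """Small OOB-drivable grid: mtry around sqrt(p), three leaf sizes."""
    base = math.ceil(math.sqrt(n_features))
    mtry = sorted({max(1, min(n_features, round(base * f))) for f in (0.5, 1, 2)})
    return [
        {"max_features": m, "min_samples_leaf": leaf, "n_trees": n_trees}
        for m in mtry
        for leaf in (1, 3, 5)
    ]


def _fit_forest(
    x: np.ndarray, y: np.ndarray, max_features: int, min_samples_leaf: int,
    n_trees: int, seed: int,
) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        min_samples_leaf=min_samples_leaf,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # tiny cohorts can leave a sample in every bag; sklearn warns
        warnings.simplefilter("ignore")
        forest.fit(x, y)
    return forest


def tune_forest(
    scores: ModuleScores | pd.DataFrame,
    labels: pd.Series,
    grid: list[dict] | None = None,
    tuning_seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> TunedConfig:
    """Select forest hyperparameters by minimizing OOB error.

    Each grid point is fit once with a fixed tuning seed. Ties are broken
    toward smaller ``max_features``, then smaller ``min_samples_leaf``.
    """
    frame = _scores_frame(scores)
    y = _check_labels(labels, frame.index)
    x = frame.to_numpy()
    if grid is None:
        grid = default_grid(frame.shape[1], n_trees=n_trees)

    ordered = sorted(grid, key=lambda g: (g["max_features"], g["min_samples_leaf"]))
    errors = []
    best = None
    for point in ordered:
        forest = _fit_forest(
            x, y, point["max_features"], point["min_samples_leaf"],
            point.get("n_trees", n_trees), tuning_seed,
        )
        err = 1.0 - float(forest.oob_score_)
        errors.append(err)
        if best is None or err < best[1] - 1e-12:
            best = (point, err)
    point, err = best
    return TunedConfig(
        grid=ordered,
        oob_errors=errors,
        max_features=point["max_features"],
        min_samples_leaf=point["min_samples_leaf"],
        n_trees=point.get("n_trees", n_trees),
        oob_error=err,
    )


def _rank_weights(gini: pd.Series, top_k: int = TOP_K) -> tuple[list[str], pd.Series]:
    """Top-k features by Gini (stable order) and their weights 11 - rank."""
    order = gini.sort_values(ascending=False, kind="stable").index
    top = list(order[: min(top_k, len(order))])
    weights = pd.Series(
        [TOP_K + 1 - (i + 1) for i in range(len(top))], index=top, dtype=float
    )
    return top, weights


def consensus_from_gini(
    gini_by_seed: Mapping[int, pd.Series],
    top_k: int = TOP_K,
) -> tuple[pd.Series, int, dict[int, list[str]]]:
    """Rank-weighted consensus over per-seed Gini vectors.

    Each seed's top-k features receive weight (k+1) - rank; weights are
    summed across seeds. The representative seed maximizes the total
    consensus weight of its own top-k list, ties going to the lowest seed
    value. Returns (consensus, representative seed, per-seed top lists).
    """
    if len(gini_by_seed) == 0:
        raise ValueError("empty seed list")
    consensus: pd.Series | None = None
    tops: dict[int, list[str]] = {}
    for seed, gini in gini_by_seed.items():
        top, weights = _rank_weights(gini, top_k)
        tops[seed] = top
        consensus = weights if consensus is None else consensus.add(weights, fill_value=0.0)
    overlap = {seed: float(consensus.reindex(top).fillna(0.0).sum())
               for seed, top in tops.items()}
    best = max(overlap.values())
    representative = min(s for s in overlap if overlap[s] >= best - 1e-12)
    return consensus, representative, tops


def stability_select(
    config: TunedConfig,
    scores: ModuleScores | pd.DataFrame,
    labels: pd.Series,
    seeds: Sequence[int] = DEFAULT_SEEDS,
) -> ClassifierResult:
    """Rerun the tuned forest across seeds and pick the representative one.

    Per seed, features are ranked by Gini importance and the top ten get
    rank weights 10, 9, ..., 1; weights are summed across seeds into a
    consensus score per feature. The representative seed is the one whose
    top-ten list has the greatest total consensus score (ties go to the
    lowest seed value); its Gini vector is reported for module selection.
    """
    if len(seeds) == 0:
        raise ValueError("empty seed list")
    frame = _scores_frame(scores)
    y = _check_labels(labels, frame.index)
    x = frame.to_numpy()
    _, counts = np.unique(y, return_counts=True)
    imbalance = counts.max() / counts.min() > 2

    gini_rows = {}
    oob = {}
    for seed in seeds:
        forest = _fit_forest(
            x, y, config.max_features, config.min_samples_leaf, config.n_trees, seed
        )
        gini_rows[seed] = pd.Series(forest.feature_importances_, index=frame.columns)
        oob[seed] = 1.0 - float(forest.oob_score_)

    consensus, representative, tops = consensus_from_gini(gini_rows)

    return ClassifierResult(
        seeds=list(seeds),
        oob_error_by_seed=oob,
        gini_by_seed=pd.DataFrame(gini_rows).T,
        top_features_by_seed=tops,
        consensus=consensus.sort_values(ascending=False, kind="stable"),
        representative_seed=representative,
        gini_importance=gini_rows[representative],
        imbalance_flag=bool(imbalance),
    )


def select_modules(
    result: ClassifierResult,
    threshold: float | str = "auto",
) -> list[str]:
    """Modules whose representative-seed Gini exceeds the threshold.

    ``threshold="auto"`` places the cutoff at the midpoint of the largest
    gap in the descending sorted Gini sequence (the knee). The threshold
    actually used is recorded on the result.
    """
    gini = result.gini_importance.sort_values(ascending=False, kind="stable")
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if (gini == 0).all():
            raise ValueError("all importances are zero; no automatic threshold")
        if len(gini) < 2:
            raise ValueError("automatic threshold needs at least 2 features")
        gaps = gini.to_numpy()[:-1] - gini.to_numpy()[1:]
        i = int(np.argmax(gaps))
        cutoff = float((gini.iloc[i] + gini.iloc[i + 1]) / 2.0)
    else:
        cutoff = float(threshold)
    selected = list(gini.index[gini > cutoff])
    result.selected_modules = selected
    result.threshold = cutoff
    return selected


def run_classification(
    table: FeatureTable,
    labels: pd.Series,
    seeds: Sequence[int] = DEFAULT_SEEDS,
    k_range: range | None = None,
    gini_threshold: float | str = "auto",
    tuning_seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple["ModuleScores", TunedConfig, ClassifierResult]:
    """Full stage: modules from the table, then tuned + stabilized forest."""
    corr = spearman_matrix(table)
    dist = correlation_to_distance(corr)
    assignment = cluster_modules(dist, k_range=k_range)
    module_scores = summarize_modules(table, assignment)
    named = module_scores.scores.rename(columns=lambda m: f"module_{m}")
    config = tune_forest(named, labels, tuning_seed=tuning_seed, n_trees=n_trees)
    result = stability_select(config, named, labels, seeds=seeds)
    select_modules(result, threshold=gini_threshold)
    return module_scores, config, result


def compare_timepoints(
    tables: Mapping[str, FeatureTable],
    labels: pd.Series,
    k_range: range | None = None,
    tuning_seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> pd.DataFrame:
    """Tuned OOB error of the module + classifier pipeline per timepoint.

    Each timepoint's table goes through module discovery, PC1 summarization
    and the OOB grid search; the tuned OOB errors are tabulated and the
    minimum flagged (ties resolved by input order). Analyses then focus on
    the timepoint parameter with the lowest OOB error.
    """
    rows = []
    for name, table in tables.items():
        corr = spearman_matrix(table)
        assignment = cluster_modules(correlation_to_distance(corr), k_range=k_range)
        module_scores = summarize_modules(table, assignment)
        named = module_scores.scores.rename(columns=lambda m: f"module_{m}")
        config = tune_forest(named, labels, tuning_seed=tuning_seed, n_trees=n_trees)
        rows.append({"timepoint": name, "oob_error": config.oob_error})
    out = pd.DataFrame(rows).set_index("timepoint")
    out["is_minimum"] = False
    out.loc[out["oob_error"].idxmin(), "is_minimum"] = True
    return out
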