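"""End-to-end pipeline runs with one config and one reproducibility manifest.

A run executes simulate (or load) -> impute -> module discovery -> PC1
summarization -> classifier tuning + seed stability -> differential
statistics, writing every stage's outputs as TSV plus a JSON manifest
(config hash, seeds, thresholds, package version). Re-running with the same
manifest reproduces every deterministic output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .assembly import impute_column_mean
from .classifier import (
    DEFAULT_N_TREES,
    select_modules,
    stability_select,
    tune_forest,
)
from .containers import FeatureTable
from .modules import (
    cluster_modules,
    correlation_to_distance,
    spearman_matrix,
    summarize_modules,
)
from .stats import differential_distribution
from .synthetic import CohortSpec, generate_feature_cohort

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "q": 0.1,
    "p": 0.05,
    "effect_size": 1.0,
    "gini": "auto",
    "mahalanobis_delta": 0.3,
    "z_difference": 0.5,
    "neoplastic_min_count": 75,
    "min_cells": 15,
    "clone_q": 0.05,
}


def config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path, **kwargs: Any) -> None:
    frame.to_csv(path, sep="\t", **kwargs)


def run(config: Mapping[str, Any], seed: int, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline described by ``config`` under ``seed``.

    ``config`` holds a ``cohort`` section (simulation spec; any
    ``CohortSpec`` field) or a ``features``/``labels`` pair of TSV paths,
    an optional ``classifier`` section (seeds, n_trees, k_min/k_max), and a
    ``thresholds`` section defaulting to the pipeline's standard cutoffs.
    Returns the manifest dictionary; all stage outputs land in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    clf_cfg = dict(config.get("classifier", {}))
    n_seeds = int(clf_cfg.get("seeds", 10))
    n_trees = int(clf_cfg.get("n_trees", DEFAULT_N_TREES))

    if "cohort" in config:
        cohort_cfg = dict(config["cohort"])
        disc = {
            int(k): float(v)
            for k, v in dict(cohort_cfg.pop("discriminative_modules", {})).items()
        }
        spec = CohortSpec(**cohort_cfg, discriminative_modules=disc, seed=seed)
        table, truth = generate_feature_cohort(spec)
        labels = truth.group_label
        _write_tsv(table.values, out / "features.tsv", index_label="subject")
        truth_payload = {
            "module_of_feature": truth.module_of_feature.to_dict(),
            "discriminative_module_ids": sorted(truth.discriminative_module_ids),
            "group_label": {str(k): int(v) for k, v in truth.group_label.items()},
        }
        (out / "ground_truth.json").write_text(json.dumps(truth_payload, indent=2))
    elif "features" in config:
        values = pd.read_csv(config["features"], sep="\t", index_col=0)
        table = FeatureTable(values=values)
        label_frame = pd.read_csv(config["labels"], sep="\t", index_col=0)
        labels = label_frame.iloc[:, 0]
    else:
        raise ValueError("config must provide a 'cohort' spec or 'features'/'labels' paths")
    if labels is None or labels.isna().any():
        raise ValueError("labels missing for classification")

    imputed, mask = impute_column_mean(table.values)
    table = FeatureTable(
        values=imputed,
        timepoint_param=table.timepoint_param,
        provenance=table.provenance,
        imputed=mask,
        constant_features=list(imputed.columns[imputed.nunique() <= 1]),
    )

    corr = spearman_matrix(table)
    dist = correlation_to_distance(corr)
    k_range = None
    if "k_min" in clf_cfg or "k_max" in clf_cfg:
        k_range = range(int(clf_cfg.get("k_min", 2)), int(clf_cfg["k_max"]) + 1)
    assignment = cluster_modules(dist, k_range=k_range)
    scores = summarize_modules(table, assignment)

    _write_tsv(
        assignment.module_of_feature.to_frame("module"),
        out / "module_assignment.tsv", index_label="feature",
    )
    sil = pd.Series(assignment.silhouette_by_k, name="mean_silhouette")
    _write_tsv(sil.to_frame(), out / "silhouette.tsv", index_label="k")
    named_scores = scores.scores.rename(columns=lambda m: f"module_{m}")
    _write_tsv(named_scores, out / "module_scores.tsv", index_label="subject")
    load = pd.concat(
        {f"module_{m}": s for m, s in scores.loadings.items()}, names=["module", "feature"]
    )
    _write_tsv(load.to_frame("loading"), out / "loadings.tsv")

    seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)]
    config_fit = tune_forest(named_scores, labels, tuning_seed=seed % (2**31), n_trees=n_trees)
    result = stability_select(config_fit, named_scores, labels, seeds=seeds)
    selected = select_modules(result, threshold=thresholds["gini"])

    per_seed = pd.DataFrame(
        {
            "oob_error": pd.Series(result.oob_error_by_seed),
        }
    ).join(result.gini_by_seed)
    _write_tsv(per_seed, out / "per_seed.tsv", index_label="seed")
    _write_tsv(result.consensus.to_frame("consensus_weight"), out / "consensus.tsv",
               index_label="feature")
    (out / "selected_modules.json").write_text(
        json.dumps(
            {
                "selected_modules": selected,
                "gini_threshold": result.threshold,
                "representative_seed": result.representative_seed,
                "tuned": {
                    "max_features": config_fit.max_features,
                    "min_samples_leaf": config_fit.min_samples_leaf,
                    "n_trees": config_fit.n_trees,
                    "oob_error": config_fit.oob_error,
                },
            },
            indent=2,
        )
    )

    diff = differential_distribution(
        table, labels,
        q_threshold=thresholds["q"], p_threshold=thresholds["p"],
        es_threshold=thresholds["effect_size"],
    )
    _write_tsv(diff, out / "differential.tsv")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "classifier_seeds": seeds,
        "config_hash": config_hash(config),
        "thresholds": thresholds,
        "k_selected": assignment.k_selected,
        "representative_seed": result.representative_seed,
        "selected_modules": selected,
        "oob_error": config_fit.oob_error,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
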