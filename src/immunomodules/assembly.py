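"""Assembly of the harmonized subjects x features table.

Three omic blocks feed the feature table: serum proteomics (panel values
with limit-of-detection floors and quality warnings), bulk tumor
transcriptomics (log2 expression normalized to housekeeping genes), and
per-sample summary statistics of clustered single-cell data (cluster
abundance, percent-positive activation markers, mean metabolic-marker
expression). Features are compiled per timepoint parameter — baseline (BL),
on-treatment (C2), or the difference delta = C2 - BL — and remaining
missing values are replaced by the column mean, with every imputed cell
recorded in a mask.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureTable, OmicBlock

MIN_CELLS_FOR_STATS = 15


def _timepoint_slice(values: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    """Rows of one timepoint, indexed by subject."""
    if isinstance(values.index, pd.MultiIndex):
        sliced = values.xs(timepoint, level=1)
        sliced.index.name = "subject"
        return sliced
    return values


def align_trial_medians(
    values: pd.DataFrame,
    trial_of_subject: pd.Series,
    baseline_timepoint: str = "BL",
    reference_trial: str | None = None,
) -> pd.DataFrame:
    """Shift each trial's values so baseline medians agree across trials.

    Per analyte, every trial's measurements (all timepoints) are shifted by
    the difference between the reference trial's baseline median and that
    trial's baseline median. The reference defaults to the first trial in
    sorted order. Applying the shift twice equals applying it once.
    """
    trials = sorted(trial_of_subject.unique())
    if len(trials) < 2:
        return values.copy()
    if reference_trial is None:
        reference_trial = trials[0]
    if reference_trial not in trials:
        raise ValueError(f"reference trial {reference_trial!r} not present")

    baseline = _timepoint_slice(values, baseline_timepoint)
    subj_level = (
        values.index.get_level_values(0)
        if isinstance(values.index, pd.MultiIndex)
        else values.index
    )
    trial_rows = trial_of_subject.reindex(subj_level)
    if trial_rows.isna().any():
        raise ValueError("subjects without a trial assignment")

    medians = baseline.groupby(trial_of_subject.reindex(baseline.index)).median()
    shifted = values.copy()
    for trial in trials:
        offset = medians.loc[reference_trial] - medians.loc[trial]
        pos = np.flatnonzero((trial_rows == trial).to_numpy())
        shifted.iloc[pos] = shifted.iloc[pos].add(offset, axis=1)
    return shifted


def preprocess_serum(
    raw: OmicBlock,
    baseline_timepoint: str = "BL",
    reference_trial: str | None = None,
) -> OmicBlock:
    """Apply the serum-panel preprocessing rules.

    Measurements below the analyte's limit of detection are replaced by the
    LOD threshold; quality-warned measurements are replaced by the assay
    median over the non-warned measurements of that analyte; finally every
    analyte is shifted so its baseline medians agree across clinical trials.
    """
    if raw.lod is None:
        raise ValueError("serum block requires per-analyte LOD thresholds")
    missing_lod = raw.values.columns.difference(raw.lod.index)
    if len(missing_lod):
        raise ValueError(f"analytes without an LOD value: {list(missing_lod)}")

    values = raw.values.copy()
    lod = raw.lod.reindex(values.columns)
    below = values.lt(lod, axis=1)
    values = values.mask(below, lod, axis=1)

    if raw.warnings is not None:
        warn = raw.warnings.reindex_like(values).fillna(False).astype(bool)
        if warn.all().any():
            bad = list(values.columns[warn.all()])
            raise ValueError(f"analytes with all measurements flagged: {bad}")
        medians = values.mask(warn).median()
        values = values.mask(warn, medians, axis=1)

    if raw.trial_of_subject is not None:
        values = align_trial_medians(
            values, raw.trial_of_subject, baseline_timepoint, reference_trial
        )
    return OmicBlock(
        values=values,
        omic="serum",
        meta=raw.meta,
        trial_of_subject=raw.trial_of_subject,
        lod=raw.lod,
    )


def preprocess_transcriptomics(
    raw: OmicBlock,
    housekeeping_genes: Sequence[str],
    baseline_timepoint: str = "BL",
    reference_trial: str | None = None,
    pseudocount: float = 1.0,
) -> OmicBlock:
    """Log2-transform counts and normalize to housekeeping genes.

    Counts become log2(count + pseudocount); each sample is then shifted by
    the arithmetic mean of its log2 housekeeping values (geometric-mean
    scaling on the count scale). Genes are finally aligned to a common
    baseline median across trials, as for serum.
    """
    missing = [g for g in housekeeping_genes if g not in raw.values.columns]
    if missing:
        raise ValueError(f"housekeeping genes absent from count table: {missing}")
    if (raw.values < 0).any().any():
        raise ValueError("negative counts")

    logged = np.log2(raw.values + pseudocount)
    hk_mean = logged[list(housekeeping_genes)].mean(axis=1)
    normalized = logged.sub(hk_mean, axis=0)

    if raw.trial_of_subject is not None:
        normalized = align_trial_medians(
            normalized, raw.trial_of_subject, baseline_timepoint, reference_trial
        )
    return OmicBlock(
        values=normalized,
        omic="tumor_rna",
        meta=raw.meta,
        trial_of_subject=raw.trial_of_subject,
    )


def summarize_single_cell(
    cells: Mapping[object, pd.DataFrame],
    activation_markers: Sequence[str],
    metabolic_markers: Sequence[str],
    positivity_thresholds: Mapping[str, float],
    cluster_column: str = "cluster",
    parent_clusters: Sequence[object] | None = None,
    min_cells: int = MIN_CELLS_FOR_STATS,
) -> OmicBlock:
    """Per-sample summary statistics of clustered single-cell data.

    ``cells`` maps sample id to an event table (one row per cell, marker
    columns plus a cluster label column). Emits per cluster: abundance
    (cluster cell count over the parent population's cell count), and — for
    clusters with at least ``min_cells`` cells in a sample — percent
    positive per activation marker and mean expression per metabolic
    marker. Statistics of smaller clusters are emitted as missing so that
    no summary is ever computed from fewer than ``min_cells`` cells.

    ``parent_clusters`` restricts the denominator population (and the
    clusters summarized) to a subset, e.g. non-neoplastic T cells.
    """
    for marker in activation_markers:
        if marker not in positivity_thresholds:
            raise ValueError(f"no positivity threshold for activation marker {marker!r}")

    all_clusters: set[object] = set()
    for sample, table in cells.items():
        if cluster_column not in table.columns:
            raise ValueError(f"sample {sample!r} lacks a {cluster_column!r} column")
        all_clusters.update(table[cluster_column].unique())
    if parent_clusters is not None:
        unknown = set(parent_clusters) - all_clusters
        if unknown:
            raise ValueError(f"unknown parent clusters: {sorted(map(str, unknown))}")
        all_clusters = set(parent_clusters)
    clusters = sorted(all_clusters, key=str)

    rows = {}
    for sample, table in cells.items():
        if parent_clusters is not None:
            table = table[table[cluster_column].isin(parent_clusters)]
        parent_n = len(table)
        feats: dict[str, float] = {}
        for cl in clusters:
            sub = table[table[cluster_column] == cl]
            n = len(sub)
            feats[f"abundance|{cl}"] = n / parent_n if parent_n else np.nan
            big_enough = n >= min_cells
            for marker in activation_markers:
                key = f"pct_pos|{cl}|{marker}"
                feats[key] = (
                    float((sub[marker] > positivity_thresholds[marker]).mean() * 100)
                    if big_enough
                    else np.nan
                )
            for marker in metabolic_markers:
                key = f"mean_expr|{cl}|{marker}"
                feats[key] = float(sub[marker].mean()) if big_enough else np.nan
        rows[sample] = feats

    values = pd.DataFrame.from_dict(rows, orient="index")
    values.index.name = "subject"
    kinds = [c.split("|")[0] for c in values.columns]
    meta = pd.DataFrame(
        {"statistic": ["pct_positive" if k == "pct_pos" else
                       "mean_expression" if k == "mean_expr" else "abundance"
                       for k in kinds]},
        index=values.columns,
    )
    return OmicBlock(values=values, omic="single_cell_summary", meta=meta)


def impute_column_mean(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing entries by the column mean; return (table, mask).

    Imputation leaves each column's mean unchanged. Columns missing for all
    subjects have no defined mean and raise.
    """
    all_missing = values.columns[values.isna().all()]
    if len(all_missing):
        raise ValueError(f"features missing for all subjects: {list(all_missing)}")
    mask = values.isna()
    return values.fillna(values.mean()), mask


_STAT_OF_PREFIX = {"abundance": "abundance", "pct_pos": "pct_positive",
                   "mean_expr": "mean_expression"}


def assemble(blocks: Sequence[OmicBlock], timepoint_param: str = "BL") -> FeatureTable:
    """Compile omic blocks into one imputed FeatureTable.

    For ``delta``, each feature is value(C2) - value(BL) computed before
    imputation, so imputed endpoint values never fabricate a change. Any
    remaining missing entry is replaced by the feature's column mean;
    constant (zero-variance) columns are retained but flagged.
    """
    if not blocks:
        raise ValueError("no omic blocks to assemble")

    pieces = []
    prov_rows = []
    for block in blocks:
        if timepoint_param == "delta":
            if not isinstance(block.values.index, pd.MultiIndex):
                raise ValueError(
                    f"block {block.omic!r} lacks timepoint-indexed rows for delta"
                )
            c2 = _timepoint_slice(block.values, "C2")
            bl = _timepoint_slice(block.values, "BL")
            subjects = c2.index.union(bl.index)
            wide = c2.reindex(subjects) - bl.reindex(subjects)
        else:
            wide = (
                _timepoint_slice(block.values, timepoint_param)
                if isinstance(block.values.index, pd.MultiIndex)
                else block.values
            )
        wide = wide.add_prefix(f"{block.omic}:")
        pieces.append(wide)
        for col, orig in zip(wide.columns, wide.columns.str.split(":", n=1).str[1]):
            stat = "expression"
            if block.omic == "single_cell_summary":
                stat = _STAT_OF_PREFIX.get(orig.split("|")[0], "expression")
            prov_rows.append({"feature": col, "omic": block.omic,
                              "analyte": orig, "statistic": stat})

    merged = pd.concat(pieces, axis=1)
    if merged.columns.duplicated().any():
        raise ValueError("duplicated feature names across blocks")
    values, mask = impute_column_mean(merged)
    constant = list(values.columns[values.nunique() <= 1])
    provenance = pd.DataFrame(prov_rows).set_index("feature")
    provenance["constant"] = provenance.index.isin(constant)
    return FeatureTable(
        values=values,
        timepoint_param=timepoint_param,
        provenance=provenance,
        imputed=mask,
        constant_features=constant,
    )
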