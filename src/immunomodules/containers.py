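"""Shared data containers for the integration pipeline.

All tabular payloads are pandas objects: subjects on rows, analytes/features
on columns. Containers are thin dataclasses that carry provenance and
bookkeeping (imputation masks, silhouette traces, PC1 loadings) alongside
the matrices themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINT_PARAMS = ("BL", "C2", "delta")


@dataclass
class OmicBlock:
    """One omic's subjects x analytes matrix before assembly.

    ``values`` may be indexed by subject alone or by a (subject, timepoint)
    MultiIndex; the latter is required when a delta feature table is
    assembled. ``lod`` (per-analyte limit of detection) and ``warnings``
    (boolean mask of quality-flagged measurements) are only meaningful for
    serum panels.
    """

    values: pd.DataFrame
    omic: str  # serum | tumor_rna | single_cell_summary | synthetic
    meta: pd.DataFrame | None = None  # per-analyte metadata
    trial_of_subject: pd.Series | None = None
    lod: pd.Series | None = None
    warnings: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated analyte columns in OmicBlock")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated (subject, timepoint) rows in OmicBlock")

    def subjects(self) -> pd.Index:
        idx = self.values.index
        if isinstance(idx, pd.MultiIndex):
            return idx.get_level_values(0).unique()
        return idx


@dataclass
class FeatureTable:
    """Harmonized subjects x features matrix for one timepoint parameter.

    ``imputed`` marks every cell that was filled by column-mean imputation;
    ``provenance`` records, per feature, the originating omic, analyte and
    statistic kind. Constant (zero-variance) columns are retained but listed
    in ``constant_features``.
    """

    values: pd.DataFrame
    timepoint_param: str = "BL"
    provenance: pd.DataFrame | None = None
    imputed: pd.DataFrame | None = None
    constant_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.timepoint_param not in TIMEPOINT_PARAMS:
            raise ValueError(
                f"timepoint_param must be one of {TIMEPOINT_PARAMS}, "
                f"got {self.timepoint_param!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def is_imputed(self) -> bool:
        return not self.values.isna().any().any()


@dataclass
class CorrelationMatrix:
    """Features x features Spearman matrix (symmetric, unit diagonal)."""

    rho: pd.DataFrame
    constant_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.rho.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(arr)) > 1 + 1e-10:
            raise ValueError("correlation coefficients must lie in [-1, 1]")


@dataclass
class DistanceMatrix:
    """Feature dissimilarities d_ij = 1 - rho_ij^4.

    The fourth power removes the sign of the correlation (anticorrelated
    features are close) and pushes moderately correlated features apart.
    """

    d: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.d.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        if arr.min() < -1e-10 or arr.max() > 1 + 1e-10:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class ModuleAssignment:
    """Partition of features into immune modules.

    ``silhouette_by_k`` traces the mean silhouette (on the module distance)
    over the searched cluster counts; ``k_selected`` maximizes it, ties
    broken toward the smallest k.
    """

    module_of_feature: pd.Series  # feature -> module id (1..k)
    k_selected: int
    silhouette_by_k: dict[int, float]
    linkage: np.ndarray | None = None

    def members(self, module_id: int) -> list[str]:
        return list(self.module_of_feature.index[self.module_of_feature == module_id])

    @property
    def module_ids(self) -> list[int]:
        return sorted(self.module_of_feature.unique())


@dataclass
class ModuleScores:
    """Per-subject module summaries: PC1 of the Z-scored member features.

    The PC1 sign is oriented so each score correlates non-negatively with
    the mean member Z-score, making scores reproducible across runs.
    """

    scores: pd.DataFrame  # subjects x modules
    loadings: dict[int, pd.Series]
    variance_explained: dict[int, float]
    orientation: dict[int, int]

    def __post_init__(self) -> None:
        for mod, ve in self.variance_explained.items():
            if not (-1e-9 <= ve <= 1 + 1e-9):
                raise ValueError(f"variance explained for module {mod} outside [0, 1]")
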