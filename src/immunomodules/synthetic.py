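"""Synthetic multi-omic cohorts with known ground truth.

Every downstream stage of the pipeline is exercised on cohorts generated
here: feature tables with planted correlated blocks and planted group
effects, single-cell event tables with exact cluster sizes, and TCR
repertoires with an optional dominant (neoplastic-like) clone.

Feature blocks use a latent-factor construction: each feature in module m is

    x = sqrt(rho) * f_m + sqrt(1 - rho) * eps,    f_m, eps ~ N(0, 1)

so any two features of one module have correlation exactly ``rho`` in
expectation and features of different modules are independent. A
discriminative module shifts its latent factor mean by the requested
standardized amount between the two groups. Missingness is injected
completely at random; limit-of-detection censoring replaces the lowest
``lod_rate`` fraction of each feature's values by that feature's censoring
threshold, mimicking assay floors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .tcr import Repertoire

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NOISE_MODULE = -1


@dataclass
class CohortSpec:
    """Parameters of a planted-block feature cohort.

    ``discriminative_modules`` maps 0-based module indices to standardized
    group mean shifts (delta-mu over sigma) applied to the module's latent
    factor.
    """

    n_subjects_per_group: int = 20
    n_modules: int = 8
    features_per_module: int = 6
    within_module_rho: float = 0.8
    n_noise_features: int = 12
    discriminative_modules: dict[int, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    lod_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects_per_group", "n_modules", "features_per_module"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be non-negative")
        if not 0.0 <= self.within_module_rho < 1.0:
            raise ValueError("within_module_rho must lie in [0, 1)")
        for rate in ("missing_rate", "lod_rate"):
            if not 0.0 <= getattr(self, rate) < 1.0:
                raise ValueError(f"{rate} must lie in [0, 1)")
        for idx in self.discriminative_modules:
            if not 0 <= idx < self.n_modules:
                raise ValueError(f"discriminative module index {idx} out of range")

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_subjects_per_group

    @property
    def n_features(self) -> int:
        return self.n_modules * self.features_per_module + self.n_noise_features


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    module_of_feature: pd.Series  # feature -> 0-based module id, noise = -1
    discriminative_module_ids: set[int]
    group_label: pd.Series  # subject -> 0/1
    neoplastic_clone_id: str | None = None
    missing_mask: pd.DataFrame | None = None
    lod_mask: pd.DataFrame | None = None


def generate_feature_cohort(spec: CohortSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate a subjects x features table with planted module structure.

    Returns the (possibly missing-valued) feature table and the ground
    truth needed to score module recovery and classifier power. The same
    spec and seed reproduce the table bit for bit.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_factor, rng_noise, rng_missing = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    n = spec.n_subjects
    subjects = pd.Index([f"S{i:03d}" for i in range(n)], name="subject")
    group = pd.Series(np.repeat([0, 1], spec.n_subjects_per_group), index=subjects)

    factors = rng_factor.standard_normal((n, spec.n_modules))
    for idx, delta in spec.discriminative_modules.items():
        factors[:, idx] += delta * group.to_numpy()

    rho = spec.within_module_rho
    cols: list[np.ndarray] = []
    names: list[str] = []
    membership: list[int] = []
    for m in range(spec.n_modules):
        eps = rng_noise.standard_normal((n, spec.features_per_module))
        block = np.sqrt(rho) * factors[:, [m]] + np.sqrt(1.0 - rho) * eps
        cols.append(block)
        names.extend(f"M{m:02d}_F{j:02d}" for j in range(spec.features_per_module))
        membership.extend([m] * spec.features_per_module)
    if spec.n_noise_features:
        cols.append(rng_noise.standard_normal((n, spec.n_noise_features)))
        names.extend(f"NOISE_{j:02d}" for j in range(spec.n_noise_features))
        membership.extend([NOISE_MODULE] * spec.n_noise_features)

    values = pd.DataFrame(np.hstack(cols), index=subjects, columns=names)

    lod_mask = pd.DataFrame(False, index=subjects, columns=names)
    if spec.lod_rate > 0:
        # left-censor the lowest lod_rate fraction of each feature at the
        # feature's empirical lod_rate-quantile (the "LOD threshold")
        thresholds = values.quantile(spec.lod_rate)
        lod_mask = values.lt(thresholds, axis=1)
        values = values.mask(lod_mask, thresholds, axis=1)

    missing_mask = pd.DataFrame(False, index=subjects, columns=names)
    if spec.missing_rate > 0:
        missing_mask = pd.DataFrame(
            rng_missing.random(values.shape) < spec.missing_rate,
            index=subjects,
            columns=names,
        )
        values = values.mask(missing_mask)

    provenance = pd.DataFrame(
        {
            "omic": "synthetic",
            "analyte": names,
            "statistic": "expression",
            "module_truth": membership,
        },
        index=pd.Index(names, name="feature"),
    )
    table = FeatureTable(values=values, timepoint_param="BL", provenance=provenance)
    truth = GroundTruth(
        module_of_feature=pd.Series(membership, index=names),
        discriminative_module_ids=set(spec.discriminative_modules),
        group_label=group,
        missing_mask=missing_mask,
        lod_mask=lod_mask,
    )
    return table, truth


def planted_assignment(truth: GroundTruth) -> "ModuleAssignment":
    """ModuleAssignment mirroring the planted ground truth.

    Planted module m maps to cluster id m + 1; noise features form one
    extra cluster. Useful for exercising summarization and classification
    independently of module discovery.
    """
    from .containers import ModuleAssignment

    labels = truth.module_of_feature + 1
    noise_id = int(labels.max()) + 1
    labels = labels.where(truth.module_of_feature != NOISE_MODULE, noise_id)
    return ModuleAssignment(
        module_of_feature=labels,
        k_selected=int(labels.nunique()),
        silhouette_by_k={},
    )


def generate_single_cell_fixture(
    n_cells_per_cluster: list[int],
    marker_spec: pd.DataFrame | dict[object, dict[str, float]],
    seed: int = 0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Generate a cell x marker event table with exact cluster sizes.

    ``marker_spec`` gives per-cluster marker means (rows = clusters in the
    same order as ``n_cells_per_cluster``, columns = markers). Intensities
    are Gaussian around the cluster mean with ``noise_sd``.
    """
    if len(n_cells_per_cluster) == 0:
        raise ValueError("at least one cluster is required")
    spec = pd.DataFrame(marker_spec).T if isinstance(marker_spec, dict) else pd.DataFrame(marker_spec)
    if len(spec) != len(n_cells_per_cluster):
        raise ValueError("marker_spec rows must match n_cells_per_cluster")
    if any(c < 0 for c in n_cells_per_cluster):
        raise ValueError("cluster sizes must be non-negative")

    rng = np.random.default_rng(seed)
    frames = []
    for (label, means), n_cells in zip(spec.iterrows(), n_cells_per_cluster):
        block = means.to_numpy()[None, :] + noise_sd * rng.standard_normal(
            (n_cells, spec.shape[1])
        )
        frame = pd.DataFrame(block, columns=spec.columns)
        frame["cluster"] = label
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _random_cdr3(rng: np.random.Generator, length: int = 12) -> str:
    middle = "".join(rng.choice(_AA, size=length - 2))
    return f"C{middle}F"


def generate_repertoire(
    n_clones: int,
    neoplastic_count: int | None = None,
    total_templates: int = 1000,
    seed: int = 0,
) -> Repertoire:
    """Generate a TCRbeta repertoire with a skewed clone-size distribution.

    Clone counts follow a Zipf-like profile (count of the r-th clone
    proportional to 1/r), the shape typical of peripheral repertoires. If
    ``neoplastic_count`` is given, one designated clone receives exactly
    that count, emulating the expanded malignant clone of a leukemic
    sample.
    """
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    if total_templates < n_clones:
        raise ValueError("total_templates must be at least n_clones")
    if neoplastic_count is not None:
        if neoplastic_count <= 0:
            raise ValueError("neoplastic_count must be positive")
        if neoplastic_count > total_templates:
            raise ValueError("neoplastic_count exceeds total_templates")
        if total_templates - neoplastic_count < n_clones - 1:
            raise ValueError("too few templates left for the remaining clones")

    rng = np.random.default_rng(seed)
    counts = np.ones(n_clones, dtype=int)  # every clone observed at least once
    if neoplastic_count is not None:
        counts[0] = neoplastic_count
        free = total_templates - neoplastic_count - (n_clones - 1)
        weights = 1.0 / np.arange(1, n_clones)  # remaining clones only
        idx = slice(1, None)
    else:
        free = total_templates - n_clones
        weights = 1.0 / np.arange(1, n_clones + 1)
        idx = slice(None)
    if free > 0 and len(weights) > 0:
        counts[idx] += rng.multinomial(free, weights / weights.sum())

    clones = pd.DataFrame(
        {
            "v_gene": [f"TRBV{rng.integers(1, 31)}" for _ in range(n_clones)],
            "j_gene": [f"TRBJ{rng.integers(1, 3)}-{rng.integers(1, 8)}" for _ in range(n_clones)],
            "cdr3_aa": [_random_cdr3(rng) for _ in range(n_clones)],
            "templates": counts,
        }
    )
    return Repertoire(clones=clones)
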