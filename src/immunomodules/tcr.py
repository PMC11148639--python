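"""TCR repertoire metrics.

A repertoire is a table of clonal families — clones sharing V gene, J gene
and CDR3 amino-acid sequence — with template counts. This module identifies
the neoplastic (malignant) clone as the single most abundant clone with at
least 75 templates, computes Gini-Simpson diversity and Morisita-Horn
similarity, tests differential clone abundance between two samples with
Fisher's exact test under BH correction, and compiles the union of
"clones of interest".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NEOPLASTIC_MIN_COUNT = 75
ABUNDANT_FRACTION = 1e-4  # 0.01% of templates

CLONE_COLUMNS = ["v_gene", "j_gene", "cdr3_aa"]


def _clone_ids(clones: pd.DataFrame) -> pd.Series:
    return clones[CLONE_COLUMNS].agg("|".join, axis=1)


@dataclass
class Repertoire:
    """Clone count table for one sample.

    Clone identity is the (V gene, J gene, CDR3 amino-acid) triple;
    rows with identical identity are merged on construction. Frequencies
    are template counts over the sample total.
    """

    clones: pd.DataFrame
    sample_id: str | None = None
    neoplastic_clone: str | None = field(default=None)

    def __post_init__(self) -> None:
        missing = [c for c in CLONE_COLUMNS + ["templates"] if c not in self.clones]
        if missing:
            raise ValueError(f"clone table missing columns: {missing}")
        if len(self.clones) == 0:
            raise ValueError("repertoire is empty")
        counts = self.clones["templates"]
        if (counts <= 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("template counts must be positive integers")
        merged = (
            self.clones.groupby(CLONE_COLUMNS, as_index=False, sort=False)["templates"]
            .sum()
        )
        merged.index = pd.Index(_clone_ids(merged), name="clone_id")
        self.clones = merged

    @property
    def total_templates(self) -> int:
        return int(self.clones["templates"].sum())

    @property
    def frequencies(self) -> pd.Series:
        counts = self.clones["templates"]
        return counts / counts.sum()

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "Repertoire":
        table = pd.read_csv(path, sep="\t")
        return cls(clones=table, sample_id=sample_id or Path(path).stem)

    def to_tsv(self, path: str | Path) -> None:
        self.clones.to_csv(path, sep="\t", index=False)


def identify_neoplastic(
    rep: Repertoire, min_count: int = NEOPLASTIC_MIN_COUNT
) -> str | None:
    """Return the neoplastic clone id, or None.

    The neoplastic clone is the single most abundant clone provided its
    template count reaches ``min_count`` (default 75). A tie at the maximum
    among qualifying clones is ambiguous and raises.
    """
    counts = rep.clones["templates"]
    top = counts.max()
    if top < min_count:
        return None
    winners = counts.index[counts == top]
    if len(winners) > 1:
        raise ValueError(
            f"ambiguous neoplastic clone: {len(winners)} clones tie at {top} templates"
        )
    return str(winners[0])


def gini_simpson(rep: Repertoire, exclude: Iterable[str] | None = None) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2) over clone frequencies.

    ``exclude`` removes the named clones (e.g. the neoplastic clone) and
    renormalizes the remaining frequencies before computing the index.
    """
    counts = rep.clones["templates"]
    if exclude is not None:
        counts = counts.drop(index=[c for c in exclude if c in counts.index])
    if len(counts) == 0:
        raise ValueError("exclusion removed all clones")
    p = counts.to_numpy(dtype=float)
    p /= p.sum()
    return float(1.0 - np.sum(p**2))


def morisita_horn(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Morisita-Horn similarity between two repertoires, in [0, 1].

    MH = 2 sum(x_i y_i) / ((d_x + d_y) X Y) with d_x = sum(x_i^2) / X^2,
    summed over the clone union; 1 for identical composition, 0 for
    disjoint clone sets.
    """
    x = rep_a.clones["templates"]
    y = rep_b.clones["templates"]
    union = x.index.union(y.index)
    xv = x.reindex(union, fill_value=0).to_numpy(dtype=float)
    yv = y.reindex(union, fill_value=0).to_numpy(dtype=float)
    big_x, big_y = xv.sum(), yv.sum()
    d_x = np.sum(xv**2) / big_x**2
    d_y = np.sum(yv**2) / big_y**2
    return float(2.0 * np.sum(xv * yv) / ((d_x + d_y) * big_x * big_y))


def differential_clones(
    rep_a: Repertoire,
    rep_b: Repertoire,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Differential clone abundance between two samples.

    Each clone of the union is tested with a two-sided Fisher's exact test
    on the 2x2 table (clone templates vs remaining templates, per sample);
    p-values are BH-corrected over the union. Returns a per-clone frame
    with counts, p, q and a ``significant`` flag at ``q_cut``.
    """
    x = rep_a.clones["templates"]
    y = rep_b.clones["templates"]
    union = x.index.union(y.index)
    xv = x.reindex(union, fill_value=0).astype(int)
    yv = y.reindex(union, fill_value=0).astype(int)
    big_x, big_y = int(xv.sum()), int(yv.sum())
    if big_x == 0 or big_y == 0:
        raise ValueError("zero total templates")

    pvals = np.array(
        [
            stats.fisher_exact(
                [[xa, big_x - xa], [yb, big_y - yb]], alternative="two-sided"
            ).pvalue
            for xa, yb in zip(xv, yv)
        ]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "count_a": xv,
            "count_b": yv,
            "p": pvals,
            "q": qvals,
            "significant": qvals < q_cut,
        },
        index=union,
    )
    return out.sort_values("q")


def clones_of_interest(
    repertoires: Mapping[str, Repertoire],
    tumor_repertoires: Mapping[str, Repertoire] | None = None,
    abundant_fraction: float = ABUNDANT_FRACTION,
    differential_q: float = 0.05,
    neoplastic_min_count: int = NEOPLASTIC_MIN_COUNT,
) -> pd.DataFrame:
    """Compile the union of clones of interest across a subject's samples.

    A clone qualifies if it is (a) the neoplastic clone of any sample,
    (b) present in a tumor repertoire, (c) abundant — above
    ``abundant_fraction`` of templates in at least one sample — or
    (d) significantly differentially abundant between any two of the given
    repertoires at ``differential_q``. Returns one row per qualifying
    clone with a boolean tag per criterion.
    """
    tumor_repertoires = tumor_repertoires or {}
    tags: dict[str, dict[str, bool]] = {}

    def tag(clone: str, reason: str) -> None:
        entry = tags.setdefault(
            clone,
            {"neoplastic": False, "tumor_present": False, "abundant": False, "differential": False},
        )
        entry[reason] = True

    for rep in repertoires.values():
        try:
            neo = identify_neoplastic(rep, min_count=neoplastic_min_count)
        except ValueError:
            # ambiguous tie at the maximum: no unambiguous neoplastic clone
            # in this sample; the tied clones still qualify as abundant
            neo = None
        if neo is not None:
            tag(neo, "neoplastic")
        freqs = rep.frequencies
        for clone in freqs.index[freqs > abundant_fraction]:
            tag(clone, "abundant")
    for rep in tumor_repertoires.values():
        for clone in rep.clones.index:
            tag(clone, "tumor_present")

    samples = list(repertoires)
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            diff = differential_clones(repertoires[a], repertoires[b], q_cut=differential_q)
            for clone in diff.index[diff["significant"]]:
                tag(clone, "differential")

    if not tags:
        return pd.DataFrame(
            columns=["neoplastic", "tumor_present", "abundant", "differential"]
        )
    out = pd.DataFrame.from_dict(tags, orient="index").sort_index()
    out.index.name = "clone_id"
    return out
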