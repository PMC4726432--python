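"""Two-group differential enrichment (PF vs WM) and target-set intersection.

Per gene, fold change is the ratio of linear group means mean(PF)/mean(WM)
and the p-value comes from a one-way fixed-effects ANOVA across the two
groups — algebraically identical to a pooled-variance two-sample t-test
(F = t^2). Selection follows the microarray convention: fold change >= 1.5
(inclusive) and ANOVA p < 0.05 (strict). No multiple-testing correction is
applied for selection; a BH-FDR column is emitted for transparency only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneAnnotation
from .target_assignment import TargetGeneSets

logger = logging.getLogger("tfcooc")

DEFAULT_FC_MIN = 1.5
DEFAULT_P_MAX = 0.05

Direction = Literal["PF-up", "both"]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample non-negative expression values with two group labels."""

    values: pd.DataFrame          # rows: gene_id, columns: sample ids
    groups: pd.Series             # sample id -> group label ("PF" / "WM")
    group_a: str = "PF"
    group_b: str = "WM"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values < 0).any().any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        labels = set(self.groups.loc[list(self.values.columns)])
        if labels != {self.group_a, self.group_b}:
            raise ValueError(
                f"expected groups {{{self.group_a}, {self.group_b}}}, got {labels}"
            )
        for g in (self.group_a, self.group_b):
            if len(self.samples_of(g)) < 2:
                raise ValueError(f"group {g} needs >= 2 samples")

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @classmethod
    def from_tsv(
        cls, matrix_path, groups_path, group_a: str = "PF", group_b: str = "WM"
    ) -> "ExpressionMatrix":
        """Load a gene-by-sample TSV (first column gene_id) and a two-column
        sample->group TSV sidecar."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        gmap = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(values=values, groups=gmap, group_a=group_a, group_b=group_b)

    def to_tsv(self, matrix_path, groups_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        self.groups.rename("group").to_csv(
            groups_path, sep="\t", index_label="sample"
        )


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-gene fold change (linear PF/WM), log2 ratio and ANOVA p-value."""

    gene_id: str
    fold_change: float
    log2_ratio: float
    p_value: float
    flag: str = ""          # "", "undefined-fc", "degenerate-p0"


def two_group_enrichment(matrix: ExpressionMatrix) -> pd.DataFrame:
    """One-way ANOVA (two groups) and linear fold change per gene.

    Returns a DataFrame indexed by gene_id with columns fold_change,
    log2_ratio, p_value, fdr_bh, flag. Degenerate genes: zero within-group
    variance with equal means -> p = 1; with unequal means -> p = 0 flagged
    "degenerate-p0"; zero WM mean -> fold change undefined, flagged
    "undefined-fc" and excluded from selection.
    """
    a = matrix.values[matrix.samples_of(matrix.group_a)].to_numpy(float)
    b = matrix.values[matrix.samples_of(matrix.group_b)].to_numpy(float)
    n1, n2 = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)

    # pooled within-group sum of squares; F = MS_between / MS_within
    ss_within = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    grand = (a.sum(axis=1) + b.sum(axis=1)) / (n1 + n2)
    ss_between = n1 * (mean_a - grand) ** 2 + n2 * (mean_b - grand) ** 2
    df_within = n1 + n2 - 2

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / 1.0) / (ss_within / df_within)
    p = stats.f.sf(f_stat, 1, df_within)

    zero_var = ss_within == 0
    equal_means = np.isclose(mean_a, mean_b, rtol=0.0, atol=0.0)
    p = np.where(zero_var & equal_means, 1.0, p)
    p = np.where(zero_var & ~equal_means, 0.0, p)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
        log2fc = np.log2(fc)

    flags = np.where(zero_var & ~equal_means, "degenerate-p0", "")
    flags = np.where(mean_b == 0, "undefined-fc", flags)

    fdr = _benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_ratio": log2fc,
            "p_value": p,
            "fdr_bh": fdr,
            "flag": flags,
        },
        index=matrix.values.index.rename("gene_id"),
    )
    n_bad = int((out["flag"] == "undefined-fc").sum())
    if n_bad:
        logger.warning("%d genes with zero %s mean: fold change undefined",
                       n_bad, matrix.group_b)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (reported only, never used for paper-mode
    selection)."""
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def select_enriched(
    records: pd.DataFrame,
    fc_min: float = DEFAULT_FC_MIN,
    p_max: float = DEFAULT_P_MAX,
    direction: Direction = "PF-up",
) -> set[str]:
    """Genes passing fold change >= fc_min (inclusive) and p < p_max (strict).

    "PF-up" keeps only fold_change >= fc_min; "both" also keeps
    fold_change <= 1/fc_min. Flagged undefined-fc genes never qualify.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    if not (0 < p_max < 1):
        raise ValueError("p_max must be in (0, 1)")
    ok = (records["flag"] != "undefined-fc") & (records["p_value"] < p_max)
    if direction == "PF-up":
        ok &= records["fold_change"] >= fc_min
    elif direction == "both":
        ok &= (records["fold_change"] >= fc_min) | (
            records["fold_change"] <= 1.0 / fc_min
        )
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return set(records.index[ok])


@dataclass
class TargetOverlap:
    """Intersection of one target category with the enriched gene set."""

    category: str
    genes: set[str]
    category_size: int
    enriched_size: int

    @property
    def size(self) -> int:
        return len(self.genes)


def intersect_with_targets(
    enriched: set[str],
    targets: TargetGeneSets,
    annotation: Optional[GeneAnnotation] = None,
    peg_filter: bool = False,
) -> dict[str, TargetOverlap]:
    """Per target category: overlap with the enriched set, plus sizes.

    With peg_filter, targets are restricted to protein-coding genes before
    intersecting. A zero overlap of identifier universes (likely namespace
    mismatch) is reported as a warning.
    """
    from .target_assignment import filter_protein_coding

    overlaps: dict[str, TargetOverlap] = {}
    any_universe_overlap = False
    for label, genes in targets.sets.items():
        members = genes
        if peg_filter:
            if annotation is None:
                raise ValueError("peg_filter requires an annotation")
            members = filter_protein_coding(members, annotation)
        if members & enriched:
            any_universe_overlap = True
        overlaps[label] = TargetOverlap(
            category=label,
            genes=members & enriched,
            category_size=len(members),
            enriched_size=len(enriched),
        )
    if enriched and targets.sets and not any_universe_overlap:
        logger.warning(
            "no overlap between enriched genes and any target set: "
            "check that gene identifier namespaces match"
        )
    return overlaps


def write_enrichment(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index_label="gene_id")
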