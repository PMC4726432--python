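"""Peak-to-gene assignment within a TSS window and TF target gene sets.

A peak is assigned to genes whose TSS lies within the window (default
+/- 50 kb, boundary inclusive) of the peak anchor. Two modes: ``all-in-window``
keeps every gene in the window ranked by distance; ``nearest-only`` keeps
rank 1 per peak. Ties on distance break by lexicographically smallest
gene_id so assignment tables are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneAnnotation, Peak

DEFAULT_TSS_WINDOW = 50_000

AnchorMode = Literal["midpoint", "summit"]
AssignMode = Literal["nearest-only", "all-in-window"]


@dataclass(frozen=True)
class PeakGeneAssignment:
    """A peak-gene link: distance from peak anchor to TSS, rank 1 = nearest."""

    peak_id: str
    gene_id: str
    tf: str
    distance: int
    rank: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass
class TargetGeneSets:
    """Named gene-id sets plus the parameters that produced them."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, label: str) -> set[str]:
        return self.sets[label]

    def __contains__(self, label: str) -> bool:
        return label in self.sets

    def add(self, label: str, genes: set[str]) -> None:
        if label in self.sets:
            raise ValueError(f"duplicate set label {label!r}")
        self.sets[label] = set(genes)

    def sizes(self) -> dict[str, int]:
        return {label: len(s) for label, s in self.sets.items()}


def peak_anchor(peak: Peak, mode: AnchorMode = "midpoint") -> int:
    """Anchor position: floor midpoint, or the peak's summit coordinate."""
    if mode == "midpoint":
        return peak.interval.midpoint
    if mode == "summit":
        if peak.summit is None:
            raise ValueError(f"peak {peak.peak_id} has no summit coordinate")
        return peak.summit
    raise ValueError(f"unknown anchor mode {mode!r}")


def assign_peaks_to_genes(
    peaks: Iterable[Peak],
    annotation: GeneAnnotation,
    window: int = DEFAULT_TSS_WINDOW,
    mode: AssignMode = "all-in-window",
    anchor_mode: AnchorMode = "midpoint",
) -> list[PeakGeneAssignment]:
    """Assign each peak to genes with |anchor - TSS| <= window (inclusive).

    Peaks with no gene in the window produce no assignment. Output order is
    deterministic: by peak, then rank.
    """
    if window <= 0:
        raise ValueError("window must be positive")

    # sorted TSS arrays per chromosome for O(log n) range queries
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    chrom_genes: dict[str, list[tuple[int, str]]] = {}
    for gene in annotation:
        chrom_genes.setdefault(gene.interval.chrom, []).append((gene.tss, gene.gene_id))
    for chrom, pairs in chrom_genes.items():
        pairs.sort()
        by_chrom[chrom] = (
            np.array([t for t, _ in pairs], dtype=np.int64),
            [g for _, g in pairs],
        )

    assignments: list[PeakGeneAssignment] = []
    for peak in peaks:
        entry = by_chrom.get(peak.interval.chrom)
        if entry is None:
            continue
        tss_arr, gene_ids = entry
        anchor = peak_anchor(peak, anchor_mode)
        lo = int(np.searchsorted(tss_arr, anchor - window, side="left"))
        hi = int(np.searchsorted(tss_arr, anchor + window, side="right"))
        if lo == hi:
            continue
        candidates = sorted(
            (int(abs(int(tss_arr[i]) - anchor)), gene_ids[i]) for i in range(lo, hi)
        )
        if mode == "nearest-only":
            candidates = candidates[:1]
        elif mode != "all-in-window":
            raise ValueError(f"unknown assignment mode {mode!r}")
        for rank, (dist, gid) in enumerate(candidates, start=1):
            assignments.append(
                PeakGeneAssignment(
                    peak_id=peak.peak_id,
                    gene_id=gid,
                    tf=peak.tf,
                    distance=dist,
                    rank=rank,
                )
            )
    return assignments


def tf_target_gene_set(
    assignments: Sequence[PeakGeneAssignment], tf: str
) -> set[str]:
    """Genes with at least one assigned peak of the named TF."""
    tfs = {a.tf for a in assignments}
    if tfs and tf not in tfs:
        raise ValueError(f"no assignments for TF {tf!r} (have {sorted(tfs)})")
    return {a.gene_id for a in assignments if a.tf == tf}


def filter_protein_coding(
    genes: set[str],
    annotation: GeneAnnotation,
    accepted_biotypes: Sequence[str] = ("protein_coding",),
) -> set[str]:
    """Keep members whose biotype is in the accepted list; genes lacking a
    biotype are excluded and logged."""
    import logging

    logger = logging.getLogger("tfcooc")
    accepted = set(accepted_biotypes)
    kept: set[str] = set()
    missing = 0
    for gid in genes:
        biotype = annotation.biotype_of(gid)
        if not biotype:
            missing += 1
            continue
        if biotype in accepted:
            kept.add(gid)
    if missing:
        logger.warning("%d genes lacked a biotype and were excluded", missing)
    return kept


def assignments_to_frame(assignments: Sequence[PeakGeneAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peak_id": a.peak_id,
                "gene_id": a.gene_id,
                "distance": a.distance,
                "rank": a.rank,
                "tf": a.tf,
            }
            for a in assignments
        ],
        columns=["peak_id", "gene_id", "distance", "rank", "tf"],
    )


def write_assignments(
    assignments: Sequence[PeakGeneAssignment], path
) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)
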