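"""Distance computations and co-occurrence gene-set construction.

Distance between two intervals is the edge-to-edge gap: 0 when they overlap
or touch, the separation between nearest edges otherwise, and infinite across
chromosomes. Co-occurrence cutoffs are inclusive (a gap of exactly 500 bp
passes the default 500 bp cutoff; 501 fails).

Set constructions:
  * pairwise TF-motif: a gene qualifies when one of its assigned peaks for
    the TF has a motif hit within the cutoff;
  * TF-pair: a gene qualifies when it has one peak from each TF with mutual
    gap within the cutoff;
  * triple: a gene qualifies when some qualifying TF-peak pair has a motif
    hit within the cutoff of BOTH peaks ("both" rule, the strictest reading;
    the looser "either" rule is available and recorded in provenance).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval, Peak
from .motif_scan import MotifHit
from .target_assignment import PeakGeneAssignment

DEFAULT_COOC_CUTOFF = 500

TripleRule = Literal["both", "either"]


@dataclass(frozen=True)
class CooccurrenceEvidence:
    """One qualifying feature configuration supporting a gene's membership."""

    gene_id: str
    category: str
    peak_ids: tuple[str, ...]
    motif_interval: GenomicInterval | None
    distances: tuple[int, ...]


@dataclass
class DistanceHistogram:
    """Binned gap distances, left-closed right-open contiguous bins."""

    bin_edges: np.ndarray
    counts: np.ndarray
    max_dist: int
    anchor: str = "edge-gap"

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(edges) == len(counts) + 1")

    def modal_bin(self) -> tuple[int, int]:
        i = int(np.argmax(self.counts))
        return int(self.bin_edges[i]), int(self.bin_edges[i + 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "count": self.counts.astype(int),
            }
        )


def interval_gap_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Edge-to-edge gap in bp: 0 for overlap/touch, inf across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    return float(max(b.start - a.end, a.start - b.end, 0))


class _HitIndex:
    """Per-chromosome sorted motif-hit index for gap-range queries."""

    def __init__(self, hits: Sequence[MotifHit]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[MotifHit]]] = {}
        grouped: dict[str, list[MotifHit]] = defaultdict(list)
        for h in hits:
            grouped[h.interval.chrom].append(h)
        for chrom, hs in grouped.items():
            hs.sort(key=lambda h: (h.interval.start, h.interval.end))
            starts = np.array([h.interval.start for h in hs], dtype=np.int64)
            ends = np.array([h.interval.end for h in hs], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, hs)

    def within(self, iv: GenomicInterval, cutoff: int) -> list[MotifHit]:
        """All hits with edge gap <= cutoff of the interval."""
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return []
        starts, ends, hs = entry
        # gap <= c  <=>  h.start <= iv.end + c  and  h.end >= iv.start - c
        hi = int(np.searchsorted(starts, iv.end + cutoff, side="right"))
        out = [hs[i] for i in range(hi) if ends[i] >= iv.start - cutoff]
        return out


def _peaks_by_gene(
    assignments: Sequence[PeakGeneAssignment], peaks: Sequence[Peak]
) -> dict[str, list[Peak]]:
    peak_map = {p.peak_id: p for p in peaks}
    out: dict[str, list[Peak]] = defaultdict(list)
    for a in assignments:
        out[a.gene_id].append(peak_map[a.peak_id])
    return out


def pairwise_cooccurrence_genes(
    tf_assignments: Sequence[PeakGeneAssignment],
    peaks: Sequence[Peak],
    motif_hits: Sequence[MotifHit],
    cutoff: int = DEFAULT_COOC_CUTOFF,
    category: str = "TF-motif",
) -> tuple[set[str], list[CooccurrenceEvidence]]:
    """Genes with >= 1 assigned peak having a motif hit within the cutoff.

    Evidence records enumerate every qualifying (peak, hit) pair.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    index = _HitIndex(motif_hits)
    genes: set[str] = set()
    evidence: list[CooccurrenceEvidence] = []
    for gene_id, gene_peaks in sorted(_peaks_by_gene(tf_assignments, peaks).items()):
        for peak in gene_peaks:
            for hit in index.within(peak.interval, cutoff):
                gap = interval_gap_distance(peak.interval, hit.interval)
                genes.add(gene_id)
                evidence.append(
                    CooccurrenceEvidence(
                        gene_id=gene_id,
                        category=category,
                        peak_ids=(peak.peak_id,),
                        motif_interval=hit.interval,
                        distances=(int(gap),),
                    )
                )
    return genes, evidence


def tf_pair_cooccurrence_genes(
    nkx_assignments: Sequence[PeakGeneAssignment],
    tbx_assignments: Sequence[PeakGeneAssignment],
    nkx_peaks: Sequence[Peak],
    tbx_peaks: Sequence[Peak],
    cutoff: int = DEFAULT_COOC_CUTOFF,
) -> set[str]:
    """Genes with one peak from each TF at mutual gap within the cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    nkx_by_gene = _peaks_by_gene(nkx_assignments, nkx_peaks)
    tbx_by_gene = _peaks_by_gene(tbx_assignments, tbx_peaks)
    genes: set[str] = set()
    for gene_id in nkx_by_gene.keys() & tbx_by_gene.keys():
        if any(
            interval_gap_distance(a.interval, b.interval) <= cutoff
            for a in nkx_by_gene[gene_id]
            for b in tbx_by_gene[gene_id]
        ):
            genes.add(gene_id)
    return genes


def triple_cooccurrence_genes(
    nkx_assignments: Sequence[PeakGeneAssignment],
    tbx_assignments: Sequence[PeakGeneAssignment],
    nkx_peaks: Sequence[Peak],
    tbx_peaks: Sequence[Peak],
    motif_hits: Sequence[MotifHit],
    cutoff: int = DEFAULT_COOC_CUTOFF,
    rule: TripleRule = "both",
) -> set[str]:
    """Genes where a qualifying TF-peak pair has a motif hit near the peaks.

    Under "both" (default) the hit must be within the cutoff of both peaks;
    under "either", of at least one. By construction the triple set is
    contained in both pairwise TF-motif sets and in the TF-pair set.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if rule not in ("both", "either"):
        raise ValueError(f"unknown triple rule {rule!r}")
    index = _HitIndex(motif_hits)
    nkx_by_gene = _peaks_by_gene(nkx_assignments, nkx_peaks)
    tbx_by_gene = _peaks_by_gene(tbx_assignments, tbx_peaks)
    genes: set[str] = set()
    for gene_id in nkx_by_gene.keys() & tbx_by_gene.keys():
        found = False
        for a in nkx_by_gene[gene_id]:
            hits_a = index.within(a.interval, cutoff)
            if not hits_a:
                continue
            for b in tbx_by_gene[gene_id]:
                if interval_gap_distance(a.interval, b.interval) > cutoff:
                    continue
                if rule == "either":
                    found = True
                    break
                if any(
                    interval_gap_distance(b.interval, h.interval) <= cutoff
                    for h in hits_a
                ):
                    found = True
                    break
            if found:
                break
        if not found and rule == "either":
            # "either" also admits a hit near only the Tbx peak of a valid pair
            for b in tbx_by_gene[gene_id]:
                if not index.within(b.interval, cutoff):
                    continue
                if any(
                    interval_gap_distance(a.interval, b.interval) <= cutoff
                    for a in nkx_by_gene[gene_id]
                ):
                    found = True
                    break
        if found:
            genes.add(gene_id)
    return genes


def distance_histogram(
    anchors_a: Iterable[GenomicInterval],
    anchors_b: Iterable[GenomicInterval],
    max_dist: int = 5_000,
    bin_width: int = 100,
    nearest_only: bool = True,
) -> DistanceHistogram:
    """Histogram of edge gaps from each a-interval to b-intervals.

    nearest_only bins the gap to the single nearest b per a; otherwise every
    b within max_dist contributes. Bins are left-closed right-open; gaps of
    exactly max_dist (or beyond) are not counted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if max_dist % bin_width != 0:
        raise ValueError("max_dist must be a multiple of bin_width")
    b_list = list(anchors_b)
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for b in b_list:
        by_chrom[b.chrom].append(b)
    gaps: list[float] = []
    for a in anchors_a:
        bs = by_chrom.get(a.chrom, [])
        if not bs:
            continue
        dists = [interval_gap_distance(a, b) for b in bs]
        if nearest_only:
            gaps.append(min(dists))
        else:
            gaps.extend(d for d in dists if d < max_dist)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    finite = [g for g in gaps if g < max_dist]
    counts, _ = np.histogram(finite, bins=edges)
    return DistanceHistogram(bin_edges=edges, counts=counts, max_dist=max_dist)


def write_evidence(evidence: Sequence[CooccurrenceEvidence], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "category": e.category,
                "peak_ids": ",".join(e.peak_ids),
                "motif_chrom": e.motif_interval.chrom if e.motif_interval else "",
                "motif_start": e.motif_interval.start if e.motif_interval else "",
                "motif_end": e.motif_interval.end if e.motif_interval else "",
                "distances": ",".join(str(d) for d in e.distances),
            }
            for e in evidence
        ],
        columns=[
            "gene_id", "category", "peak_ids",
            "motif_chrom", "motif_start", "motif_end", "distances",
        ],
    ).to_csv(path, sep="\t", index=False)
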