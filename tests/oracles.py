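"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive: exhaustive enumeration, per-window
Python loops and nested loops over all feature pairs. The oracles share no
code with the implementation beyond the public data types.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from tfcooc.genome_io import GenomicInterval
from tfcooc.motif_scan import BASES, ScoreTable

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def enumerate_pvalues(table: ScoreTable, background: np.ndarray) -> dict[int, float]:
    """p-value per integer lattice score by enumerating all 4^w words.

    Uses the table's own integer matrix (the shared discretization) but sums
    background word probabilities directly: p(k) = sum of Pr[W] over words
    with finite integer score >= k.
    """
    int_matrix = np.asarray(table.int_matrix)
    w = int_matrix.shape[0]
    mass: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=w):
        ks = [int(int_matrix[i, a]) for i, a in enumerate(word)]
        if any(k < 0 for k in ks):
            continue
        prob = float(np.prod([background[a] for a in word]))
        mass[sum(ks)] = mass.get(sum(ks), 0.0) + prob
    out: dict[int, float] = {}
    for k in range(table.n_bins + 1):
        out[k] = sum(p for kk, p in mass.items() if kk >= k)
    return out


def naive_scan(
    seq: str,
    matrix: np.ndarray,
    background: np.ndarray,
    table: ScoreTable,
    p_threshold: float,
    palindromic: bool,
) -> list[tuple[int, str, float]]:
    """Per-window scorer: (start, strand, pvalue) of every qualifying window.

    Scores each window letter by letter on both strands, converts through the
    table's integer lattice, applies the inclusive threshold, and collapses
    +/- pairs for palindromic motifs.
    """
    w = matrix.shape[0]
    int_matrix = np.asarray(table.int_matrix)
    hits = []
    for start in range(len(seq) - w + 1):
        window = seq[start:start + w]
        for strand in (("+",) if palindromic else ("+", "-")):
            word = window if strand == "+" else revcomp(window)
            k = 0
            dead = False
            for i, ch in enumerate(word):
                a = BASES.find(ch)
                if a < 0 or int_matrix[i, a] < 0:
                    dead = True
                    break
                k += int(int_matrix[i, a])
            if dead:
                continue
            p = table.pvalue_of_int(k)
            if p <= p_threshold:
                hits.append((start, "." if palindromic else strand, p))
    return hits


def gap(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return math.inf
    return max(b.start - a.end, a.start - b.end, 0)


def naive_assign(peaks, genes, window, nearest_only):
    """All (peak_id, gene_id, distance, rank) by scanning every pair."""
    out = []
    for peak in peaks:
        anchor = (peak.interval.start + peak.interval.end) // 2
        cands = []
        for gene in genes:
            if gene.interval.chrom != peak.interval.chrom:
                continue
            d = abs(anchor - gene.tss)
            if d <= window:
                cands.append((d, gene.gene_id))
        cands.sort()
        if nearest_only:
            cands = cands[:1]
        for rank, (d, gid) in enumerate(cands, start=1):
            out.append((peak.peak_id, gid, d, rank))
    return out


def naive_pairwise_set(assignments, peaks, hits, cutoff):
    peak_by_id = {p.peak_id: p for p in peaks}
    genes = set()
    for a in assignments:
        peak = peak_by_id[a.peak_id]
        for h in hits:
            if gap(peak.interval, h.interval) <= cutoff:
                genes.add(a.gene_id)
    return genes


def naive_pair_set(nkx_assign, tbx_assign, nkx_peaks, tbx_peaks, cutoff):
    nkx_by_id = {p.peak_id: p for p in nkx_peaks}
    tbx_by_id = {p.peak_id: p for p in tbx_peaks}
    nkx_of = {}
    tbx_of = {}
    for a in nkx_assign:
        nkx_of.setdefault(a.gene_id, []).append(nkx_by_id[a.peak_id])
    for a in tbx_assign:
        tbx_of.setdefault(a.gene_id, []).append(tbx_by_id[a.peak_id])
    genes = set()
    for gid in nkx_of:
        if gid not in tbx_of:
            continue
        for pa in nkx_of[gid]:
            for pb in tbx_of[gid]:
                if gap(pa.interval, pb.interval) <= cutoff:
                    genes.add(gid)
    return genes


def naive_triple_set(
    nkx_assign, tbx_assign, nkx_peaks, tbx_peaks, hits, cutoff, rule="both"
):
    nkx_by_id = {p.peak_id: p for p in nkx_peaks}
    tbx_by_id = {p.peak_id: p for p in tbx_peaks}
    nkx_of = {}
    tbx_of = {}
    for a in nkx_assign:
        nkx_of.setdefault(a.gene_id, []).append(nkx_by_id[a.peak_id])
    for a in tbx_assign:
        tbx_of.setdefault(a.gene_id, []).append(tbx_by_id[a.peak_id])
    genes = set()
    for gid in nkx_of:
        if gid not in tbx_of:
            continue
        for pa in nkx_of[gid]:
            for pb in tbx_of[gid]:
                if gap(pa.interval, pb.interval) > cutoff:
                    continue
                for h in hits:
                    ga = gap(pa.interval, h.interval)
                    gb = gap(pb.interval, h.interval)
                    ok = (
                        ga <= cutoff and gb <= cutoff
                        if rule == "both"
                        else ga <= cutoff or gb <= cutoff
                    )
                    if ok:
                        genes.add(gid)
    return genes
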