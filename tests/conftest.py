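"""Shared fixtures: small random genomic fixtures with known structure."""

from __future__ import annotations

import numpy as np
import pytest

from tfcooc.genome_io import (
    Gene,
    GeneAnnotation,
    GenomicInterval,
    Peak,
)


def random_fixture(rng: np.random.Generator, n_genes=30, n_peaks=40, n_hits=60,
                   chrom_len=200_000, n_chroms=2, peak_width=200, hit_width=6):
    """A random annotation + two peak sets + motif-hit intervals."""
    from tfcooc.motif_scan import MotifHit

    genes = {}
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_len - 3_000))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{i:03d}"
        genes[gid] = Gene(
            gid, gid, GenomicInterval(chrom, start, start + 2_000, strand),
            biotype="protein_coding" if rng.random() < 0.7 else "lincRNA",
        )
    annotation = GeneAnnotation(genes=genes)

    def peaks(tf, n):
        out = []
        for i in range(n):
            chrom = f"chr{rng.integers(1, n_chroms + 1)}"
            start = int(rng.integers(0, chrom_len - peak_width))
            out.append(
                Peak(GenomicInterval(chrom, start, start + peak_width, "."),
                     tf=tf, peak_id=f"{tf}_{i:03d}")
            )
        return out

    hits = []
    for i in range(n_hits):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_len - hit_width))
        hits.append(
            MotifHit(GenomicInterval(chrom, start, start + hit_width, "."),
                     motif="ACATGT", score=12.0, pvalue=1 / 4096)
        )
    return annotation, peaks("Nkx2.5", n_peaks), peaks("Tbx5", n_peaks), hits


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_fixture(rng):
    return random_fixture(rng)
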