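"""Genomic coordinate data model and readers/writers for standard formats.

All coordinates are internally 0-based half-open; conversion from 1-based
inclusive formats (GFF/GTF) happens only at the I/O boundary. The minus-strand
TSS is the last base of the half-open span (``end - 1``), i.e. the biological
5' end of a minus-strand gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("tfcooc")

VALID_STRANDS = ("+", "-", ".")
IUPAC_NUCLEOTIDES = set("ACGTURYSWKMBDHVN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware coordinate span: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Gene:
    """A gene with its span, strand-resolved TSS and biotype."""

    gene_id: str
    name: str
    interval: GenomicInterval
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """5' end: interval.start on +, interval.end - 1 on -."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass
class GeneAnnotation:
    """Collection of genes keyed by gene_id, with optional chromosome sizes."""

    genes: dict[str, Gene] = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, gene in self.genes.items():
            if gid != gene.gene_id:
                raise ValueError(f"key {gid!r} != gene_id {gene.gene_id!r}")
            size = self.chrom_sizes.get(gene.interval.chrom)
            if size is not None and gene.interval.end > size:
                raise ValueError(
                    f"gene {gid} extends past end of {gene.interval.chrom}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def biotype_of(self, gene_id: str) -> str:
        return self.genes[gene_id].biotype


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq enrichment interval for a named transcription factor."""

    interval: GenomicInterval
    tf: str
    peak_id: str
    score: Optional[float] = None
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError("tf label must be nonempty")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(f"peak {self.peak_id}: summit outside interval")


class GenomeSequence:
    """Per-chromosome nucleotide strings, upper-cased, over {A,C,G,T,N...}."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            up = seq.upper()
            bad = set(up) - IUPAC_NUCLEOTIDES
            if bad:
                pos = next(i for i, c in enumerate(up) if c in bad)
                raise FormatError(
                    f"non-IUPAC character {up[pos]!r} in {name} at position {pos}"
                )
            self._seqs[name] = up

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def fetch(self, interval: GenomicInterval) -> str:
        return self._seqs[interval.chrom][interval.start:interval.end]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gene_annotation(
    path: str | Path,
    biotype_attr: str = "gene_biotype",
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> GeneAnnotation:
    """Read gene-level records from a GFF3 or GTF file.

    1-based inclusive coordinates are converted to 0-based half-open. One
    Gene per ``gene`` feature; TSS is derived from strand. Genes without a
    strand are rejected and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        return GeneAnnotation(chrom_sizes=dict(chrom_sizes or {}))
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted parse exceptions
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    genes: dict[str, Gene] = {}
    rejected = 0
    for rec in db.features_of_type("gene"):
        if rec.strand not in ("+", "-"):
            rejected += 1
            logger.warning("gene %s has no strand; record rejected", rec.id)
            continue
        interval = GenomicInterval(
            chrom=rec.seqid, start=rec.start - 1, end=rec.end, strand=rec.strand
        )
        gene_id = rec.attributes.get("gene_id", [rec.id])[0]
        name = rec.attributes.get("gene_name", [gene_id])[0]
        biotype = rec.attributes.get(biotype_attr, [""])[0]
        if gene_id in genes:
            raise FormatError(f"duplicate gene_id {gene_id!r} in {path}")
        genes[gene_id] = Gene(gene_id, name, interval, biotype)
    if rejected:
        logger.warning("%d strandless gene records rejected", rejected)
    return GeneAnnotation(genes=genes, chrom_sizes=dict(chrom_sizes or {}))


def read_peaks(path: str | Path, tf: str, fmt: Optional[str] = None) -> list[Peak]:
    """Read peaks from BED (0-based half-open) or GFF (1-based inclusive).

    Format is inferred from the extension unless ``fmt`` ("bed" or "gff") is
    given. All peaks carry the supplied TF label; peak_ids are auto-generated
    when the file provides none. Records with end <= start are rejected and
    counted in the log.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff" if path.suffix.lower() in (".gff", ".gff3", ".gtf") else "bed"
    if fmt not in ("bed", "gff"):
        raise ValueError(f"unknown peak format {fmt!r}")

    peaks: list[Peak] = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if fmt == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
                    score = (
                        float(fields[4])
                        if len(fields) > 4 and fields[4] != "."
                        else None
                    )
                else:
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    score = (
                        float(fields[5])
                        if len(fields) > 5 and fields[5] != "."
                        else None
                    )
                    name = ""
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if end <= start:
                rejected += 1
                continue
            peak_id = name or f"{tf}_peak_{len(peaks) + 1}"
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, "."),
                    tf=tf,
                    peak_id=peak_id,
                    score=score,
                )
            )
    if rejected:
        logger.warning("%s: %d records with end <= start rejected", path, rejected)
    seen: set[str] = set()
    for p in peaks:
        if p.peak_id in seen:
            raise FormatError(f"duplicate peak_id {p.peak_id!r} in {path}")
        seen.add(p.peak_id)
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as 5-column BED."""
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.peak_id}\t{score}\n"
            )


def read_genome_sequence(path: str | Path) -> GenomeSequence:
    """Read a FASTA genome; record names must be unique."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSequence(seqs)


def write_genome_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms():
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene-set output
# ---------------------------------------------------------------------------

def venn_counts(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Sizes plus all pairwise and triple intersection cardinalities."""
    counts: dict[str, int] = {name: len(s) for name, s in sets.items()}
    names = list(sets)
    for r in (2, 3):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            counts[" & ".join(combo)] = len(inter)
    return counts


def write_gene_sets(
    sets: Mapping[str, set[str]],
    annotation: GeneAnnotation,
    tsv_path: str | Path,
    json_path: str | Path,
) -> None:
    """Write named gene sets as a TSV of members plus a JSON Venn summary.

    Every member must exist in the annotation; unknown ids raise with the
    full offender list.
    """
    unknown = sorted(
        gid for s in sets.values() for gid in s if gid not in annotation
    )
    if unknown:
        raise ValueError(f"gene ids not in annotation: {unknown}")
    rows = [
        {"set_name": name, "gene_id": gid, "gene_name": annotation[gid].name}
        for name in sets
        for gid in sorted(sets[name])
    ]
    pd.DataFrame(rows, columns=["set_name", "gene_id", "gene_name"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    with open(json_path, "w") as fh:
        json.dump(venn_counts(sets), fh, indent=2, sort_keys=True)
        fh.write("\n")
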