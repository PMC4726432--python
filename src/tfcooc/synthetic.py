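"""Seeded synthetic data: toy genome, annotation, planted regulatory
architecture and a two-group expression matrix with known ground truth.

The generator instantiates the geometry the co-occurrence analysis assumes:
ChIP-seq peaks placed within the TSS window of their gene, binding motifs
written into the sequence at controlled edge gaps from the peaks (within the
co-occurrence cutoff for planted positives, beyond it for planted decoys),
and a PF/WM expression matrix with planted fold changes over multiplicative
lognormal noise. Gene territories are spaced so that a peak planted for one
gene cannot fall into the TSS window of a neighbour, which is what makes
exact recovery assertable.

Background sequence is rejection-screened: every spurious match to the
configured consensus motifs (both strands) is destroyed, so that with
background rates at zero the only motif occurrences are the planted ones.

One integer seed drives everything; per-stage sub-streams are derived from
it with numpy's SeedSequence spawning, so each stage is reproducible in
isolation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .genome_io import (
    Gene,
    GeneAnnotation,
    GenomeSequence,
    GenomicInterval,
    Peak,
)
from .motif_scan import IUPAC_CODES, reverse_complement

CATEGORIES = (
    "nkx_only",
    "tbx_only",
    "nkx_irx",
    "tbx_irx",
    "nkx_tbx",
    "nkx_tbx_irx",
    "none",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic regulatory architecture.

    Defaults mirror the analysis parameters: a ±50 kb TSS assignment window,
    a 500 bp co-occurrence cutoff (planted positives sit inside it, planted
    decoys outside), 200 bp peaks, the "ACATGT" Irx consensus, and a 3 vs 3
    PF/WM design with 2-fold planted enrichment over ~10% multiplicative
    noise.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_600_000
    gc_content: float = 0.42
    gene_length: int = 2_000
    gene_spacing: int = 60_000
    category_counts: dict[str, int] = field(
        default_factory=lambda: {
            "nkx_only": 6,
            "tbx_only": 6,
            "nkx_irx": 8,
            "tbx_irx": 8,
            "nkx_tbx": 6,
            "nkx_tbx_irx": 6,
            "none": 10,
        }
    )
    noncoding_fraction: float = 0.2
    peak_width: int = 200
    peak_tss_dist: tuple[int, int] = (500, 5_000)
    motif_peak_gap: tuple[int, int] = (0, 500)
    decoy_motif_gap: tuple[int, int] = (600, 1_000)
    pair_peak_gap: tuple[int, int] = (100, 400)
    motif_consensus: str = "ACATGT"
    scrub_consensi: tuple[str, ...] = ("ACATGT", "ACAnnTGT")
    background_peak_rate: float = 0.0   # peaks per Mb, per TF
    background_motif_rate: float = 0.0  # motif copies per Mb
    samples_per_group: int = 3
    planted_fold_change: float = 2.0
    enriched_fraction: float = 0.5
    noise_sigma: float = 0.1
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sigma: float = 1.0
    tss_window: int = 50_000
    cooc_cutoff: int = 500

    @property
    def n_genes(self) -> int:
        return sum(self.category_counts.values())

    def validate(self) -> None:
        if any(v < 0 for v in self.category_counts.values()):
            raise ValueError("category counts must be >= 0")
        unknown = set(self.category_counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        if self.samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        lo, hi = self.motif_peak_gap
        if not (0 <= lo <= hi <= self.cooc_cutoff):
            raise ValueError("planted motif gaps must lie within [0, cutoff]")
        dlo, dhi = self.decoy_motif_gap
        if not (self.cooc_cutoff < dlo <= dhi):
            raise ValueError("decoy motif gaps must exceed the cutoff")
        plo, phi = self.peak_tss_dist
        if not (0 <= plo <= phi <= self.tss_window):
            raise ValueError("peak-TSS distances must lie within [0, window]")
        glo, ghi = self.pair_peak_gap
        if not (len(self.motif_consensus) + 2 <= glo <= ghi <= self.cooc_cutoff):
            raise ValueError(
                "pair peak gap must fit the motif and respect the cutoff"
            )

    def slot_length(self) -> int:
        return self.gene_length + self.gene_spacing

    def required_chrom_length(self, genes_on_chrom: int) -> int:
        margin = self.tss_window // 4
        return genes_on_chrom * self.slot_length() + 2 * margin


@dataclass
class SyntheticDataset:
    """Everything one simulation produces, in memory."""

    genome: GenomeSequence
    annotation: GeneAnnotation
    nkx_peaks: list[Peak]
    tbx_peaks: list[Peak]
    ground_truth: pd.DataFrame
    expression: Optional[pd.DataFrame] = None
    groups: Optional[pd.Series] = None

    def expected_sets(self) -> dict[str, set[str]]:
        """Category sets the pipeline should recover at zero background."""
        gt = self.ground_truth
        by_cat = {c: set(gt.index[gt["category"] == c]) for c in CATEGORIES}
        return {
            "Nkx2.5": by_cat["nkx_only"] | by_cat["nkx_irx"] | by_cat["nkx_tbx"]
            | by_cat["nkx_tbx_irx"],
            "Tbx5": by_cat["tbx_only"] | by_cat["tbx_irx"] | by_cat["nkx_tbx"]
            | by_cat["nkx_tbx_irx"],
            "Nkx2.5-Irx": by_cat["nkx_irx"] | by_cat["nkx_tbx_irx"],
            "Tbx5-Irx": by_cat["tbx_irx"] | by_cat["nkx_tbx_irx"],
            "Nkx2.5-Tbx5": by_cat["nkx_tbx"] | by_cat["nkx_tbx_irx"],
            "Nkx2.5-Tbx5-Irx": by_cat["nkx_tbx_irx"],
        }

    def enriched_genes(self) -> set[str]:
        gt = self.ground_truth
        return set(gt.index[gt["expr_enriched"]])


# ---------------------------------------------------------------------------
# Stage 1: genome and annotation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _orientation_patterns(consensus: str) -> list[tuple[str, re.Pattern]]:
    out = []
    for s in dict.fromkeys(
        (consensus.upper(), reverse_complement(consensus.upper()))
    ):
        out.append((s, re.compile("".join(f"[{IUPAC_CODES[c]}]" for c in s))))
    return out


def _scrub(
    seq: np.ndarray,
    rng: np.random.Generator,
    consensi: tuple[str, ...],
    protected: Optional[list[tuple[int, int]]] = None,
    max_rounds: int = 50,
) -> np.ndarray:
    """Destroy every match to the consensi (both strands) by mutating one
    constrained position per match to a disallowed base, never touching
    protected spans."""
    protected = protected or []
    oriented = [op for c in consensi for op in _orientation_patterns(c)]
    for _ in range(max_rounds):
        text = seq.tobytes().decode()
        dirty = False
        for cons, pat in oriented:
            pos = 0
            while True:
                m = pat.search(text, pos)
                if m is None:
                    break
                pos = m.start() + 1
                span = (m.start(), m.end())
                if any(span[0] >= p0 and span[1] <= p1 for p0, p1 in protected):
                    continue  # this IS a planted motif
                # mutate a constrained (non-N) position to a disallowed base
                editable = [
                    j for j, ch in enumerate(cons)
                    if len(IUPAC_CODES[ch]) < 4
                    and not any(p0 <= span[0] + j < p1 for p0, p1 in protected)
                ]
                if not editable:
                    continue
                j = editable[len(editable) // 2]
                disallowed = [b for b in "ACGT" if b not in IUPAC_CODES[cons[j]]]
                pick = disallowed[int(rng.integers(0, len(disallowed)))]
                seq[span[0] + j] = ord(pick)
                dirty = True
        if not dirty:
            return seq
    raise RuntimeError("could not scrub spurious motif matches")


def simulate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[GenomeSequence, GeneAnnotation, pd.DataFrame, dict[int, np.ndarray]]:
    """Generate the background genome and a packed gene annotation.

    Returns the genome, annotation, a ground-truth skeleton (gene_id,
    category, coordinates) and the raw per-chromosome byte arrays for later
    in-place motif planting.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_seq, rng_layout = [np.random.default_rng(s) for s in ss.spawn(2)]

    n_genes = config.n_genes
    per_chrom = int(np.ceil(n_genes / config.n_chromosomes))
    required = config.required_chrom_length(per_chrom)
    if required > config.chrom_length:
        raise ValueError(
            f"infeasible packing: {per_chrom} genes/chromosome need "
            f">= {required} bp, have {config.chrom_length}"
        )

    arrays: dict[int, np.ndarray] = {}
    for c in range(config.n_chromosomes):
        arrays[c] = _random_sequence(rng_seq, config.chrom_length, config.gc_content)
        if config.background_motif_rate == 0:
            arrays[c] = _scrub(arrays[c], rng_seq, config.scrub_consensi)

    # shuffled category labels, then packed into fixed slots
    labels = [c for c in CATEGORIES for _ in range(config.category_counts.get(c, 0))]
    rng_layout.shuffle(labels)
    margin = config.tss_window // 4
    genes: dict[str, Gene] = {}
    rows = []
    for i, category in enumerate(labels):
        chrom_idx = i % config.n_chromosomes
        slot = i // config.n_chromosomes
        chrom = f"chr{chrom_idx + 1}"
        jitter = int(rng_layout.integers(0, 2_000))
        start = margin + slot * config.slot_length() + jitter
        end = start + config.gene_length
        strand = "+" if rng_layout.random() < 0.5 else "-"
        gene_id = f"SYNG{i + 1:04d}"
        biotype = (
            "lincRNA"
            if rng_layout.random() < config.noncoding_fraction
            else "protein_coding"
        )
        gene = Gene(
            gene_id=gene_id,
            name=f"Syn{i + 1}",
            interval=GenomicInterval(chrom, start, end, strand),
            biotype=biotype,
        )
        genes[gene_id] = gene
        rows.append(
            {
                "gene_id": gene_id,
                "category": category,
                "chrom": chrom,
                "tss": gene.tss,
                "strand": strand,
                "biotype": biotype,
            }
        )

    chrom_sizes = {f"chr{c + 1}": config.chrom_length for c in range(config.n_chromosomes)}
    annotation = GeneAnnotation(genes=genes, chrom_sizes=chrom_sizes)
    skeleton = pd.DataFrame(rows).set_index("gene_id")
    genome = GenomeSequence(
        {f"chr{c + 1}": arrays[c].tobytes().decode() for c in range(config.n_chromosomes)}
    )
    return genome, annotation, skeleton, arrays


# ---------------------------------------------------------------------------
# Stage 2: regulatory architecture
# ---------------------------------------------------------------------------

def _place_peak(
    rng: np.random.Generator, config: SimulationConfig, tss: int, chrom_len: int
) -> tuple[int, int]:
    """A peak whose anchor (midpoint) sits peak_tss_dist from the TSS."""
    lo, hi = config.peak_tss_dist
    d = int(rng.integers(lo, hi + 1))
    sign = 1 if rng.random() < 0.5 else -1
    anchor = tss + sign * d
    half = config.peak_width // 2
    start = anchor - half
    end = start + config.peak_width
    if start < 0 or end > chrom_len:
        anchor = tss - sign * d
        start, end = anchor - half, anchor - half + config.peak_width
    return start, end


def plant_regulatory_architecture(
    config: SimulationConfig,
    genome: GenomeSequence,
    annotation: GeneAnnotation,
    skeleton: pd.DataFrame,
    arrays: dict[int, np.ndarray],
) -> tuple[GenomeSequence, list[Peak], list[Peak], pd.DataFrame]:
    """Plant peaks and motifs per category; return edited genome, peak sets
    and the completed ground-truth table.

    Planted geometry per category (gaps are edge gaps):
      nkx_only / tbx_only — one peak; plus a decoy motif at gap > cutoff;
      nkx_irx / tbx_irx   — one peak with a motif at gap <= cutoff;
      nkx_tbx             — one peak per TF at mutual gap <= cutoff, no motif;
      nkx_tbx_irx         — the pair with the motif centred between the peaks
                            (within the cutoff of BOTH);
      none                — nothing planted.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])
    motif = config.motif_consensus.upper()
    w = len(motif)
    motif_bytes = np.frombuffer(motif.encode(), dtype=np.uint8)
    chrom_index = {f"chr{c + 1}": c for c in arrays}

    nkx_peaks: list[Peak] = []
    tbx_peaks: list[Peak] = []
    planted_spans: dict[int, list[tuple[int, int]]] = {c: [] for c in arrays}
    gt = skeleton.copy()
    for col in ("nkx_peak", "tbx_peak", "motif_span", "decoy_span"):
        gt[col] = ""

    def write_motif(ci: int, start: int) -> None:
        arrays[ci][start:start + w] = motif_bytes
        planted_spans[ci].append((start, start + w))

    def add_peak(tf: str, chrom: str, start: int, end: int) -> Peak:
        peaks = nkx_peaks if tf == "Nkx2.5" else tbx_peaks
        p = Peak(
            interval=GenomicInterval(chrom, start, end, "."),
            tf=tf,
            peak_id=f"{tf}_p{len(peaks) + 1:04d}",
        )
        peaks.append(p)
        return p

    for gene_id, row in gt.iterrows():
        category = row["category"]
        if category == "none":
            continue
        chrom = row["chrom"]
        ci = chrom_index[chrom]
        chrom_len = len(arrays[ci])
        tss = int(row["tss"])

        if category in ("nkx_only", "tbx_only", "nkx_irx", "tbx_irx"):
            tf = "Nkx2.5" if category.startswith("nkx") else "Tbx5"
            ps, pe = _place_peak(rng, config, tss, chrom_len)
            peak = add_peak(tf, chrom, ps, pe)
            gt.at[gene_id, "nkx_peak" if tf == "Nkx2.5" else "tbx_peak"] = f"{ps}-{pe}"
            if category.endswith("_irx"):
                glo, ghi = config.motif_peak_gap
                gap = int(rng.integers(glo, ghi + 1))
                ms = pe + gap
                write_motif(ci, ms)
                gt.at[gene_id, "motif_span"] = f"{ms}-{ms + w}"
            else:
                dlo, dhi = config.decoy_motif_gap
                gap = int(rng.integers(dlo, dhi + 1))
                ms = pe + gap
                write_motif(ci, ms)
                gt.at[gene_id, "decoy_span"] = f"{ms}-{ms + w}"
        elif category in ("nkx_tbx", "nkx_tbx_irx"):
            ps, pe = _place_peak(rng, config, tss, chrom_len)
            glo, ghi = config.pair_peak_gap
            gap = int(rng.integers(glo, ghi + 1))
            ts, te = pe + gap, pe + gap + config.peak_width
            add_peak("Nkx2.5", chrom, ps, pe)
            add_peak("Tbx5", chrom, ts, te)
            gt.at[gene_id, "nkx_peak"] = f"{ps}-{pe}"
            gt.at[gene_id, "tbx_peak"] = f"{ts}-{te}"
            if category == "nkx_tbx_irx":
                ms = pe + (gap - w) // 2
                write_motif(ci, ms)
                gt.at[gene_id, "motif_span"] = f"{ms}-{ms + w}"
        else:
            raise AssertionError(f"unhandled category {category}")

    # background features, if requested
    if config.background_peak_rate > 0:
        genome_mb = config.n_chromosomes * config.chrom_length / 1e6
        for tf in ("Nkx2.5", "Tbx5"):
            n_bg = rng.poisson(config.background_peak_rate * genome_mb)
            for _ in range(n_bg):
                ci = int(rng.integers(0, config.n_chromosomes))
                start = int(
                    rng.integers(0, config.chrom_length - config.peak_width)
                )
                add_peak(tf, f"chr{ci + 1}", start, start + config.peak_width)
    if config.background_motif_rate > 0:
        genome_mb = config.n_chromosomes * config.chrom_length / 1e6
        n_bg = rng.poisson(config.background_motif_rate * genome_mb)
        for _ in range(n_bg):
            ci = int(rng.integers(0, config.n_chromosomes))
            start = int(rng.integers(0, config.chrom_length - w))
            write_motif(ci, start)

    # planting can create chance matches at motif boundaries; re-screen
    if config.background_motif_rate == 0:
        for ci in arrays:
            arrays[ci] = _scrub(
                arrays[ci], rng, config.scrub_consensi, protected=planted_spans[ci]
            )

    edited = GenomeSequence(
        {f"chr{c + 1}": arrays[c].tobytes().decode() for c in arrays}
    )
    return edited, nkx_peaks, tbx_peaks, gt


# ---------------------------------------------------------------------------
# Stage 3: expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig, ground_truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """PF/WM expression with planted fold changes over lognormal noise.

    Genes flagged enriched get their PF mean multiplied by the planted fold
    change; every value is the gene's baseline times exp(N(0, sigma)).
    Returns (matrix, group map, ground truth with expr columns filled).
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(4)[3])
    gt = ground_truth.copy()
    n = len(gt)
    if "expr_enriched" not in gt.columns:
        enriched = rng.random(n) < config.enriched_fraction
        gt["expr_enriched"] = enriched
        gt["true_fold"] = np.where(enriched, config.planted_fold_change, 1.0)

    baselines = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sigma, size=n)
    )
    k = config.samples_per_group
    samples = [f"PF_{i + 1}" for i in range(k)] + [f"WM_{i + 1}" for i in range(k)]
    means = np.column_stack(
        [baselines * gt["true_fold"].to_numpy()] * k + [baselines] * k
    )
    noise = np.exp(rng.normal(0.0, config.noise_sigma, size=(n, 2 * k)))
    values = pd.DataFrame(means * noise, index=gt.index, columns=samples)
    groups = pd.Series(
        ["PF"] * k + ["WM"] * k, index=pd.Index(samples, name="sample"), name="group"
    )
    return values, groups, gt


# ---------------------------------------------------------------------------
# One-call simulation
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all three generator stages and return the full dataset."""
    genome, annotation, skeleton, arrays = simulate_genome_and_annotation(config)
    genome, nkx_peaks, tbx_peaks, gt = plant_regulatory_architecture(
        config, genome, annotation, skeleton, arrays
    )
    values, groups, gt = simulate_expression(config, gt)
    return SyntheticDataset(
        genome=genome,
        annotation=annotation,
        nkx_peaks=nkx_peaks,
        tbx_peaks=tbx_peaks,
        ground_truth=gt,
        expression=values,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# File emission (the exact formats the real-mode pipeline consumes)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write FASTA, GFF3, BED per TF, expression + group TSVs and the
    ground-truth table; returns the path map."""
    from pathlib import Path

    from .genome_io import write_genome_fasta, write_peaks_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(outdir / "genome.fa"),
        "annotation": str(outdir / "genes.gff3"),
        "nkx_peaks": str(outdir / "nkx_peaks.bed"),
        "tbx_peaks": str(outdir / "tbx_peaks.bed"),
        "expression": str(outdir / "expression.tsv"),
        "groups": str(outdir / "groups.tsv"),
        "ground_truth": str(outdir / "ground_truth.tsv"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
    }
    write_genome_fasta(dataset.genome, paths["genome"])
    with open(paths["annotation"], "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(dataset.annotation, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = gene.interval
            attrs = (
                f"ID={gene.gene_id};gene_id={gene.gene_id};"
                f"gene_name={gene.name};gene_biotype={gene.biotype}"
            )
            fh.write(
                f"{iv.chrom}\tsynth\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
    write_peaks_bed(dataset.nkx_peaks, paths["nkx_peaks"])
    write_peaks_bed(dataset.tbx_peaks, paths["tbx_peaks"])
    if dataset.expression is not None:
        dataset.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
        dataset.groups.to_csv(paths["groups"], sep="\t", index_label="sample")
    dataset.ground_truth.to_csv(paths["ground_truth"], sep="\t")
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in dataset.genome.chrom_sizes().items():
            fh.write(f"{chrom}\t{size}\n")
    return paths
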