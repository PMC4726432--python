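"""FIMO-style motif scanning with exact score-to-p-value calibration.

A motif is a position probability matrix (PPM). Candidate words are scored by
the log-likelihood ratio against a background mononucleotide model,

    score(w) = sum_i log2( M[i, w_i] / b[w_i] )   (bits),

and each score is converted to the p-value Pr[score(W) >= s] for a random
background word W. The p-value is computed exactly on an integer-scaled score
lattice by dynamic programming (convolution of the per-position score
distributions under the background), the same discretization FIMO uses. Hits
are windows on either strand whose p-value is at or below the threshold
(default 1e-5, inclusive).

Both Irx consensus motifs handled downstream ("ACATGT", "ACAnnTGT") are
reverse-complement palindromes: a forward hit always coincides with a reverse
hit on the same span, so coincident strand pairs are collapsed to a single
hit with strand ".".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .genome_io import GenomeSequence, GenomicInterval

logger = logging.getLogger("tfcooc")

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_GRANULARITY = 1000


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BackgroundModel:
    """Mononucleotide background probabilities (A, C, G, T)."""

    p: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=float)
        if arr.shape != (4,) or np.any(arr <= 0):
            raise ValueError("background needs 4 strictly positive probabilities")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"background probabilities sum to {arr.sum()}, not 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls()

    @classmethod
    def from_genome(cls, genome: GenomeSequence) -> "BackgroundModel":
        """Mononucleotide frequencies over all chromosomes (N excluded)."""
        counts = np.zeros(4)
        for chrom in genome.chroms():
            seq = np.frombuffer(genome[chrom].encode(), dtype=np.uint8)
            for i, b in enumerate(BASES):
                counts[i] += np.count_nonzero(seq == ord(b))
        if counts.sum() == 0:
            raise ValueError("genome contains no A/C/G/T bases")
        freqs = counts / counts.sum()
        freqs = np.clip(freqs, 1e-6, None)
        freqs = freqs / freqs.sum()
        return cls(tuple(freqs))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


@dataclass(frozen=True)
class Motif:
    """A named position probability matrix with provenance."""

    name: str
    matrix: tuple[tuple[float, float, float, float], ...]
    source: str = ""
    consensus: Optional[str] = None

    def __post_init__(self) -> None:
        arr = self.as_array()
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
            raise ValueError("matrix must be width x 4 with width >= 1")
        if np.any(arr < 0):
            raise ValueError("matrix probabilities must be >= 0")
        colsums = arr.sum(axis=1)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError("each matrix column must sum to 1 (within 1e-9)")

    @property
    def width(self) -> int:
        return len(self.matrix)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    def reverse_complement(self) -> "Motif":
        rc = self.as_array()[::-1, ::-1]
        return Motif(
            name=self.name,
            matrix=tuple(map(tuple, rc)),
            source=self.source,
            consensus=(
                reverse_complement(self.consensus) if self.consensus else None
            ),
        )

    def is_rc_palindrome(self, tol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.as_array(), self.reverse_complement().as_array(), atol=tol)
        )


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: span, strand, LLR score (bits) and p-value."""

    interval: GenomicInterval
    motif: str
    score: float
    pvalue: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")


# ---------------------------------------------------------------------------
# Motif construction
# ---------------------------------------------------------------------------

def build_pwm_from_consensus(
    consensus: str, epsilon: float = 0.0, name: Optional[str] = None
) -> Motif:
    """Build a PPM from an IUPAC consensus string.

    Each column spreads ``1 - k_disallowed * epsilon`` uniformly over the
    allowed bases of the IUPAC code and gives ``epsilon`` to each disallowed
    base; an 'n' column is uniform 0.25.
    """
    if not (0.0 <= epsilon < 0.25):
        raise ValueError("epsilon must satisfy 0 <= epsilon < 0.25")
    cols = []
    for ch in consensus.upper():
        allowed = IUPAC_CODES.get(ch)
        if allowed is None:
            raise ValueError(f"invalid IUPAC character {ch!r} in consensus")
        col = np.full(4, epsilon)
        n_allowed = len(allowed)
        share = (1.0 - (4 - n_allowed) * epsilon) / n_allowed
        for b in allowed:
            col[BASE_INDEX[b]] = share
        cols.append(tuple(col))
    return Motif(
        name=name or consensus.upper(),
        matrix=tuple(cols),
        source="consensus",
        consensus=consensus.upper(),
    )


def _check_meme_probability_rows(path: str | Path) -> None:
    """Enforce the column-sum tolerance on the raw letter-probability rows
    (the minimal-format parser renormalizes silently, so check the text)."""
    name = ""
    in_matrix = False
    row_idx = 0
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped.startswith("MOTIF"):
            name = stripped.split()[1] if len(stripped.split()) > 1 else "?"
            in_matrix = False
        elif stripped.startswith("letter-probability matrix"):
            in_matrix = True
            row_idx = 0
        elif in_matrix:
            parts = stripped.split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                in_matrix = False
                continue
            if not vals:
                in_matrix = False
                continue
            if abs(sum(vals) - 1.0) > 1e-3 + 1e-9:  # 0.999 is still accepted
                raise ValueError(
                    f"{path}: motif {name}: column {row_idx} sums to "
                    f"{sum(vals):.4f} (tolerance 1e-3)"
                )
            row_idx += 1


def read_pwm_meme(path: str | Path) -> list[Motif]:
    """Read motifs from a MEME minimal-format file.

    Columns off by less than 1e-3 from summing to 1 are renormalized; larger
    deviations are an error.
    """
    _check_meme_probability_rows(path)
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "minimal")
        except Exception as exc:
            raise ValueError(f"cannot parse MEME file {path}: {exc}") from exc
        out = []
        for rec in records:
            arr = np.array(
                [[rec.pwm[b][i] for b in BASES] for i in range(rec.length)],
                dtype=float,
            )
            colsums = arr.sum(axis=1)
            arr = arr / colsums[:, None]
            out.append(
                Motif(
                    name=rec.name or f"motif_{len(out) + 1}",
                    matrix=tuple(map(tuple, arr)),
                    source=f"meme:{path}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def log_odds_matrix(motif: Motif, background: BackgroundModel) -> np.ndarray:
    """Width x 4 matrix of log2(M/b); zero matrix entries map to -inf."""
    with np.errstate(divide="ignore"):
        return np.log2(motif.as_array()) - np.log2(background.as_array())


def log_odds_score(motif: Motif, background: BackgroundModel, word: str) -> float:
    """LLR score in bits of one word; -inf for zero entries or non-ACGT."""
    word = word.upper()
    if len(word) != motif.width:
        raise ValueError(f"word length {len(word)} != motif width {motif.width}")
    lom = log_odds_matrix(motif, background)
    total = 0.0
    for i, ch in enumerate(word):
        idx = BASE_INDEX.get(ch)
        if idx is None:
            return float("-inf")
        total += lom[i, idx]
    return total


@dataclass(frozen=True)
class ScoreTable:
    """Monotone map from integer-scaled LLR score to exact p-value.

    Real scores are mapped to a lattice with ``granularity`` bins per motif
    position: entry ``survival[k]`` is Pr[scaled score >= k] under the
    background, for k in [0, n_bins]. Words hitting a -inf log-odds entry are
    unscorable and never contribute to finite-score tails.
    """

    offsets: tuple[float, ...]       # per-position min finite log-odds
    scale: float                     # lattice units per bit
    survival: tuple[float, ...]      # survival function over integer scores
    min_score: float                 # smallest finite attainable score (bits)
    max_score: float                 # largest attainable score (bits)
    int_matrix: tuple[tuple[int, ...], ...] = field(repr=False, default=())

    @property
    def n_bins(self) -> int:
        return len(self.survival) - 1

    def scaled(self, lom_word_scores: Sequence[int]) -> int:
        return int(sum(lom_word_scores))

    def pvalue_of_int(self, k: int) -> float:
        k = max(0, min(k, self.n_bins))
        return self.survival[k]

    def pvalue_of_score(self, score: float) -> float:
        """P-value of a real-valued score (scores <= min finite map to 1)."""
        if score == float("-inf"):
            return 1.0
        k = int(round((score - sum(self.offsets)) * self.scale))
        return self.pvalue_of_int(k)


def score_pvalue_table(
    motif: Motif,
    background: BackgroundModel = BackgroundModel(),
    granularity: int = DEFAULT_GRANULARITY,
) -> ScoreTable:
    """Exact score -> p-value calibration by DP over the integer lattice.

    p(s) = Pr[score(W) >= s] for a random background word W; non-increasing
    in s; p at the minimum attainable score is 1.
    """
    if granularity < 100:
        raise ValueError("granularity must be >= 100")
    lom = log_odds_matrix(motif, background)
    if np.any(np.all(np.isinf(lom) & (lom < 0), axis=1)):
        raise ValueError("motif has an all-zero column: no scorable word")
    w = motif.width
    bg = background.as_array()

    finite_mask = np.isfinite(lom)
    offsets = np.where(finite_mask, lom, np.inf).min(axis=1)
    maxima = np.where(finite_mask, lom, -np.inf).max(axis=1)
    total_range = float((maxima - offsets).sum())
    scale = (w * granularity) / total_range if total_range > 0 else 1.0

    # integer-scaled per-position scores; -1 marks unscorable letters
    int_matrix = np.full((w, 4), -1, dtype=np.int64)
    for i in range(w):
        for a in range(4):
            if finite_mask[i, a]:
                int_matrix[i, a] = int(round((lom[i, a] - offsets[i]) * scale))
    n_bins = int(int_matrix.max(axis=1, where=int_matrix >= 0, initial=0).sum())

    pmf = np.zeros(n_bins + 1)
    pmf[0] = 1.0
    top = 0
    for i in range(w):
        nxt = np.zeros(n_bins + 1)
        hi = 0
        for a in range(4):
            k = int_matrix[i, a]
            if k < 0:
                continue  # -inf letter: word drops out of the finite tail
            nxt[k:top + k + 1] += bg[a] * pmf[:top + 1]
            hi = max(hi, top + k)
        pmf = nxt
        top = hi
    survival = np.minimum(pmf[::-1].cumsum()[::-1], 1.0)

    return ScoreTable(
        offsets=tuple(offsets),
        scale=scale,
        survival=tuple(survival),
        min_score=float(offsets.sum()),
        max_score=float(maxima.sum()),
        int_matrix=tuple(map(tuple, int_matrix)),
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """Map sequence to 0..3 indices; anything not A/C/G/T becomes 4."""
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_int_scores(codes: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Integer-lattice score per window; -1 where any letter is unscorable."""
    w = int_matrix.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    padded = np.vstack([int_matrix.T, np.full((1, w), -1, dtype=np.int64)])  # 5 x w
    per_pos = np.empty((n, w), dtype=np.int64)
    for i in range(w):
        per_pos[:, i] = padded[codes[i:i + n], i]
    dead = (per_pos < 0).any(axis=1)
    totals = per_pos.sum(axis=1)
    totals[dead] = -1
    return totals


def scan_sequences(
    genome: GenomeSequence,
    motif: Motif,
    background: BackgroundModel = BackgroundModel(),
    p_threshold: float = DEFAULT_P_THRESHOLD,
    granularity: int = DEFAULT_GRANULARITY,
    table: Optional[ScoreTable] = None,
) -> list[MotifHit]:
    """Scan every window of every chromosome on both strands.

    Windows with p-value <= p_threshold (inclusive) are reported; reverse
    hits carry forward-genome coordinates. For reverse-complement-palindromic
    motifs the coincident +/- hits at one span collapse to strand ".".
    Windows containing N are unscorable and never reported.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError("p_threshold must be in (0, 1]")
    if table is None:
        table = score_pvalue_table(motif, background, granularity)
    int_matrix = np.asarray(table.int_matrix, dtype=np.int64)
    palindromic = motif.is_rc_palindrome()

    # threshold in lattice units: smallest k with survival[k] <= p_threshold
    survival = np.asarray(table.survival)
    qualifying = np.nonzero(survival <= p_threshold)[0]
    if qualifying.size == 0:
        return []
    k_min = int(qualifying[0])

    rc_matrix = (
        None
        if palindromic
        else np.asarray(
            score_pvalue_table(motif.reverse_complement(), background, granularity).int_matrix,
            dtype=np.int64,
        )
    )

    w = motif.width
    offset_sum = sum(table.offsets)
    hits: list[MotifHit] = []
    for chrom in genome.chroms():
        codes = _encode(genome[chrom])
        if codes.size < w:
            continue
        fwd = _window_int_scores(codes, int_matrix)
        strand_scores = [(fwd, "+" if not palindromic else ".")]
        if rc_matrix is not None:
            strand_scores.append((_window_int_scores(codes, rc_matrix), "-"))
        for totals, strand in strand_scores:
            for pos in np.nonzero(totals >= k_min)[0]:
                k = int(totals[pos])
                score = offset_sum + k / table.scale
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(chrom, int(pos), int(pos) + w, strand),
                        motif=motif.name,
                        score=score,
                        pvalue=table.pvalue_of_int(k),
                    )
                )
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def scan_iupac_exact(
    genome: GenomeSequence, consensus: str, name: Optional[str] = None
) -> list[MotifHit]:
    """Exact-IUPAC-match scan mode: report every window matching the
    consensus pattern on either strand, with score 0 and p-value 1.

    For palindromic consensi (both Irx motifs) forward and reverse matches
    coincide and are reported once with strand ".".
    """
    consensus = consensus.upper()
    w = len(consensus)
    pattern = re.compile(
        "".join(f"[{IUPAC_CODES[c]}]" for c in consensus)
    )
    rc = reverse_complement(consensus)
    palindromic = rc == consensus
    rc_pattern = None if palindromic else re.compile(
        "".join(f"[{IUPAC_CODES[c]}]" for c in rc)
    )
    motif_name = name or consensus
    hits: list[MotifHit] = []
    for chrom in genome.chroms():
        seq = genome[chrom]
        spans: dict[tuple[int, str], None] = {}
        for m in _finditer_overlapping(pattern, seq):
            spans[(m, "." if palindromic else "+")] = None
        if rc_pattern is not None:
            for m in _finditer_overlapping(rc_pattern, seq):
                spans[(m, "-")] = None
        for (start, strand) in sorted(spans):
            hits.append(
                MotifHit(
                    interval=GenomicInterval(chrom, start, start + w, strand),
                    motif=motif_name,
                    score=0.0,
                    pvalue=1.0,
                )
            )
    return hits


def _finditer_overlapping(pattern: re.Pattern, seq: str) -> Iterable[int]:
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return
        yield m.start()
        pos = m.start() + 1


# ---------------------------------------------------------------------------
# Hit output
# ---------------------------------------------------------------------------

def write_hits(hits: Sequence[MotifHit], bed_path: str | Path, tsv_path: str | Path) -> None:
    """Write hits as 6-column BED (score = -log10 p scaled x100, capped at
    1000) plus a TSV with exact score and p-value."""
    import pandas as pd

    with open(bed_path, "w") as fh:
        for h in hits:
            bed_score = min(1000, int(round(-100 * np.log10(h.pvalue))))
            fh.write(
                f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}"
                f"\t{h.motif}\t{bed_score}\t{h.interval.strand}\n"
            )
    pd.DataFrame(
        [
            {
                "chrom": h.interval.chrom,
                "start": h.interval.start,
                "end": h.interval.end,
                "strand": h.interval.strand,
                "motif": h.motif,
                "score_bits": h.score,
                "pvalue": h.pvalue,
            }
            for h in hits
        ],
        columns=["chrom", "start", "end", "strand", "motif", "score_bits", "pvalue"],
    ).to_csv(tsv_path, sep="\t", index=False)
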