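# Methods

## The prediction procedure

`tfcooc` predicts genes co-regulated by a pair of cardiac transcription
factors (Nkx2.5, Tbx5) and the Irx3 homeodomain factor, from three evidence
layers:

1. **Motif occurrences.** The genome is scanned for Irx binding motifs —
   the consensus strings `ACATGT` and `ACAnnTGT`, or MEME-format PWMs. A
   candidate word `w` of motif width is scored by the log-likelihood ratio
   against a mononucleotide background `b`:

       score(w) = Σ_i log2( M[i, w_i] / b[w_i] )   (bits)

   and converted to the p-value `Pr[score(W) ≥ s]` for a random background
   word `W`. Occurrences with p ≤ 1e-5 (inclusive) qualify.
2. **Peak-to-gene assignment.** ChIP-seq peaks for each TF are assigned to
   genes whose TSS lies within ±50 kb of the peak anchor (midpoint by
   default; boundary inclusive). A gene with ≥ 1 assigned peak of a TF is a
   target of that TF.
3. **Co-occurrence.** Distances between features are edge-to-edge gaps
   (overlap = 0; infinite across chromosomes). A gene is an
   `Nkx2.5-Irx` (resp. `Tbx5-Irx`) co-occurrence target when one of its
   assigned peaks has a motif occurrence within 500 bp; an `Nkx2.5-Tbx5`
   target when it has one peak of each TF at mutual gap ≤ 500 bp; a triple
   target when some qualifying peak pair has a motif within 500 bp of
   **both** peaks. All cutoffs are inclusive.

Target sets are then restricted to protein-coding genes and intersected
with expression-defined conduction-system-enriched genes: per gene, fold
change = mean(PF)/mean(WM) on the linear scale and a one-way fixed-effects
ANOVA p-value across the two groups (two groups, so F = t² of the pooled
two-sample t-test); a gene is enriched when fold change ≥ 1.5 (inclusive)
and p < 0.05 (strict), PF-up by default.

## Exact p-value calibration

The score→p-value map is computed by dynamic programming on an integer
score lattice, the discretization FIMO uses. Per-position log-odds scores
are shifted by their per-position finite minimum and scaled so the full
score range spans `width × granularity` lattice units (granularity default
1000 bins/position). The lattice distribution of the background word score
is built by convolving the per-position integer score distributions
weighted by the background; its survival function is the p-value table.
Letters with zero motif probability score −∞: such words are excluded from
every finite tail (a window containing them, or any `N`, is never
reported). Scanning computes each window's integer score with the same
lattice, so every reported hit's p-value equals its table entry exactly —
tests verify the table against exhaustive enumeration of all `4^width`
words, which agrees to machine precision because both sides share the
discretization.

Under a uniform background a perfect match to a width-6 consensus has
p = (1/4)^6 = 1/4096 ≈ 2.4e-4, above the 1e-5 threshold: strict consensus
motifs cannot pass a FIMO-style 1e-5 filter, only information-richer PWMs
can. The package therefore treats MEME-format PWMs as first-class scan
input and also provides an exact-IUPAC-match mode (`scan_mode:
iupac-exact`, the default for consensus strings), recording the mode in the
run report. Exact-match hits carry score 0 and p-value 1 as sentinels —
exact matching has no score distribution, and downstream distance analysis
uses only the hit coordinates. Both Irx consensus motifs are reverse-complement palindromes;
coincident +/− hits on one span are collapsed to a single hit with strand
`.` so downstream distance analysis never double-counts.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `tss_window` | 50,000 bp | peak-anchor to TSS assignment radius, inclusive |
| `cooccurrence_cutoff` | 500 bp | edge-gap cutoff for all co-occurrence rules, inclusive |
| `p_threshold` | 1e-5 | motif occurrence p-value cutoff, inclusive |
| `granularity` | 1000 | lattice bins per motif position |
| `background` | uniform | FIMO's documented default when no background file is given; genome-derived mononucleotide frequencies optional |
| `assignment_mode` | all-in-window | every gene in the window counts ("genes containing binding within ±50 kb"); `nearest-only` keeps rank 1 |
| `triple_rule` | both | motif must be within the cutoff of both peaks of a qualifying pair; `either` relaxes this |
| `fc_min` / `p_max` | 1.5 / 0.05 | enrichment selection, fold inclusive, p strict |
| `direction` | PF-up | enrichment is one-sided toward the conduction-system population |

Where the procedure is ambiguous in the literature, both readings are
implemented and the choice is recorded in the report's parameter echo: the
distance anchor (edge gap default; midpoints available through
`peak_anchor`), nearest-gene versus all-genes-in-window assignment, and the
both/either triple rule. The `both` default is the strictest reading
consistent with the observed containment of the triple set inside both
pairwise sets; with `either` the containment in the pair set still holds
but the motif constraint weakens.

No multiple-testing correction is applied to the enrichment selection —
the selection criterion is the raw ANOVA p-value, matching standard
microarray-console practice; a Benjamini-Hochberg column is emitted in
`enrichment.tsv` for transparency only. Expression values are used as
given; normalization is assumed to have happened upstream.

## The synthetic generator

`tfcooc.synthetic` emulates the statistical structure the analysis assumes,
with a machine-readable ground truth:

* a small genome (default 2 × 1.6 Mb, GC 0.42) of i.i.d. bases, with 50
  genes packed in fixed slots (2 kb genes, 60 kb spacing, random strand,
  20% non-coding biotype);
* seven planted gene categories (Nkx-only, Tbx-only, Nkx-Irx, Tbx-Irx,
  Nkx-Tbx, Nkx-Tbx-Irx, none) with 200 bp peaks placed 0.5–5 kb from the
  TSS, motifs written into the sequence at edge gaps of 0–500 bp from
  their peak (between and within 500 bp of both peaks for the triple
  category), and decoy motifs at 600–1000 bp for the single-TF categories —
  planted negatives that must never enter an Irx co-occurrence set;
* a PF/WM expression matrix (3 samples per group) with lognormal baselines,
  a planted 2-fold PF effect in a random half of the genes, and ~10%
  multiplicative lognormal noise.

Gene spacing (60 kb) exceeds the TSS window plus the maximum planted
peak–TSS distance, so a planted peak can never fall into a neighbouring
gene's window; this is what lets recovery tests assert exact set equality
rather than superset-with-noise. When the background motif rate is zero the
genome is rejection-screened: every spurious match to the configured
consensus strings (either strand) is destroyed by mutating a constrained
position, before and after planting (planted spans are protected). One
integer seed drives all stages through numpy `SeedSequence` spawning, so
each stage is reproducible in isolation and a fixed seed gives
byte-identical output files.

What the generator does **not** emulate: read-level ChIP-seq noise, peak
callers and their width/score distributions, probe-level microarray
artefacts, correlated expression noise, overlapping genes, repetitive
sequence, and realistic motif information content in the background.
Passing recovery tests therefore demonstrates the correctness of the set
constructions and distance rules under controlled geometry — not the
biological error rate of the predictions on real data, which is dominated
by annotation release, peak quality and the PWM used.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GFF/GTF conversion happens
  only at I/O. Minus-strand TSS = `end − 1`.
* Assignment ties on distance break by lexicographically smallest gene_id,
  making assignment tables byte-reproducible.
* Peak midpoint is `floor((start+end)/2)`.
* Enrichment degeneracies: zero within-group variance with equal means →
  p = 1; with unequal means → p = 0, flagged `degenerate-p0`; zero WM mean →
  fold change undefined, flagged `undefined-fc` and never selected.
* An empty annotation, empty peak file or motif wider than a chromosome are
  identity cases, not errors.
* Histograms are left-closed right-open; a gap equal to `max_dist` is not
  counted.

## Problem sizes

Default test and acceptance runs use the 50-gene / 3.2 Mb configuration
above (≈ 60 peaks, ≈ 30 planted motifs), five seeds for recovery sweeps,
and 3,400 simulated genes for enrichment calibration. These sizes keep
the full validation suite under a minute while leaving every boundary case
(50,000 bp window edge, 500/501 bp gaps, fold change exactly 1.5,
p exactly 0.05) explicitly exercised.

## Known limitations

* Real-mode inputs must share one genome assembly; no coordinate
  conversion is performed or checked.
* The background model is mononucleotide; no higher-order Markov
  backgrounds.
* No statistical enrichment test for co-occurrence counts (no permutation
  null) — the pipeline reports the sets, not their significance.
* Motif q-values/FDR over hits are out of scope; the hit filter is the
  per-occurrence p-value, as in the original procedure.
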