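"""End-to-end orchestration: scan -> assign -> co-occurrence -> PEG filter
-> enrichment -> intersection, with a machine-readable JSON report.

Every default equals the analysis constants: ±50 kb TSS window, 500 bp
co-occurrence cutoff, motif p-value threshold 1e-5, fold change >= 1.5 and
ANOVA p < 0.05. Each parameter (default or override) is echoed into the
report, which together with the input paths suffices to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd

from . import genome_io
from .cooccurrence import (
    DEFAULT_COOC_CUTOFF,
    distance_histogram,
    pairwise_cooccurrence_genes,
    tf_pair_cooccurrence_genes,
    triple_cooccurrence_genes,
    write_evidence,
)
from .expression import (
    DEFAULT_FC_MIN,
    DEFAULT_P_MAX,
    ExpressionMatrix,
    intersect_with_targets,
    select_enriched,
    two_group_enrichment,
    write_enrichment,
)
from .motif_scan import (
    DEFAULT_P_THRESHOLD,
    BackgroundModel,
    build_pwm_from_consensus,
    read_pwm_meme,
    scan_iupac_exact,
    scan_sequences,
    write_hits,
)
from .synthetic import SimulationConfig, SyntheticDataset, simulate_dataset, write_dataset
from .target_assignment import (
    DEFAULT_TSS_WINDOW,
    assign_peaks_to_genes,
    filter_protein_coding,
    tf_target_gene_set,
    write_assignments,
    TargetGeneSets,
)

logger = logging.getLogger("tfcooc")

__version__ = "0.1.0"

EXIT_CONFIG_ERROR = 2
EXIT_INPUT_ERROR = 3
EXIT_STAGE_FAILURE = 4

ScanMode = Literal["pwm", "iupac-exact"]


@dataclass
class PipelineConfig:
    """Inputs and parameters for one run; defaults are the analysis values."""

    genome: Optional[str] = None
    annotation: Optional[str] = None
    nkx_peaks: Optional[str] = None
    tbx_peaks: Optional[str] = None
    motifs: list[str] = field(default_factory=lambda: ["ACATGT", "ACAnnTGT"])
    meme_file: Optional[str] = None
    expression: Optional[str] = None
    groups: Optional[str] = None
    outdir: str = "tfcooc_out"

    tss_window: int = DEFAULT_TSS_WINDOW
    cooccurrence_cutoff: int = DEFAULT_COOC_CUTOFF
    p_threshold: float = DEFAULT_P_THRESHOLD
    scan_mode: ScanMode = "iupac-exact"
    consensus_epsilon: float = 0.0
    background: Literal["uniform", "genome"] = "uniform"
    assignment_mode: Literal["all-in-window", "nearest-only"] = "all-in-window"
    triple_rule: Literal["both", "either"] = "both"
    fc_min: float = DEFAULT_FC_MIN
    p_max: float = DEFAULT_P_MAX
    direction: Literal["PF-up", "both"] = "PF-up"
    peg_biotypes: tuple[str, ...] = ("protein_coding",)
    seed: int = 0

    nkx_label: str = "Nkx2.5"
    tbx_label: str = "Tbx5"

    def validate(self) -> None:
        if self.tss_window <= 0:
            raise ValueError("tss_window must be positive")
        if self.cooccurrence_cutoff <= 0:
            raise ValueError("cooccurrence_cutoff must be positive")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.scan_mode not in ("pwm", "iupac-exact"):
            raise ValueError(f"unknown scan mode {self.scan_mode!r}")

    def parameter_echo(self) -> dict:
        keep = (
            "tss_window", "cooccurrence_cutoff", "p_threshold", "scan_mode",
            "consensus_epsilon", "background", "assignment_mode", "triple_rule",
            "fc_min", "p_max", "direction", "peg_biotypes", "motifs", "seed",
        )
        d = dataclasses.asdict(self)
        return {k: d[k] for k in keep}


def run_pipeline(
    config: PipelineConfig,
    dataset: Optional[SyntheticDataset] = None,
) -> dict:
    """Run all stages and write outputs + report.json under config.outdir.

    Inputs come either from the file paths in the config or, for synthetic
    runs, from an in-memory dataset. Stages whose inputs are absent are
    skipped (no expression table -> stop after the PEG filter).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "tfcooc",
        "version": __version__,
        "parameters": config.parameter_echo(),
        "stages": {},
        "set_sizes": {},
        "histograms": {},
    }
    t_all = time.perf_counter()

    def stage(name):
        report["stages"][name] = {"seconds": None}
        return time.perf_counter()

    def stage_done(name, t0, **counts):
        report["stages"][name]["seconds"] = round(time.perf_counter() - t0, 4)
        report["stages"][name].update(counts)

    try:
        # ---- load inputs -------------------------------------------------
        t0 = stage("load")
        if dataset is not None:
            genome = dataset.genome
            annotation = dataset.annotation
            nkx_peaks = dataset.nkx_peaks
            tbx_peaks = dataset.tbx_peaks
        else:
            genome = genome_io.read_genome_sequence(config.genome)
            annotation = genome_io.read_gene_annotation(
                config.annotation, chrom_sizes=genome.chrom_sizes()
            )
            nkx_peaks = genome_io.read_peaks(config.nkx_peaks, config.nkx_label)
            tbx_peaks = genome_io.read_peaks(config.tbx_peaks, config.tbx_label)
        stage_done(
            "load", t0,
            genes=len(annotation),
            nkx_peaks=len(nkx_peaks),
            tbx_peaks=len(tbx_peaks),
            chromosomes=len(genome.chroms()),
        )

        # ---- motif scan --------------------------------------------------
        t0 = stage("scan")
        background = (
            BackgroundModel.from_genome(genome)
            if config.background == "genome"
            else BackgroundModel.uniform()
        )
        hits = []
        if config.meme_file:
            for motif in read_pwm_meme(config.meme_file):
                hits.extend(
                    scan_sequences(genome, motif, background, config.p_threshold)
                )
        for consensus in config.motifs:
            if config.scan_mode == "iupac-exact":
                hits.extend(scan_iupac_exact(genome, consensus))
            else:
                motif = build_pwm_from_consensus(consensus, config.consensus_epsilon)
                hits.extend(
                    scan_sequences(genome, motif, background, config.p_threshold)
                )
        write_hits(hits, outdir / "motif_hits.bed", outdir / "motif_hits.tsv")
        stage_done("scan", t0, motif_hits=len(hits))

        # ---- assignment --------------------------------------------------
        t0 = stage("assign")
        nkx_assign = assign_peaks_to_genes(
            nkx_peaks, annotation, config.tss_window, config.assignment_mode
        )
        tbx_assign = assign_peaks_to_genes(
            tbx_peaks, annotation, config.tss_window, config.assignment_mode
        )
        write_assignments(nkx_assign + tbx_assign, outdir / "assignments.tsv")
        targets = TargetGeneSets(provenance=report["parameters"])
        targets.add(config.nkx_label, tf_target_gene_set(nkx_assign, config.nkx_label) if nkx_assign else set())
        targets.add(config.tbx_label, tf_target_gene_set(tbx_assign, config.tbx_label) if tbx_assign else set())
        stage_done("assign", t0, assignments=len(nkx_assign) + len(tbx_assign))

        # ---- co-occurrence -----------------------------------------------
        t0 = stage("cooccur")
        cutoff = config.cooccurrence_cutoff
        nkx_irx, ev_n = pairwise_cooccurrence_genes(
            nkx_assign, nkx_peaks, hits, cutoff, f"{config.nkx_label}-Irx"
        )
        tbx_irx, ev_t = pairwise_cooccurrence_genes(
            tbx_assign, tbx_peaks, hits, cutoff, f"{config.tbx_label}-Irx"
        )
        pair = tf_pair_cooccurrence_genes(
            nkx_assign, tbx_assign, nkx_peaks, tbx_peaks, cutoff
        )
        triple = triple_cooccurrence_genes(
            nkx_assign, tbx_assign, nkx_peaks, tbx_peaks, hits, cutoff,
            rule=config.triple_rule,
        )
        targets.add(f"{config.nkx_label}-Irx", nkx_irx)
        targets.add(f"{config.tbx_label}-Irx", tbx_irx)
        targets.add(f"{config.nkx_label}-{config.tbx_label}", pair)
        targets.add(f"{config.nkx_label}-{config.tbx_label}-Irx", triple)
        write_evidence(ev_n + ev_t, outdir / "cooccurrence_evidence.tsv")

        peak_ivs = [p.interval for p in nkx_peaks]
        hit_ivs = [h.interval for h in hits]
        hist_pm = distance_histogram(peak_ivs, hit_ivs, max_dist=5_000, bin_width=100)
        hist_pp = distance_histogram(
            peak_ivs, [p.interval for p in tbx_peaks], max_dist=5_000, bin_width=100
        )
        hist_pm.to_frame().to_csv(outdir / "hist_peak_motif.tsv", sep="\t", index=False)
        hist_pp.to_frame().to_csv(outdir / "hist_nkx_tbx.tsv", sep="\t", index=False)
        report["histograms"] = {
            "peak_motif_modal_bin": list(hist_pm.modal_bin()) if hist_pm.counts.sum() else None,
            "nkx_tbx_modal_bin": list(hist_pp.modal_bin()) if hist_pp.counts.sum() else None,
        }
        stage_done("cooccur", t0, evidence_records=len(ev_n) + len(ev_t))

        # ---- PEG filter --------------------------------------------------
        t0 = stage("peg_filter")
        for label in (
            f"{config.nkx_label}-Irx",
            f"{config.tbx_label}-Irx",
            f"{config.nkx_label}-{config.tbx_label}-Irx",
        ):
            targets.add(
                f"{label} PEG",
                filter_protein_coding(targets[label], annotation, config.peg_biotypes),
            )
        stage_done("peg_filter", t0)

        # ---- expression enrichment (optional) ----------------------------
        have_expression = (
            dataset is not None and dataset.expression is not None
        ) or (config.expression and config.groups)
        overlaps_report = {}
        if have_expression:
            t0 = stage("enrich")
            if dataset is not None and dataset.expression is not None:
                matrix = ExpressionMatrix(dataset.expression, dataset.groups)
            else:
                matrix = ExpressionMatrix.from_tsv(config.expression, config.groups)
            records = two_group_enrichment(matrix)
            write_enrichment(records, outdir / "enrichment.tsv")
            enriched = select_enriched(
                records, config.fc_min, config.p_max, config.direction
            )
            overlaps = intersect_with_targets(enriched, targets, annotation)
            overlaps_report = {
                label: ov.size for label, ov in overlaps.items()
            }
            targets.add("VCS-enriched", enriched)
            for label, ov in overlaps.items():
                if label.endswith("-Irx") or label.endswith("-Irx PEG"):
                    targets.add(f"{label} & VCS", ov.genes)
            stage_done("enrich", t0, genes_tested=len(records), enriched=len(enriched))

        # ---- outputs -----------------------------------------------------
        genome_io.write_gene_sets(
            targets.sets, annotation, outdir / "gene_sets.tsv", outdir / "gene_sets.json"
        )
        report["set_sizes"] = targets.sizes()
        report["overlap_sizes"] = overlaps_report
        report["seconds_total"] = round(time.perf_counter() - t_all, 4)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except Exception:
        (outdir / "FAILED").write_text(
            f"failed in stage: {list(report['stages'])[-1] if report['stages'] else 'setup'}\n"
        )
        raise


def simulate_and_run(
    sim_config: SimulationConfig,
    overrides: Optional[dict] = None,
    outdir: str = "tfcooc_out",
) -> tuple[dict, pd.DataFrame]:
    """Generate a synthetic dataset, run the pipeline on it, and score the
    predictions against the planted ground truth.

    Returns (report, recovery summary). The recovery table has one row per
    category with sensitivity and specificity of the predicted set against
    the planted set.
    """
    dataset = simulate_dataset(sim_config)
    out = Path(outdir)
    data_paths = write_dataset(dataset, out / "data")
    config = PipelineConfig(
        outdir=str(out),
        seed=sim_config.seed,
        tss_window=sim_config.tss_window,
        cooccurrence_cutoff=sim_config.cooc_cutoff,
        motifs=[sim_config.motif_consensus],
        **(overrides or {}),
    )
    report = run_pipeline(config, dataset=dataset)
    report["data_paths"] = data_paths

    expected = dataset.expected_sets()
    universe = set(dataset.ground_truth.index)
    rows = []
    with open(out / "gene_sets.json") as fh:
        _ = json.load(fh)
    sets_df = pd.read_csv(out / "gene_sets.tsv", sep="\t")
    predicted = {
        name: set(group["gene_id"])
        for name, group in sets_df.groupby("set_name")
    }
    for label, truth in expected.items():
        pred = predicted.get(label, set())
        tp = len(pred & truth)
        fp = len(pred - truth)
        fn = len(truth - pred)
        tn = len(universe - pred - truth)
        rows.append(
            {
                "category": label,
                "planted": len(truth),
                "predicted": len(pred),
                "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                "sensitivity": tp / len(truth) if truth else 1.0,
                "specificity": tn / (tn + fp) if (tn + fp) else 1.0,
            }
        )
    recovery = pd.DataFrame(rows).set_index("category")
    recovery.to_csv(out / "recovery.tsv", sep="\t")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report, recovery
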