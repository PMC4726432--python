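"""Gap distances, co-occurrence set construction and distance histograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_fixture
from oracles import naive_pair_set, naive_pairwise_set, naive_triple_set

from tfcooc.cooccurrence import (
    distance_histogram,
    interval_gap_distance,
    pairwise_cooccurrence_genes,
    tf_pair_cooccurrence_genes,
    triple_cooccurrence_genes,
)
from tfcooc.genome_io import Gene, GeneAnnotation, GenomicInterval, Peak
from tfcooc.motif_scan import MotifHit
from tfcooc.target_assignment import assign_peaks_to_genes


def hit(chrom, start, width=6):
    return MotifHit(
        GenomicInterval(chrom, start, start + width, "."),
        motif="ACATGT", score=12.0, pvalue=1 / 4096,
    )


class TestGapDistance:
    def test_overlap_is_zero(self):
        a = GenomicInterval("c", 100, 200)
        b = GenomicInterval("c", 150, 300)
        assert interval_gap_distance(a, b) == 0

    def test_gap_edge_to_edge(self):
        motif = GenomicInterval("c", 1_000, 1_006)
        peak = GenomicInterval("c", 1_500, 1_700)
        assert interval_gap_distance(motif, peak) == 494

    def test_cutoff_boundary_501_fails(self):
        motif = GenomicInterval("c", 1_000, 1_006)
        peak = GenomicInterval("c", 1_507, 1_700)
        assert interval_gap_distance(motif, peak) == 501

    def test_cross_chromosome_infinite(self):
        a = GenomicInterval("c1", 0, 10)
        b = GenomicInterval("c2", 0, 10)
        assert math.isinf(interval_gap_distance(a, b))

    @given(
        s1=st.integers(0, 10_000), l1=st.integers(1, 500),
        s2=st.integers(0, 10_000), l2=st.integers(1, 500),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetric_and_consistent_with_pointwise_minimum(self, s1, l1, s2, l2):
        a = GenomicInterval("c", s1, s1 + l1)
        b = GenomicInterval("c", s2, s2 + l2)
        d = interval_gap_distance(a, b)
        assert d == interval_gap_distance(b, a)
        # gap equals the minimum |x - y| - adjacency over base pairs
        brute = max(0, max(b.start - a.end, a.start - b.end))
        assert d == brute
        if a.start < b.end and b.start < a.end:
            assert d == 0


def _fixture_sets(rng, cutoff, n_genes=25, n_peaks=35, n_hits=45, window=30_000):
    ann, nkx_peaks, tbx_peaks, hits = random_fixture(
        rng, n_genes=n_genes, n_peaks=n_peaks, n_hits=n_hits
    )
    nkx_a = assign_peaks_to_genes(nkx_peaks, ann, window)
    tbx_a = assign_peaks_to_genes(tbx_peaks, ann, window)
    return ann, nkx_peaks, tbx_peaks, hits, nkx_a, tbx_a


class TestSetConstruction:
    def test_no_hits_empty(self, rng):
        _, nkx_peaks, _, _, nkx_a, _ = _fixture_sets(rng, 500)
        genes, ev = pairwise_cooccurrence_genes(nkx_a, nkx_peaks, [], 500)
        assert genes == set() and ev == []

    def test_planted_positive_and_negative(self):
        ann = GeneAnnotation(
            genes={
                "G": Gene("G", "G", GenomicInterval("c", 10_000, 12_000, "+")),
                "H": Gene("H", "H", GenomicInterval("c", 200_000, 202_000, "+")),
            }
        )
        peaks = [
            Peak(GenomicInterval("c", 11_000, 11_200, "."), "Nkx2.5", "pG"),
            Peak(GenomicInterval("c", 201_000, 201_200, "."), "Nkx2.5", "pH"),
        ]
        hits = [hit("c", 11_600), hit("c", 201_800)]  # gaps 400 and 600
        assign = assign_peaks_to_genes(peaks, ann, 50_000)
        genes, ev = pairwise_cooccurrence_genes(assign, peaks, hits, 500)
        assert genes == {"G"}
        assert all(d <= 500 for e in ev for d in e.distances)

    def test_cutoff_zero_keeps_only_touching(self):
        ann = GeneAnnotation(
            genes={"G": Gene("G", "G", GenomicInterval("c", 10_000, 12_000, "+"))}
        )
        peaks = [Peak(GenomicInterval("c", 11_000, 11_200, "."), "Nkx2.5", "p")]
        assign = assign_peaks_to_genes(peaks, ann, 50_000)
        touching, _ = pairwise_cooccurrence_genes(assign, peaks, [hit("c", 11_200)], 0)
        separated, _ = pairwise_cooccurrence_genes(assign, peaks, [hit("c", 11_201)], 0)
        assert touching == {"G"} and separated == set()

    def test_single_tf_gene_excluded_from_pair(self, rng):
        ann, nkx_peaks, tbx_peaks, _, nkx_a, tbx_a = _fixture_sets(rng, 500)
        pair = tf_pair_cooccurrence_genes(nkx_a, tbx_a, nkx_peaks, tbx_peaks, 500)
        nkx_genes = {a.gene_id for a in nkx_a}
        tbx_genes = {a.gene_id for a in tbx_a}
        assert pair <= (nkx_genes & tbx_genes)

    def test_cross_chromosome_peaks_never_pair(self):
        ann = GeneAnnotation(
            genes={"G": Gene("G", "G", GenomicInterval("c1", 10_000, 12_000, "+"))}
        )
        nkx = [Peak(GenomicInterval("c1", 11_000, 11_200, "."), "Nkx2.5", "pn")]
        # mis-assignment fixture: a Tbx peak on another chromosome
        tbx = [Peak(GenomicInterval("c2", 11_000, 11_200, "."), "Tbx5", "pt")]
        nkx_a = assign_peaks_to_genes(nkx, ann, 50_000)
        tbx_a = [
            type(a)(peak_id="pt", gene_id="G", tf="Tbx5", distance=0, rank=1)
            for a in nkx_a
        ]
        assert tf_pair_cooccurrence_genes(nkx_a, tbx_a, nkx, tbx, 500) == set()

    def test_triple_architecture_planted(self):
        ann = GeneAnnotation(
            genes={"G": Gene("G", "G", GenomicInterval("c", 10_000, 12_000, "+"))}
        )
        nkx = [Peak(GenomicInterval("c", 11_000, 11_200, "."), "Nkx2.5", "pn")]
        tbx = [Peak(GenomicInterval("c", 11_500, 11_700, "."), "Tbx5", "pt")]  # gap 300
        motif_between = [hit("c", 11_340)]  # gaps 140 and 154
        nkx_a = assign_peaks_to_genes(nkx, ann, 50_000)
        tbx_a = assign_peaks_to_genes(tbx, ann, 50_000)
        assert triple_cooccurrence_genes(nkx_a, tbx_a, nkx, tbx, motif_between, 500) == {"G"}

    def test_motif_near_one_peak_only_fails_both_rule(self):
        ann = GeneAnnotation(
            genes={"G": Gene("G", "G", GenomicInterval("c", 10_000, 12_000, "+"))}
        )
        nkx = [Peak(GenomicInterval("c", 11_000, 11_200, "."), "Nkx2.5", "pn")]
        tbx = [Peak(GenomicInterval("c", 11_300, 11_500, "."), "Tbx5", "pt")]
        far_left = [hit("c", 10_750)]  # 244 from Nkx, 544 from Tbx
        nkx_a = assign_peaks_to_genes(nkx, ann, 50_000)
        tbx_a = assign_peaks_to_genes(tbx, ann, 50_000)
        both = triple_cooccurrence_genes(nkx_a, tbx_a, nkx, tbx, far_left, 500, "both")
        either = triple_cooccurrence_genes(nkx_a, tbx_a, nkx, tbx, far_left, 500, "either")
        pair_irx, _ = pairwise_cooccurrence_genes(nkx_a, nkx, far_left, 500)
        assert both == set() and either == {"G"} and pair_irx == {"G"}

    @pytest.mark.parametrize("seed", range(6))
    def test_all_constructions_match_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(1_000 + seed)
        ann, nkx_peaks, tbx_peaks, hits, nkx_a, tbx_a = _fixture_sets(rng, 500)
        for cutoff in (0, 200, 500):
            got, _ = pairwise_cooccurrence_genes(nkx_a, nkx_peaks, hits, cutoff)
            assert got == naive_pairwise_set(nkx_a, nkx_peaks, hits, cutoff)
            got_pair = tf_pair_cooccurrence_genes(
                nkx_a, tbx_a, nkx_peaks, tbx_peaks, cutoff
            )
            assert got_pair == naive_pair_set(
                nkx_a, tbx_a, nkx_peaks, tbx_peaks, cutoff
            )
            for rule in ("both", "either"):
                got_triple = triple_cooccurrence_genes(
                    nkx_a, tbx_a, nkx_peaks, tbx_peaks, hits, cutoff, rule
                )
                assert got_triple == naive_triple_set(
                    nkx_a, tbx_a, nkx_peaks, tbx_peaks, hits, cutoff, rule
                )

    def test_cutoff_monotonicity_and_subset_laws(self, rng):
        ann, nkx_peaks, tbx_peaks, hits, nkx_a, tbx_a = _fixture_sets(
            rng, 500, n_genes=40, n_peaks=60, n_hits=80
        )
        prev = {}
        for cutoff in (100, 500, 1_000):
            nkx_irx, _ = pairwise_cooccurrence_genes(nkx_a, nkx_peaks, hits, cutoff)
            tbx_irx, _ = pairwise_cooccurrence_genes(tbx_a, tbx_peaks, hits, cutoff)
            pair = tf_pair_cooccurrence_genes(nkx_a, tbx_a, nkx_peaks, tbx_peaks, cutoff)
            triple = triple_cooccurrence_genes(
                nkx_a, tbx_a, nkx_peaks, tbx_peaks, hits, cutoff
            )
            assert triple <= nkx_irx and triple <= tbx_irx and triple <= pair
            assert nkx_irx <= {a.gene_id for a in nkx_a}
            if prev:
                for key, cur in (("n", nkx_irx), ("t", tbx_irx), ("p", pair), ("3", triple)):
                    assert prev[key] <= cur
            prev = {"n": nkx_irx, "t": tbx_irx, "p": pair, "3": triple}


class TestDistanceHistogram:
    def test_disjoint_chromosomes_all_zero(self):
        a = [GenomicInterval("c1", 100, 200)]
        b = [GenomicInterval("c2", 100, 200)]
        h = distance_histogram(a, b, max_dist=1_000, bin_width=100)
        assert h.counts.sum() == 0

    def test_single_pair_binning(self):
        a = [GenomicInterval("c", 1_000, 1_006)]
        b = [GenomicInterval("c", 1_500, 1_700)]
        h = distance_histogram(a, b, max_dist=1_000, bin_width=100)
        assert h.counts[4] == 1 and h.counts.sum() == 1  # bin [400, 500)

    def test_modal_bin_contains_planted_mode(self, rng):
        a, b = [], []
        pos = 10_000
        for i in range(60):
            g = int(rng.integers(480, 520))
            a.append(GenomicInterval("c", pos, pos + 200))
            b.append(GenomicInterval("c", pos + 200 + g, pos + 400 + g))
            pos += 5_000
        h = distance_histogram(a, b, max_dist=2_000, bin_width=100)
        lo, hi = h.modal_bin()
        assert lo <= 500 < hi
        # cross-check against the naive O(n^2) nearest computation
        naive = []
        for iv in a:
            naive.append(min(interval_gap_distance(iv, x) for x in b))
        counts, _ = np.histogram([d for d in naive if d < 2_000],
                                 bins=np.arange(0, 2_100, 100))
        assert (h.counts == counts).all()

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            distance_histogram([], [], max_dist=1_050, bin_width=100)
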