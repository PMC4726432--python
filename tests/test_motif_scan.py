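"""Motif construction, log-odds scoring, exact p-values and scanning."""

import numpy as np
import pytest

from oracles import enumerate_pvalues, naive_scan

from tfcooc.genome_io import GenomeSequence
from tfcooc.motif_scan import (
    BackgroundModel,
    Motif,
    build_pwm_from_consensus,
    log_odds_score,
    read_pwm_meme,
    scan_iupac_exact,
    scan_sequences,
    score_pvalue_table,
)

UNIFORM = BackgroundModel.uniform()


def random_motif(rng: np.random.Generator, width: int, zeros: bool = False) -> Motif:
    mat = rng.dirichlet(np.full(4, 0.5), size=width)
    if zeros:
        # zero out one random entry per some columns, renormalize
        for i in range(width):
            if rng.random() < 0.3:
                j = rng.integers(0, 4)
                mat[i, j] = 0.0
                mat[i] /= mat[i].sum()
    return Motif(name=f"rnd{width}", matrix=tuple(map(tuple, mat)))


class TestConsensusPwm:
    def test_strict_consensus_columns(self):
        m = build_pwm_from_consensus("ACATGT", epsilon=0.0)
        assert m.width == 6
        assert m.matrix[0] == (1.0, 0.0, 0.0, 0.0)

    def test_n_columns_uniform(self):
        m = build_pwm_from_consensus("ACAnnTGT")
        assert m.width == 8
        assert m.matrix[3] == (0.25, 0.25, 0.25, 0.25)
        assert m.matrix[4] == (0.25, 0.25, 0.25, 0.25)

    def test_epsilon_spread(self):
        m = build_pwm_from_consensus("ACATGT", epsilon=0.01)
        np.testing.assert_allclose(m.matrix[0], (0.97, 0.01, 0.01, 0.01))

    def test_invalid_character(self):
        with pytest.raises(ValueError, match="IUPAC"):
            build_pwm_from_consensus("ACXTGT")

    @pytest.mark.parametrize("consensus", ["ACATGT", "ACAnnTGT"])
    def test_irx_motifs_are_rc_palindromes(self, consensus):
        assert build_pwm_from_consensus(consensus).is_rc_palindrome()


class TestMemeReader:
    def _write(self, tmp_path, rows, alength=4, w=None):
        w = w if w is not None else len(rows)
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF TEST\n"
            f"letter-probability matrix: alength= {alength} w= {w} nsites= 20 E= 0\n"
            + "\n".join("  ".join(f"{x:.6f}" for x in r) for r in rows)
            + "\n"
        )
        p = tmp_path / "m.meme"
        p.write_text(text)
        return p

    def test_reads_width_6(self, tmp_path):
        rows = [[1, 0, 0, 0], [0, 1, 0, 0], [1, 0, 0, 0],
                [0, 0, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]]
        (m,) = read_pwm_meme(self._write(tmp_path, rows))
        assert m.width == 6
        assert m.name == "TEST"

    def test_small_deviation_renormalized(self, tmp_path):
        rows = [[0.2495, 0.2495, 0.25, 0.25]]
        (m,) = read_pwm_meme(self._write(tmp_path, rows))
        assert abs(sum(m.matrix[0]) - 1.0) < 1e-12

    def test_large_deviation_rejected(self, tmp_path):
        rows = [[0.2, 0.2, 0.25, 0.25]]
        with pytest.raises(ValueError, match="sums to"):
            read_pwm_meme(self._write(tmp_path, rows))


class TestLogOdds:
    def test_uniform_motif_scores_zero(self):
        m = Motif("u", ((0.25, 0.25, 0.25, 0.25),))
        assert log_odds_score(m, UNIFORM, "A") == 0.0

    def test_perfect_consensus_match(self):
        m = build_pwm_from_consensus("ACATGT")
        assert log_odds_score(m, UNIFORM, "ACATGT") == pytest.approx(12.0)

    def test_mismatch_is_minus_infinity(self):
        m = build_pwm_from_consensus("ACATGT")
        assert log_odds_score(m, UNIFORM, "ACATGA") == float("-inf")

    def test_word_with_n_is_minus_infinity(self):
        m = build_pwm_from_consensus("ACATGT", epsilon=0.01)
        assert log_odds_score(m, UNIFORM, "ACANGT") == float("-inf")


class TestPvalueTable:
    def test_uniform_width1_p_is_one(self):
        m = Motif("u", ((0.25, 0.25, 0.25, 0.25),))
        t = score_pvalue_table(m, UNIFORM)
        assert t.pvalue_of_score(0.0) == 1.0

    def test_strict_consensus_max_score_pvalue(self):
        m = build_pwm_from_consensus("ACATGT")
        t = score_pvalue_table(m, UNIFORM)
        assert t.pvalue_of_score(t.max_score) == pytest.approx(1 / 4096, abs=0)

    @pytest.mark.parametrize("width", [1, 2, 3])
    def test_matches_exhaustive_enumeration(self, width, rng):
        for _ in range(5):
            m = random_motif(rng, width)
            t = score_pvalue_table(m, UNIFORM)
            expected = enumerate_pvalues(t, UNIFORM.as_array())
            got = {k: t.pvalue_of_int(k) for k in expected}
            for k in expected:
                assert got[k] == pytest.approx(expected[k], rel=1e-9, abs=1e-15)

    def test_table_non_increasing_and_bounded(self, rng):
        m = random_motif(rng, 5)
        t = score_pvalue_table(m, UNIFORM)
        s = np.asarray(t.survival)
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all(s > 0) and np.all(s <= 1.0)
        assert t.pvalue_of_int(0) == pytest.approx(1.0)

    def test_all_zero_column_rejected(self):
        m = Motif("z", ((0.0, 0.0, 0.5, 0.5), (1.0, 0.0, 0.0, 0.0)))
        bad = Motif.__new__(Motif)
        object.__setattr__(bad, "name", "bad")
        object.__setattr__(bad, "matrix", ((0.0, 0.0, 0.0, 0.0), (1.0, 0.0, 0.0, 0.0)))
        object.__setattr__(bad, "source", "")
        object.__setattr__(bad, "consensus", None)
        with pytest.raises(ValueError, match="all-zero"):
            score_pvalue_table(bad, UNIFORM)
        score_pvalue_table(m, UNIFORM)  # partial zeros are fine


class TestScan:
    def test_all_n_chromosome_has_no_hits(self):
        g = GenomeSequence({"c": "N" * 100})
        m = build_pwm_from_consensus("ACATGT")
        assert scan_sequences(g, m, p_threshold=1.0) == []

    def test_palindromic_hit_deduplicated(self):
        g = GenomeSequence({"c": "GGACATGTGG"})
        m = build_pwm_from_consensus("ACATGT")
        (hit,) = scan_sequences(g, m, p_threshold=1.0)
        assert (hit.interval.start, hit.interval.end) == (2, 8)
        assert hit.interval.strand == "."

    def test_iupac_exact_degenerate_consensus(self):
        g = GenomeSequence({"c": "TTACAGGTGTTT"})
        (hit,) = scan_iupac_exact(g, "ACAnnTGT")
        assert (hit.interval.start, hit.interval.end) == (2, 10)

    def test_motif_wider_than_chromosome(self):
        g = GenomeSequence({"c": "ACA"}, )
        m = build_pwm_from_consensus("ACATGT")
        assert scan_sequences(g, m, p_threshold=1.0) == []

    def test_threshold_monotonicity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        g = GenomeSequence({"c": seq})
        m = random_motif(rng, 5)
        spans = {}
        for p in (0.001, 0.01, 0.1, 1.0):
            hits = scan_sequences(g, m, UNIFORM, p_threshold=p)
            spans[p] = {(h.interval.start, h.interval.strand) for h in hits}
        assert spans[0.001] <= spans[0.01] <= spans[0.1] <= spans[1.0]

    def test_matches_naive_window_scan(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=1_500, p=[0.24] * 4 + [0.04]))
        g = GenomeSequence({"c": seq})
        for width in (3, 5):
            m = random_motif(rng, width, zeros=True)
            t = score_pvalue_table(m, UNIFORM)
            hits = scan_sequences(g, m, UNIFORM, p_threshold=0.2, table=t)
            expected = naive_scan(
                seq, m.as_array(), UNIFORM.as_array(), t, 0.2, m.is_rc_palindrome()
            )
            got = [(h.interval.start, h.interval.strand, h.pvalue) for h in hits]
            assert sorted(got) == sorted(expected)

    def test_strand_symmetry_under_reverse_complement(self, rng):
        from tfcooc.motif_scan import reverse_complement

        seq = "".join(rng.choice(list("ACGT"), size=1_000))
        g = GenomeSequence({"c": seq})
        g_rc = GenomeSequence({"c": reverse_complement(seq)})
        m = random_motif(rng, 4)
        fwd = scan_sequences(g, m, UNIFORM, p_threshold=0.1)
        rev = scan_sequences(g_rc, m, UNIFORM, p_threshold=0.1)
        n = len(seq)
        w = m.width
        flip = {"+": "-", "-": "+", ".": "."}
        remapped = {
            (n - h.interval.end, flip[h.interval.strand], round(h.pvalue, 12))
            for h in rev
        }
        original = {
            (h.interval.start, h.interval.strand, round(h.pvalue, 12)) for h in fwd
        }
        assert remapped == original
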