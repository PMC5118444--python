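"""Translation, protein alignment, gap projection, and Nei-Gojobori dN/dS."""

import math
from itertools import product

import pytest
from Bio.Align import substitution_matrices

from cnvrkit.selection import (
    CodonSequencePair,
    align_proteins,
    compare_constraint,
    dnds_pair,
    filter_saturated,
    nei_gojobori_dnds,
    project_gaps,
    translate,
    _diff_counts,
    _site_counts,
)


class TestTranslate:
    @pytest.mark.parametrize(
        "nt, aa",
        [
            ("TTTGCT", "FA"),
            ("ATGTAA", "M"),  # terminal stop trimmed
            ("ATNGCT", "XA"),  # ambiguous codon
            ("ATGAAACTG", "MKL"),
        ],
    )
    def test_examples(self, nt, aa):
        assert translate(nt) == aa

    def test_internal_stop_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            translate("ATGTAAGCT")

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            translate("ATGA")

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            translate("ATGXYZ")


def brute_force_alignment_score(s1: str, s2: str, gap_open=10.0, gap_extend=1.0) -> float:
    """Max global alignment score by enumerating every alignment (tiny inputs).

    An alignment is scored column-wise with BLOSUM50; each maximal gap run of
    length L costs gap_open + (L - 1) * gap_extend.
    """
    blosum = substitution_matrices.load("BLOSUM50")

    def alignments(a, b):
        if not a and not b:
            yield ("", "")
            return
        if a:
            for ga, gb in alignments(a[1:], b):
                yield (a[0] + ga, "-" + gb)
        if b:
            for ga, gb in alignments(a, b[1:]):
                yield ("-" + ga, b[0] + gb)
        if a and b:
            for ga, gb in alignments(a[1:], b[1:]):
                yield (a[0] + ga, b[0] + gb)

    def score(ga, gb):
        total = 0.0
        for row in (ga, gb):
            run = 0
            for ch in row:
                if ch == "-":
                    run += 1
                else:
                    if run:
                        total -= gap_open + (run - 1) * gap_extend
                    run = 0
            if run:
                total -= gap_open + (run - 1) * gap_extend
        for x, y in zip(ga, gb):
            if x != "-" and y != "-":
                total += blosum[x][y]
        return total

    return max(score(ga, gb) for ga, gb in alignments(s1, s2))


class TestAlignment:
    def test_identical_sequences_align_gapless(self):
        blosum = substitution_matrices.load("BLOSUM50")
        a1, a2 = align_proteins("MKVLW", "MKVLW")
        assert a1 == a2 == "MKVLW"

    def test_single_residue_deletion_makes_one_gap_column(self):
        a1, a2 = align_proteins("MKV", "MV")
        assert len(a1) == 3 and a2.count("-") == 1
        assert a1.replace("-", "") == "MKV" and a2.replace("-", "") == "MV"

    @pytest.mark.parametrize("pair", [("MKV", "MV"), ("WNDG", "WDG"), ("ACDEF", "ADF")])
    def test_score_matches_enumeration_oracle(self, pair):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM50")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
        assert aligner.score(*pair) == pytest.approx(brute_force_alignment_score(*pair))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("", "MKV")


class TestProjectGaps:
    def test_gapless_alignment_reproduces_codons(self):
        pair = CodonSequencePair("g", "ATGAAACTG", "ATGAAGCTG")
        c1, c2 = project_gaps(pair, ("MKL", "MKL"))
        assert (c1, c2) == ("ATGAAACTG", "ATGAAGCTG")

    def test_aa_gap_becomes_codon_gap(self):
        pair = CodonSequencePair("g", "ATGAAACTG", "ATGCTG")
        c1, c2 = project_gaps(pair, ("MKL", "M-L"))
        assert c1 == "ATGAAACTG"
        assert c2 == "ATG---CTG"

    def test_round_trip_strips_back_to_inputs(self):
        pair = CodonSequencePair("g", "ATGAAACTGGGG", "ATGCTGGGG")
        aln = align_proteins(translate(pair.seq_query), translate(pair.seq_ortholog))
        c1, c2 = project_gaps(pair, aln)
        assert c1.replace("-", "") == pair.seq_query
        assert c2.replace("-", "") == pair.seq_ortholog

    def test_length_mismatch_rejected(self):
        pair = CodonSequencePair("g", "ATG", "ATGAAA")
        with pytest.raises(ValueError):
            project_gaps(pair, ("MK", "MK"))


class TestNeiGojobori:
    def test_identical_sequences_have_zero_rates(self):
        r = nei_gojobori_dnds(("ATGAAACTG", "ATGAAACTG"))
        assert r.dN == 0 and r.dS == 0
        assert math.isnan(r.omega)

    def test_hand_worked_synonymous_example(self):
        # one synonymous third-position difference over four codons
        r = nei_gojobori_dnds(("TTTGCTGCTGCT", "TTCGCTGCTGCT"))
        assert r.S == pytest.approx(10 / 3)
        assert r.Sd == pytest.approx(1.0)
        assert r.pS == pytest.approx(0.3)
        assert r.dS == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)
        assert r.dN == 0
        assert r.omega == 0

    def test_site_counts_conserve_three_per_codon(self):
        for codon in ("TTT", "GCT", "ATG", "TGG", "CGA"):
            s, n = _site_counts(codon)
            assert s + n == pytest.approx(3.0)

    def test_multi_hit_codon_averages_minimal_pathways(self):
        # TTT -> CTC: both orders contain one synonymous and one
        # nonsynonymous step, so the average is (1, 1)
        assert _diff_counts("TTT", "CTC") == (pytest.approx(1.0), pytest.approx(1.0))

    def test_pathways_through_stop_codons_are_discarded(self):
        # TGG -> TAT: the order via TAG (stop) is invalid, leaving the
        # all-nonsynonymous route via TGT
        assert _diff_counts("TGG", "TAT") == (pytest.approx(0.0), pytest.approx(2.0))

    def test_s_plus_n_equals_three_per_ungapped_column(self):
        a = "ATGAAACTGTTTGGG"
        b = "ATGAAGCTTTTCGGG"
        r = nei_gojobori_dnds((a, b))
        assert r.S + r.N == pytest.approx(3 * 5)

    def test_gapped_and_stop_columns_skipped(self):
        r = nei_gojobori_dnds(("ATG---TTT", "ATGAAATTC"))
        assert r.S + r.N == pytest.approx(6.0)

    def test_swap_invariance(self, rng):
        codons = [c for c in map("".join, product("ACGT", repeat=3)) if c not in ("TAA", "TAG", "TGA")]
        for _ in range(10):
            a = "".join(rng.choice(codons, size=20))
            b = "".join(rng.choice(codons, size=20))
            r1 = nei_gojobori_dnds((a, b))
            r2 = nei_gojobori_dnds((b, a))
            assert r1.dS == pytest.approx(r2.dS, nan_ok=True)
            assert r1.dN == pytest.approx(r2.dN, nan_ok=True)

    def test_saturation_flagged_and_filtered(self):
        # random-vs-random 20-codon pairs are usually saturated in pN;
        # construct a pair where every third position differs synonymously
        # beyond the correctable range is hard, so force pN high instead
        a = "ATGGCTGCTGCT"
        b = "ATGCGACGACGA"  # Ala -> Arg everywhere: pN large
        r = nei_gojobori_dnds((a, b))
        if r.saturated:
            assert math.isnan(r.omega)
            assert filter_saturated([r]) == []

    def test_no_usable_columns_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori_dnds(("---", "ATG"))


class TestCompareConstraint:
    def _result(self, gene, omega, dn=0.1, ds=0.4):
        from cnvrkit.selection import DndsResult

        return DndsResult(gene, 100.0, 200.0, 10.0, 10.0, 0.1, 0.05, ds, dn, omega, False)

    def test_fully_separated_groups_exact_p(self):
        cls = [self._result(f"c{i}", 0.5 + i / 10) for i in range(3)]
        neu = [self._result(f"n{i}", 0.1 + i / 100) for i in range(3)]
        out = compare_constraint(cls, neu, statistic="omega")
        assert out.p_one_tailed == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_undefined_and_infinite_omegas_excluded(self):
        cls = [self._result("c0", 0.5), self._result("c1", math.inf, ds=0.0)]
        neu = [self._result(f"n{i}", 0.2) for i in range(3)]
        out = compare_constraint(cls, neu, statistic="omega")
        assert out.n1 == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_constraint([], [self._result("n", 0.2)], statistic="dN")


class TestFullProtocol:
    def test_pipeline_on_diverged_pair_with_indel(self):
        q = "ATGAAATTTGCTGGGCTG"
        o = "ATGAAATTCGGGCTG"  # codon 4 deleted, codon 3 synonymous change
        r = dnds_pair(CodonSequencePair("g1", q, o))
        assert not r.saturated
        assert r.Sd >= 1.0
        assert r.S + r.N == pytest.approx(3 * 5)  # 5 ungapped codon columns

    def test_purely_synonymous_divergence_keeps_protein_fixed(self):
        from cnvrkit.simulate import SimulationConfig, simulate_ortholog_pairs

        cfg = SimulationConfig(seed=3, n_codons=100, class_omega={"neutral": 0.0})
        pairs, _ = simulate_ortholog_pairs(cfg, {f"G{i}": "neutral" for i in range(5)})
        for p in pairs:
            # every substitution the generator accepted was synonymous
            assert translate(p.seq_query) == translate(p.seq_ortholog)
            # the estimate may attribute a sliver of dN to multi-hit codons
            # whose minimal pathways pass through nonsynonymous intermediates
            r = dnds_pair(p)
            assert r.dN < 0.02
            assert r.dS > 0.2
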