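"""Folding, shuffle significance, excision, scoring, exon overlap."""

from collections import Counter

import numpy as np
import pytest

from mirpipe.hairpin import (
    HairpinCandidate,
    ScoreWeights,
    classify_exon_overlap,
    dinucleotide_shuffle,
    excise_candidates,
    fold,
    fold_oracle_enumerate,
    render_hairpin,
    score_candidate,
    shuffle_p_value,
)
from mirpipe.io import ExonRecord, Scaffold
from mirpipe.mapping import Alignment

from conftest import random_dna


class TestFold:
    def test_triloop(self):
        structure, mfe = fold("GGGAAACCC")
        assert structure == "(((...)))"
        assert mfe == -9.0

    def test_homopolymer_unpaired(self):
        structure, mfe = fold("AAAAAAAAA")
        assert structure == "." * 9
        assert mfe == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        """The DP optimum equals brute-force enumeration for short RNAs."""
        rng = np.random.default_rng(seed)
        for _ in range(8):
            n = int(rng.integers(5, 19))
            s = random_dna(rng, n)
            _, mfe = fold(s)
            assert -mfe == pytest.approx(fold_oracle_enumerate(s))

    def test_structure_well_formed(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            s = random_dna(rng, int(rng.integers(20, 80)))
            structure, _ = fold(s)
            assert len(structure) == len(s)
            stack = []
            for i, c in enumerate(structure):
                if c == "(":
                    stack.append(i)
                elif c == ")":
                    j = stack.pop()
                    assert i - j - 1 >= 3  # minimum hairpin loop
            assert not stack

    def test_n_unpairable(self):
        structure, mfe = fold("GGGNNNNNCCC")
        # Ns can only sit unpaired; G/C still pair across them
        assert mfe <= 0 and len(structure) == 11


class TestShuffle:
    def test_dinucleotide_composition_preserved(self):
        rng = np.random.default_rng(1)
        s = "ACGTACGGGCTTAGCGATCGATCGGGATCC"
        for _ in range(10):
            sh = dinucleotide_shuffle(s, rng)
            assert Counter(zip(sh, sh[1:])) == Counter(zip(s, s[1:]))
            assert sh[0] == s[0] and sh[-1] == s[-1]

    def test_inverted_repeat_significant(self):
        arm = "GCGGCCATAGCTAGCGATCGATCGCACGCG"
        hp = arm + "AAAA" + arm[::-1].translate(str.maketrans("ACGT", "TGCA"))[::-1][::-1]
        # build a clean fold-back: arm + loop + revcomp(arm)
        from mirpipe.io import revcomp

        hp = arm + "AAAA" + revcomp(arm)
        assert shuffle_p_value(hp, 99, seed=3) <= 0.05

    def test_homopolymer_p_one(self):
        assert shuffle_p_value("A" * 40, 19, seed=0) == 1.0

    def test_p_in_unit_interval_and_reproducible(self):
        rng = np.random.default_rng(4)
        s = random_dna(rng, 60)
        p1 = shuffle_p_value(s, 19, seed=5)
        p2 = shuffle_p_value(s, 19, seed=5)
        assert p1 == p2 and 0 < p1 <= 1

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError):
            shuffle_p_value("ACGTACGTACGT", 10, seed=0)


def _aln(seq, scaffold, start, strand):
    return Alignment(seq, scaffold, start, strand, 0, 1)


class TestExcision:
    def test_window_arithmetic(self):
        g = [Scaffold("s1", "A" * 300)]
        seq = "C" * 22
        alns = [_aln(seq, "s1", 100, "+")]
        wins = excise_candidates(alns, {seq: 25}, g, min_stack=5, flank_up=70, flank_down=70)
        assert wins == [("s1", 30, 121, "+"), ("s1", 100, 191, "+")]

    def test_below_min_stack_no_window(self):
        g = [Scaffold("s1", "A" * 300)]
        alns = [_aln("C" * 22, "s1", 100, "+")]
        assert excise_candidates(alns, {"C" * 22: 3}, g, min_stack=5) == []

    def test_clipped_at_scaffold_ends(self):
        g = [Scaffold("s1", "A" * 120)]
        alns = [_aln("C" * 22, "s1", 5, "+")]
        wins = excise_candidates(alns, {"C" * 22: 9}, g)
        assert all(1 <= lo <= hi <= 120 for _, lo, hi, _ in wins)

    def test_order_invariance(self):
        g = [Scaffold("s1", "A" * 500)]
        alns = [
            _aln("C" * 22, "s1", 100, "+"),
            _aln("G" * 22, "s1", 110, "+"),
            _aln("T" * 22, "s1", 400, "+"),
        ]
        counts = {"C" * 22: 5, "G" * 22: 5, "T" * 22: 9}
        assert excise_candidates(alns, counts, g) == excise_candidates(
            list(reversed(alns)), counts, g
        )

    def test_stacks_on_opposite_strands_not_merged(self):
        g = [Scaffold("s1", "A" * 300)]
        alns = [_aln("C" * 22, "s1", 100, "+"), _aln("G" * 22, "s1", 105, "-")]
        wins = excise_candidates(alns, {"C" * 22: 9, "G" * 22: 9}, g)
        strands = {w[3] for w in wins}
        assert strands == {"+", "-"}


class TestScore:
    def _cand(self, mature, star, loop, other, shuffle_p, one_arm=True, pf=0.75):
        return HairpinCandidate(
            scaffold="s", start=1, end=100, strand="+",
            precursor_seq="a" * 100, structure="." * 100, mfe_proxy=-10,
            mature_count=mature, star_count=star, loop_count=loop,
            other_count=other, shuffle_p=shuffle_p, mature_on_one_arm=one_arm,
            mature_paired_fraction=pf,
        )

    def test_clean_candidate_reported(self):
        # 95/4/1 split, significant fold, fully paired mature:
        # 2.5*log2(100/2) + 2 + 3 + 4*(1 - 0.75) = 20.11
        c = self._cand(95, 4, 1, 0, shuffle_p=0.01, pf=1.0)
        assert score_candidate(c) == pytest.approx(
            2.5 * np.log2(100 / 2) + 2 + 3 + 4 * 0.25
        )
        assert score_candidate(c) > 2

    def test_smear_rejected(self):
        # uniform smear, no star arm, insignificant fold, baseline pairing:
        # 0 + 0 - 8 + 0 = -8
        c = self._cand(50, 0, 25, 25, shuffle_p=0.5)
        assert score_candidate(c) == pytest.approx(2.5 * np.log2(51 / 51) - 8)
        assert score_candidate(c) <= 2

    def test_malformed_hairpin_penalized(self):
        good = self._cand(95, 4, 1, 0, 0.01, one_arm=True)
        bad = self._cand(95, 4, 1, 0, 0.01, one_arm=False)
        assert score_candidate(bad) == score_candidate(good) - 10

    def test_weak_stem_scores_below_strong_stem(self):
        strong = self._cand(95, 4, 1, 0, 0.01, pf=1.0)
        weak = self._cand(95, 4, 1, 0, 0.01, pf=0.6)
        assert score_candidate(strong) > score_candidate(weak)


class TestExonOverlap:
    EXONS = [ExonRecord("s1", 100, 200, "+", "g1", "exon")]

    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((120, 180), "within_exon"),
            ((90, 210), "contains_exon"),
            ((90, 150), "overlaps_exon_boundary"),
            ((150, 250), "overlaps_exon_boundary"),
            ((300, 400), "intergenic"),
        ],
    )
    def test_interval_algebra(self, interval, expected):
        call = classify_exon_overlap(("s1", *interval), self.EXONS)
        assert call.category == expected

    def test_intronic(self):
        exons = [
            ExonRecord("s1", 100, 200, "+", "g1", "exon"),
            ExonRecord("s1", 800, 900, "+", "g1", "exon"),
        ]
        assert classify_exon_overlap(("s1", 400, 500), exons).category == "intronic"

    def test_other_scaffold_is_intergenic(self):
        assert classify_exon_overlap(("s2", 120, 180), self.EXONS).category == "intergenic"


def test_render_hairpin_marks_tracks():
    c = HairpinCandidate(
        scaffold="s", start=1, end=9, strand="+",
        precursor_seq="gggaaaccc", structure="(((...)))", mfe_proxy=-9,
        mature_seq="ggg", star_seq="ccc", loop_seq="aaa",
    )
    lines = render_hairpin(c).splitlines()
    assert lines[3] == "MMMLLLSSS"
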