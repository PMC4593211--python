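"""Collapsing and mapping, checked against brute-force oracles."""

import numpy as np
import pytest

from mirpipe.io import Scaffold, revcomp
from mirpipe.mapping import (
    CollapsedRead,
    KmerIndex,
    filter_and_collapse,
    map_collapsed_reads,
)

from conftest import random_dna


class TestFilterAndCollapse:
    def test_length_rule(self):
        reads = {"L1": ["ACGTACGTACGTACGTA"] * 3 + ["ACGT"] * 5}
        collapsed, summary = filter_and_collapse(reads)
        assert len(collapsed) == 1
        assert collapsed[0].counts == {"L1": 3}
        row = summary.iloc[0]
        assert (row.total_reads, row.usable_reads, row.unique_sequences) == (8, 3, 1)

    def test_counts_preserved_across_libraries(self):
        seq = "ACGTACGTACGTACGTA"
        collapsed, _ = filter_and_collapse({"L1": [seq] * 2, "L2": [seq] * 7})
        assert collapsed[0].counts == {"L1": 2, "L2": 7}
        assert collapsed[0].total_count == 9

    def test_zero_usable_library_warns_but_kept(self):
        with pytest.warns(UserWarning, match="zero usable"):
            _, summary = filter_and_collapse({"L1": ["ACG"], "L2": ["A" * 20]})
        assert summary.set_index("library_id").loc["L1", "usable_reads"] == 0

    def test_planted_short_fraction_recovered(self):
        """A 4.7 % sub-length fraction leaves ~95.3 % usable."""
        rng = np.random.default_rng(0)
        reads = [random_dna(rng, 22) for _ in range(953)] + [
            random_dna(rng, 12) for _ in range(47)
        ]
        _, summary = filter_and_collapse({"L1": reads})
        assert summary.iloc[0].usable_reads / summary.iloc[0].total_reads == pytest.approx(0.953)


class TestKmerIndex:
    def test_self_word_found(self):
        g = [Scaffold("s1", "ACGTACGTACGTACGTAC")]
        idx = KmerIndex(g, word=18)
        assert idx.find("ACGTACGTACGTACGTAC") == [("s1", 1, "+")]

    def test_reverse_complement_found_on_minus(self):
        g = [Scaffold("s1", "ACGTACGTACGTACGTAC")]
        idx = KmerIndex(g, word=18)
        assert idx.find(revcomp("ACGTACGTACGTACGTAC")) == [("s1", 1, "-")]

    def test_absent_word_empty(self):
        idx = KmerIndex([Scaffold("s1", "A" * 30)], word=18)
        assert idx.find("C" * 18) == []

    def test_small_word_rejected(self):
        with pytest.raises(ValueError):
            KmerIndex([Scaffold("s1", "A" * 30)], word=7)


def _oracle_loci(read, genome, seed_len=18, max_tail=2):
    """Brute-force scan of every genomic window on both strands."""
    out = {}
    L, k = len(read), min(seed_len, len(read))
    for sc in genome:
        s = sc.sequence
        for strand in "+-":
            q = read if strand == "+" else revcomp(read)
            for i in range(len(s) - L + 1):
                w = s[i : i + L]
                if strand == "+":
                    if w[:k] != q[:k]:
                        continue
                    mm = sum(a != b for a, b in zip(w[k:], q[k:]))
                else:
                    if w[L - k :] != q[L - k :]:
                        continue
                    mm = sum(a != b for a, b in zip(w[: L - k], q[: L - k]))
                if mm <= max_tail:
                    out[(sc.name, i + 1, strand)] = mm
    return out


class TestMapper:
    def test_unique_exact_read(self, toy_genome):
        idx = KmerIndex(toy_genome, word=17)
        seq = toy_genome[0].sequence[100:122]
        res = map_collapsed_reads([CollapsedRead(seq, {"L": 1})], idx)
        (a,) = res.alignments
        assert (a.scaffold, a.start, a.strand, a.mismatches, a.n_hits) == ("t1", 101, "+", 0, 1)

    def test_tail_mismatch_tolerated_seed_mismatch_not(self, toy_genome):
        idx = KmerIndex(toy_genome, word=17)
        base = toy_genome[0].sequence[200:222]
        tail_mut = base[:19] + ("A" if base[19] != "A" else "C") + base[20:]
        res = map_collapsed_reads([CollapsedRead(tail_mut, {"L": 1})], idx)
        assert res.alignments and res.alignments[0].mismatches == 1
        seed_mut = ("A" if base[0] != "A" else "C") + base[1:]
        res2 = map_collapsed_reads([CollapsedRead(seed_mut, {"L": 1})], idx)
        assert not res2.alignments or res2.alignments[0].start != 201

    def test_three_tail_mismatches_unmapped(self, toy_genome):
        idx = KmerIndex(toy_genome, word=17)
        base = list(toy_genome[0].sequence[300:322])
        for p in (18, 19, 21):
            base[p] = "A" if base[p] != "A" else "C"
        res = map_collapsed_reads([CollapsedRead("".join(base), {"L": 1})], idx)
        assert [a for a in res.alignments if a.start == 301] == []

    def test_multicopy_read_dropped(self):
        rng = np.random.default_rng(3)
        insert = random_dna(rng, 22)
        parts = []
        for _ in range(6):
            parts.append(random_dna(rng, 400))
            parts.append(insert)
        g = [Scaffold("s1", "".join(parts) + random_dna(rng, 400))]
        idx = KmerIndex(g, word=17)
        res = map_collapsed_reads([CollapsedRead(insert, {"L": 9})], idx, max_hits=5)
        assert res.dropped and res.dropped[0].sequence == insert
        res6 = map_collapsed_reads([CollapsedRead(insert, {"L": 9})], idx, max_hits=6)
        assert res6.alignments and res6.alignments[0].n_hits == 6

    def test_equivalence_with_bruteforce_oracle(self, toy_genome):
        """Candidate locus sets equal the exhaustive <=2-mismatch scan."""
        rng = np.random.default_rng(17)
        idx = KmerIndex(toy_genome, word=17)
        reads = []
        for _ in range(40):
            sc = toy_genome[rng.integers(len(toy_genome))]
            L = int(rng.integers(17, 29))
            p = int(rng.integers(0, len(sc) - L))
            r = sc.sequence[p : p + L]
            if rng.integers(2):
                r = revcomp(r)
            r = list(r)
            for _ in range(int(rng.integers(0, 4))):
                q = int(rng.integers(0, L))
                r[q] = "ACGT"[rng.integers(4)]
            reads.append("".join(r))
        reads += [random_dna(rng, int(rng.integers(17, 29))) for _ in range(10)]
        from mirpipe.mapping import _candidate_loci

        for r in reads:
            mine = {(sc, pos, st): mm for sc, pos, st, mm in _candidate_loci(r, idx, 18, 2)}
            assert mine == _oracle_loci(r, toy_genome)

    def test_order_invariance_and_count_conservation(self, toy_genome):
        rng = np.random.default_rng(23)
        reads = []
        for i in range(30):
            sc = toy_genome[0]
            p = int(rng.integers(0, len(sc) - 22))
            reads.append(CollapsedRead(sc.sequence[p : p + 22], {"L": int(rng.integers(1, 9))}))
        reads.append(CollapsedRead(random_dna(rng, 22), {"L": 4}))
        idx = KmerIndex(toy_genome, word=17)
        fwd = map_collapsed_reads(reads, idx)
        rev = map_collapsed_reads(list(reversed(reads)), idx)
        assert fwd.alignments == rev.alignments
        total = sum(r.total_count for r in reads)
        mapped = {a.sequence for a in fwd.alignments}
        got = (
            sum(r.total_count for r in reads if r.sequence in mapped)
            + sum(r.total_count for r in fwd.unmapped)
            + sum(r.total_count for r in fwd.dropped)
        )
        assert got == total
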