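"""Length filtering, read collapsing, and seed-and-extend genome mapping.

The mapper emulates the classic short-read stringency used for small-RNA
discovery: an exact 18-nt 5' seed (0 mismatches), up to two substitutions in
the tail beyond the seed, reads hitting more than ``max_hits`` genomic loci
dropped outright, and only the single best alignment reported per read.
Substitutions only — small-RNA mapping does not tolerate indels at this
read length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import Scaffold, revcomp

__all__ = [
    "CollapsedRead",
    "Alignment",
    "MappingResult",
    "filter_and_collapse",
    "KmerIndex",
    "map_collapsed_reads",
]


@dataclass
class CollapsedRead:
    """A unique small-RNA sequence with its count in every library."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Alignment:
    """The reported (best) genomic placement of one collapsed read."""

    sequence: str
    scaffold: str
    start: int  # 1-based, leftmost genomic position of the read on + coords
    strand: str
    mismatches: int
    n_hits: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


def filter_and_collapse(
    reads_by_library: Mapping[str, Iterable[str]], min_len: int = 17
) -> tuple[list[CollapsedRead], pd.DataFrame]:
    """Drop reads below ``min_len`` and merge identical sequences.

    Collapsing happens across libraries with per-library counts preserved, so
    one unique sequence carries its full count vector.  The summary frame has
    one row per library: total reads, usable reads (>= min_len), and the number
    of unique usable sequences seen in that library.
    """
    collapsed: dict[str, CollapsedRead] = {}
    rows = []
    for lib_id, reads in reads_by_library.items():
        total = 0
        usable = 0
        uniq: set[str] = set()
        for seq in reads:
            total += 1
            if len(seq) < min_len:
                continue
            usable += 1
            uniq.add(seq)
            cr = collapsed.get(seq)
            if cr is None:
                cr = collapsed[seq] = CollapsedRead(seq)
            cr.counts[lib_id] = cr.counts.get(lib_id, 0) + 1
        rows.append(
            {
                "library_id": lib_id,
                "total_reads": total,
                "usable_reads": usable,
                "unique_sequences": len(uniq),
            }
        )
        if usable == 0:
            import warnings

            warnings.warn(f"library {lib_id!r} has zero usable reads")
    # deterministic order regardless of input ordering
    out = [collapsed[s] for s in sorted(collapsed)]
    return out, pd.DataFrame(rows)


class KmerIndex:
    """Exact k-mer lookup over a genome, searchable on both strands.

    Forward-strand words are indexed; minus-strand occurrences are resolved at
    query time by looking up the reverse complement, so every word occurrence
    on either strand is retrievable as ``(scaffold, start, strand)`` with
    ``start`` the 1-based leftmost position on forward coordinates.
    """

    def __init__(self, genome: Sequence[Scaffold], word: int = 18):
        if word < 8:
            raise ValueError("index word size below 8 would blow up the index")
        if not genome:
            raise ValueError("cannot index an empty genome")
        self.word = word
        self.scaffolds = {s.name: s for s in genome}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for s in genome:
            seq = s.sequence
            for i in range(len(seq) - word + 1):
                kmer = seq[i : i + word]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((s.name, i + 1))

    def find(self, word: str, both_strands: bool = True) -> list[tuple[str, int, str]]:
        """All occurrences of ``word``; minus-strand hits are positions where
        the reverse complement of ``word`` lies on the forward strand."""
        if len(word) != self.word:
            raise ValueError(f"query length {len(word)} != index word {self.word}")
        hits = [(sc, pos, "+") for sc, pos in self._index.get(word, [])]
        if both_strands:
            rc = revcomp(word)
            hits += [(sc, pos, "-") for sc, pos in self._index.get(rc, [])]
        return hits


def _count_mismatches(a: str, b: str, budget: int) -> int:
    """Mismatches between equal-length strings, early exit past budget."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return mm
    return mm


@dataclass
class MappingResult:
    alignments: list[Alignment]
    unmapped: list[CollapsedRead]
    dropped: list[CollapsedRead]  # multiplicity above max_hits


def _candidate_loci(
    read: str,
    index: KmerIndex,
    seed_len: int,
    max_tail_mismatch: int,
) -> list[tuple[str, int, str, int]]:
    """All (scaffold, start, strand, mismatches) loci with an exact 5' seed and
    at most ``max_tail_mismatch`` substitutions beyond it."""
    L = len(read)
    k = min(seed_len, L)
    word = index.word
    loci: dict[tuple[str, int, str], int] = {}
    if k < word:
        # read shorter than the index word: scan candidate words that extend
        # the whole-read seed (only possible when the whole read is the seed)
        raise ValueError(
            f"read length {L} below index word size {word}; rebuild the index "
            f"with word <= min read length"
        )
    seed = read[:k]
    tail = read[k:]
    # plus strand: seed word at its 5' end anchors the read
    for sc, pos, strand in index.find(seed[:word], both_strands=False):
        scaffold = index.scaffolds[sc]
        start, end = pos, pos + L - 1
        if end > len(scaffold):
            continue
        window = scaffold.subseq(start, end)
        if window[:k] != seed:
            continue
        mm = _count_mismatches(window[k:], tail, max_tail_mismatch)
        if mm <= max_tail_mismatch:
            loci[(sc, start, "+")] = mm
    # minus strand: the reverse complement of the read lies on forward coords;
    # the read's 5' seed maps to the 3' end of that window
    rc = revcomp(read)
    rc_seed_word = rc[L - word :]  # revcomp of the first `word` nt of the read
    for sc, pos, strand in index.find(rc_seed_word, both_strands=False):
        scaffold = index.scaffolds[sc]
        start = pos - (L - word)
        end = start + L - 1
        if start < 1 or end > len(scaffold):
            continue
        window = scaffold.subseq(start, end)
        if window[L - k :] != rc[L - k :]:  # exact seed on read coordinates
            continue
        mm = _count_mismatches(window[: L - k], rc[: L - k], max_tail_mismatch)
        if mm <= max_tail_mismatch:
            loci[(sc, start, "-")] = mm
    return [(sc, pos, st, mm) for (sc, pos, st), mm in loci.items()]


def map_collapsed_reads(
    reads: Iterable[CollapsedRead],
    index: KmerIndex,
    max_seed_mismatch: int = 0,
    seed_len: int = 18,
    max_tail_mismatch: int = 2,
    max_hits: int = 5,
) -> MappingResult:
    """Map collapsed reads under the discovery stringency.

    The 5' prefix of length ``min(seed_len, read length)`` must match exactly
    (a 17-nt read is its own seed); the remaining tail tolerates up to
    ``max_tail_mismatch`` substitutions.  Reads with more than ``max_hits``
    qualifying loci are dropped entirely; otherwise the single best alignment
    is reported — fewest mismatches, ties broken by (scaffold, start, strand)
    with '+' before '-'.
    """
    if max_seed_mismatch != 0:
        raise NotImplementedError("the seed is exact by design")
    alignments: list[Alignment] = []
    unmapped: list[CollapsedRead] = []
    dropped: list[CollapsedRead] = []
    strand_rank = {"+": 0, "-": 1}
    for read in sorted(reads, key=lambda r: r.sequence):
        loci = _candidate_loci(read.sequence, index, seed_len, max_tail_mismatch)
        if not loci:
            unmapped.append(read)
            continue
        if len(loci) > max_hits:
            dropped.append(read)
            continue
        best = min(loci, key=lambda l: (l[3], l[0], l[1], strand_rank[l[2]]))
        alignments.append(
            Alignment(
                sequence=read.sequence,
                scaffold=best[0],
                start=best[1],
                strand=best[2],
                mismatches=best[3],
                n_hits=len(loci),
            )
        )
    return MappingResult(alignments, unmapped, dropped)
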