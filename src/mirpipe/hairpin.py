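"""Precursor excision, hairpin folding, shuffle significance, and scoring.

Folding is a Nussinov-style maximum-weight pairing (GC=3, AU=2, GU=1, minimum
hairpin loop of 3, pseudoknot-free) rather than a thermodynamic
nearest-neighbor model; its negated optimum, ``mfe_proxy``, is a unit-free
stability score where more negative means more stable.  Structural
significance is assessed against dinucleotide-preserving shuffles
(Altschul–Erickson), giving a permutation p-value.

The candidate score is a documented additive surrogate for the opaque
discovery scores of read-stack pipelines: it rewards mature-arm read
dominance and star-read support, penalizes loop/other reads and malformed
hairpins, and adds a stability bonus when the shuffle test is significant.
The retention (-50) and reporting (2) thresholds act on this scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log2
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .io import ExonRecord, Scaffold, revcomp, to_rna
from .mapping import Alignment, CollapsedRead

__all__ = [
    "PAIR_WEIGHTS",
    "fold",
    "fold_oracle_enumerate",
    "dinucleotide_shuffle",
    "shuffle_p_value",
    "excise_candidates",
    "group_alignments",
    "alignments_in_window",
    "build_candidate",
    "score_candidate",
    "classify_exon_overlap",
    "HairpinCandidate",
    "ExonOverlapCall",
    "ScoreWeights",
    "render_hairpin",
]

# DNA alphabet internally; T plays U's role.
PAIR_WEIGHTS = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "T"): 2.0, ("T", "A"): 2.0,
    ("G", "T"): 1.0, ("T", "G"): 1.0,
}
MIN_LOOP = 3


def _pair_weight(a: str, b: str) -> float:
    return PAIR_WEIGHTS.get((a, b), 0.0)


@njit(cache=True)
def _nussinov_fill(pairw: np.ndarray, n: int) -> np.ndarray:  # pragma: no cover
    """O(n^3) maximum-weight pairing fill (minimum loop enforced by the
    span offset at which pairing becomes available)."""
    W = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i + 1, j]
            if W[i, j - 1] > best:
                best = W[i, j - 1]
            if pairw[i, j] > 0:
                v = W[i + 1, j - 1] + pairw[i, j]
                if v > best:
                    best = v
            for m in range(1, span):
                v = W[i, i + m] + W[i + m + 1, j]
                if v > best:
                    best = v
            W[i, j] = best
    return W


def fold(seq: str) -> tuple[str, float]:
    """Fold a sequence into its maximum-weight pseudoknot-free structure.

    Returns a dot-bracket string of equal length and ``mfe_proxy`` (the
    negated optimal pairing weight; 0 for an unpairable sequence).  ``N`` and
    any other non-ACGU(T) character are treated as unpairable.  Intended for
    precursor-scale inputs (~40–200 nt); anything outside that range still
    folds but draws a warning.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n < 40 or n > 200:
        warnings.warn(f"folding a sequence of unusual length {n}", stacklevel=2)
    if n == 0:
        return "", 0.0
    # pair weight matrix, 0 where pairing is disallowed
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    idx = np.array([codes.get(c, 4) for c in s])
    wtab = np.zeros((5, 5))
    for (a, b), w in PAIR_WEIGHTS.items():
        wtab[codes[a], codes[b]] = w
    pairw = wtab[idx[:, None], idx[None, :]]

    W = _nussinov_fill(pairw, n)

    structure = ["."] * n
    Wl = W.tolist()
    pw = pairw.tolist()
    eps = 1e-9

    def traceback(i: int, j: int) -> None:
        while i < j:
            w = Wl[i][j]
            if w == 0:
                return
            if abs(w - Wl[i + 1][j]) <= eps:
                i += 1
                continue
            if abs(w - Wl[i][j - 1]) <= eps:
                j -= 1
                continue
            if pw[i][j] > 0 and abs(w - (Wl[i + 1][j - 1] + pw[i][j])) <= eps:
                structure[i] = "("
                structure[j] = ")"
                i += 1
                j -= 1
                continue
            for m in range(1, j - i):
                if abs(w - (Wl[i][i + m] + Wl[i + m + 1][j])) <= eps:
                    traceback(i, i + m)
                    i = i + m + 1
                    break
            else:  # pragma: no cover - DP and traceback disagree
                raise AssertionError("traceback failed")

    traceback(0, n - 1)
    return "".join(structure), -float(W[0, n - 1])


def fold_oracle_enumerate(seq: str) -> float:
    """Best pairing weight by brute-force enumeration of every valid structure.

    Exponential; independent check of :func:`fold` for short sequences
    (<= ~18 nt).  Returns the (non-negated) optimal weight.
    """
    s = seq.upper().replace("U", "T")

    def best(i: int, j: int) -> float:
        if j - i < MIN_LOOP + 1:
            return 0.0
        # position i unpaired, or paired with some k
        out = best(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            w = _pair_weight(s[i], s[k])
            if w > 0:
                out = max(out, w + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(s) - 1)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle preserving exact dinucleotide composition.

    Builds the multigraph of first-order transitions, draws a random last
    edge per vertex until the implied arborescence reaches the terminal
    character, then permutes the remaining edge lists.
    """
    s = seq.upper()
    if len(s) < 3:
        return s
    chars = sorted(set(s))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]

    for _ in range(200):
        # pick a candidate last edge for every non-terminal vertex
        lastedge: dict[str, str] = {}
        ok = True
        for c in chars:
            if c == last or not edges[c]:
                continue
            lastedge[c] = edges[c][rng.integers(len(edges[c]))]
        # check connectivity: from every vertex, following last edges reaches `last`
        for c in lastedge:
            seen = set()
            cur = c
            while cur in lastedge and cur not in seen:
                seen.add(cur)
                cur = lastedge[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - pathological composition
        return s

    shuffled_edges: dict[str, list[str]] = {}
    for c in chars:
        rest = list(edges[c])
        if c in lastedge:
            rest.remove(lastedge[c])
        perm = rng.permutation(len(rest))
        rest = [rest[k] for k in perm]
        if c in lastedge:
            rest.append(lastedge[c])
        shuffled_edges[c] = rest

    # walk the Eulerian path
    out = [s[0]]
    ptr = {c: 0 for c in chars}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled_edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def shuffle_p_value(seq: str, n_shuffles: int = 99, seed: int | np.random.Generator = 0) -> float:
    """Permutation p-value for fold stability under dinucleotide shuffling.

    p = (1 + #{shuffles at least as stable as observed}) / (n_shuffles + 1).
    Sequences too short to shuffle meaningfully (<10 nt) return 1.0.
    """
    if n_shuffles < 19:
        raise ValueError("need at least 19 shuffles for a p-value below 0.05")
    if len(seq) < 10:
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, observed = fold(seq)
        k = 0
        for _ in range(n_shuffles):
            _, m = fold(dinucleotide_shuffle(seq, rng))
            if m <= observed:
                k += 1
    return (1 + k) / (n_shuffles + 1)


def excise_candidates(
    alignments: Iterable[Alignment],
    counts: dict[str, int],
    genome: Sequence[Scaffold],
    min_stack: int = 5,
    flank_up: int = 70,
    flank_down: int = 70,
) -> list[tuple[str, int, int, str]]:
    """Excise candidate precursor windows from read stacks.

    A stack is a maximal set of overlapping same-strand alignments; stacks
    whose summed read count reaches ``min_stack`` yield two windows — the
    stack read as the 5' arm (downstream flank appended) and as the 3' arm
    (upstream flank prepended) — clipped at scaffold ends and deduplicated.
    Output is sorted, so excision is independent of alignment input order.
    """
    lengths = {s.name: len(s) for s in genome}
    by_key: dict[tuple[str, str], list[Alignment]] = {}
    for a in alignments:
        by_key.setdefault((a.scaffold, a.strand), []).append(a)
    windows: set[tuple[str, int, int, str]] = set()
    for (sc, strand), group in by_key.items():
        group.sort(key=lambda a: (a.start, a.end))
        # merge overlapping intervals into stacks
        cur: list[Alignment] = []
        cur_end = -1
        stacks: list[list[Alignment]] = []
        for a in group:
            if cur and a.start > cur_end:
                stacks.append(cur)
                cur = []
                cur_end = -1
            cur.append(a)
            cur_end = max(cur_end, a.end)
        if cur:
            stacks.append(cur)
        for stack in stacks:
            total = sum(counts.get(a.sequence, 0) for a in stack)
            if total < min_stack:
                continue
            lo = min(a.start for a in stack)
            hi = max(a.end for a in stack)
            L = lengths[sc]
            windows.add((sc, lo, min(hi + flank_down, L), strand))
            windows.add((sc, max(lo - flank_up, 1), hi, strand))
    return sorted(windows)


def group_alignments(
    alignments: Iterable[Alignment],
) -> dict[tuple[str, str], tuple[list[Alignment], list[int]]]:
    """Index alignments by (scaffold, strand), sorted by start, for fast
    window lookup via :func:`alignments_in_window`."""
    by_key: dict[tuple[str, str], list[Alignment]] = {}
    for a in alignments:
        by_key.setdefault((a.scaffold, a.strand), []).append(a)
    out = {}
    for key, group in by_key.items():
        group.sort(key=lambda a: (a.start, a.end))
        out[key] = (group, [a.start for a in group])
    return out


def alignments_in_window(
    window: tuple[str, int, int, str],
    grouped: dict[tuple[str, str], tuple[list[Alignment], list[int]]],
) -> list[Alignment]:
    """Alignments fully contained in one excised window."""
    from bisect import bisect_left

    sc, lo, hi, strand = window
    group, starts = grouped.get((sc, strand), ([], []))
    i = bisect_left(starts, lo)
    out = []
    for a in group[i:]:
        if a.start > hi:
            break
        if a.end <= hi:
            out.append(a)
    return out


@dataclass
class HairpinCandidate:
    """An excised precursor window with fold, read stacks and score."""

    scaffold: str
    start: int
    end: int
    strand: str
    precursor_seq: str  # RNA, 5'->3' on the candidate strand
    structure: str
    mfe_proxy: float
    mature_seq: str = ""
    star_seq: str = ""
    loop_seq: str = ""
    mature_count: int = 0
    star_count: int = 0
    loop_count: int = 0
    other_count: int = 0
    score: float = 0.0
    shuffle_p: float = 1.0
    mature_on_one_arm: bool = True
    mature_offset: int = 0  # 0-based start of the mature block on the precursor
    hairpin_seq: str = ""  # trimmed fold-back core (mature..star span), RNA
    mature_paired_fraction: float = 0.0  # of mature bases paired in the fold

    @property
    def total_count(self) -> int:
        return self.mature_count + self.star_count + self.loop_count + self.other_count

    @property
    def locus_id(self) -> str:
        return f"{self.scaffold}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class ScoreWeights:
    """Tunable components of the surrogate discovery score."""

    signal_to_noise: float = 2.5
    star_bonus: float = 2.0
    stability_bonus: float = 3.0
    instability_penalty: float = -8.0
    malformed_penalty: float = -10.0
    # stem term: rewards the mature arm pairing beyond what an arbitrary
    # block in a maximum-pairing fold achieves anyway (the baseline)
    pairing_bonus: float = 4.0
    pairing_baseline: float = 0.75
    stability_alpha: float = 0.05


def _star_like(read_seq: str, mature_dna: str, min_identity: float = 0.7,
               min_overlap: int = 15, max_offset: int = 6) -> bool:
    """Does a read look like the mature's star partner?

    A star read is (near-)reverse-complementary to the mature; both
    sequences here are on the precursor strand, so the test is identity to
    revcomp(mature) over the best ungapped offset within the usual duplex
    overhang range."""
    target = revcomp(mature_dna)
    for off in range(-max_offset, max_offset + 1):
        lo = max(0, off)
        hi = min(len(read_seq), off + len(target))
        if hi - lo < min_overlap:
            continue
        matches = sum(read_seq[i] == target[i - off] for i in range(lo, hi))
        if matches / (hi - lo) >= min_identity:
            return True
    return False


def _arm_of(position: int, structure: str) -> str:
    """Which arm a position sits on: '5' (opens), '3' (closes), 'L' (loop)."""
    # find the innermost pairing span: last '(' before first ')'
    open_idx = [i for i, c in enumerate(structure) if c == "("]
    close_idx = [i for i, c in enumerate(structure) if c == ")"]
    if not open_idx or not close_idx:
        return "L"
    loop_lo, loop_hi = max(i for i in open_idx if i < close_idx[0]), close_idx[0]
    if position <= loop_lo:
        return "5"
    if position >= loop_hi:
        return "3"
    return "L"


def build_candidate(
    window: tuple[str, int, int, str],
    alignments: Iterable[Alignment],
    reads: dict[str, CollapsedRead],
    genome: Sequence[Scaffold],
    weights: ScoreWeights = ScoreWeights(),
    n_shuffles: int = 0,
    shuffle_seed: int = 0,
    score_prefilter: float = -50.0,
) -> HairpinCandidate | None:
    """Fold one excised window and assign read stacks to mature/star/loop.

    The mature block is the contiguous run of overlapping reads with the
    highest summed count; the star block is the best-supported block on the
    opposite arm; everything else counts as loop/other.  The shuffle test is
    run only when ``n_shuffles`` > 0 and the candidate's pre-stability score
    clears ``score_prefilter`` (the permanent-rejection threshold), since the
    shuffle is the expensive step.
    """
    sc, lo, hi, strand = window
    scaffold = {s.name: s for s in genome}[sc]
    dna = scaffold.subseq(lo, hi)
    if strand == "-":
        dna = revcomp(dna)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure, mfe = fold(dna)

    # project alignments into precursor coordinates (0-based on the candidate strand)
    inside = [
        a
        for a in alignments
        if a.scaffold == sc and a.strand == strand and a.start >= lo and a.end <= hi
    ]

    def to_precursor(a: Alignment) -> tuple[int, int]:
        if strand == "+":
            return a.start - lo, a.end - lo
        return hi - a.end, hi - a.start

    mature_seq = star_seq = loop_seq = ""
    mature_count = star_count = loop_count = other_count = 0
    mature_arm = None
    mature_on_one_arm = True
    mature_off = 0
    core_lo = core_hi = None
    mature_paired_fraction = 0.0
    partners: list[int] = []
    if inside:
        # the highest-count read defines the mature block; everything else is
        # assigned by position: overlapping the mature -> mature (isomiR
        # wobble), opposite arm -> star, loop region -> loop, else other
        top = max(
            inside,
            key=lambda a: (reads[a.sequence].total_count, -a.start, a.sequence),
        )
        m_lo, m_hi = to_precursor(top)
        mature_off = m_lo
        mature_seq = dna[m_lo : m_hi + 1]
        core_lo, core_hi = m_lo, m_hi
        arm_lo, arm_hi = _arm_of(m_lo, structure), _arm_of(m_hi, structure)
        mature_arm = arm_lo if arm_lo == arm_hi else None
        mature_on_one_arm = mature_arm in {"5", "3"}

        # where do the mature bases pair?  the partner region is where a
        # genuine star read must sit, and the partner density scores the stem
        pair_of: dict[int, int] = {}
        open_stack: list[int] = []
        for i, ch in enumerate(structure):
            if ch == "(":
                open_stack.append(i)
            elif ch == ")":
                j = open_stack.pop()
                pair_of[i] = j
                pair_of[j] = i
        partners = [pair_of[i] for i in range(m_lo, m_hi + 1) if i in pair_of]
        mature_paired_fraction = len(partners) / max(1, len(mature_seq))

        star_best = None
        star_best_count = 0
        for a in inside:
            b_lo, b_hi = to_precursor(a)
            cnt = reads[a.sequence].total_count
            if not (b_hi < m_lo or b_lo > m_hi):
                mature_count += cnt
                continue
            read_on_precursor = dna[b_lo : b_hi + 1]
            if _star_like(read_on_precursor, mature_seq):
                star_count += cnt
                if cnt > star_best_count:
                    star_best, star_best_count = (b_lo, b_hi), cnt
            elif _arm_of((b_lo + b_hi) // 2, structure) == "L":
                loop_count += cnt
                if not loop_seq:
                    loop_seq = dna[b_lo : b_hi + 1]
            else:
                other_count += cnt
        if star_best is not None:
            star_seq = dna[star_best[0] : star_best[1] + 1]
            core_lo = min(core_lo, star_best[0])
            core_hi = max(core_hi, star_best[1])

    # trimmed fold-back core: mature through star when star reads exist;
    # otherwise through the mature's pairing partners (if they form a
    # compact precursor-scale region); last resort, a loop-side margin
    if core_lo is None:
        hairpin_core = ""
    elif star_seq:
        hairpin_core = dna[core_lo : core_hi + 1]
    else:
        span = None
        if mature_paired_fraction >= 0.5:
            p_lo, p_hi = min(partners), max(partners)
            lo2, hi2 = min(core_lo, p_lo), max(core_hi, p_hi)
            if hi2 - lo2 + 1 <= 120:
                span = (lo2, hi2)
        if span is not None:
            hairpin_core = dna[span[0] : span[1] + 1]
        elif mature_arm == "3":  # loop side is upstream of a 3'-arm mature
            hairpin_core = dna[max(0, core_lo - 40) : core_hi + 1]
        else:
            hairpin_core = dna[core_lo : min(len(dna), core_hi + 40)]

    cand = HairpinCandidate(
        scaffold=sc,
        start=lo,
        end=hi,
        strand=strand,
        precursor_seq=to_rna(dna),
        structure=structure,
        mfe_proxy=mfe,
        mature_seq=to_rna(mature_seq),
        star_seq=to_rna(star_seq),
        loop_seq=to_rna(loop_seq),
        mature_count=mature_count,
        star_count=star_count,
        loop_count=loop_count,
        other_count=other_count,
        mature_on_one_arm=mature_on_one_arm,
        mature_offset=mature_off,
        hairpin_seq=to_rna(hairpin_core),
        mature_paired_fraction=mature_paired_fraction,
    )
    cand.score = score_candidate(cand, weights)
    if n_shuffles > 0 and cand.score > score_prefilter:
        cand.shuffle_p = shuffle_p_value(dna, n_shuffles, shuffle_seed)
        cand.score = score_candidate(cand, weights)
    return cand


def score_candidate(candidate: HairpinCandidate, weights: ScoreWeights = ScoreWeights()) -> float:
    """Additive surrogate discovery score.

    signal-to-noise term + star bonus + stability bonus/penalty + malformed
    penalty; see the module docstring for the rationale of each component.
    """
    signal = candidate.mature_count + candidate.star_count
    noise = candidate.loop_count + candidate.other_count
    score = weights.signal_to_noise * log2((signal + 1) / (noise + 1))
    if 0 < candidate.star_count <= candidate.mature_count:
        score += weights.star_bonus
    if candidate.shuffle_p <= weights.stability_alpha:
        score += weights.stability_bonus
    else:
        score += weights.instability_penalty
    score += weights.pairing_bonus * (
        candidate.mature_paired_fraction - weights.pairing_baseline
    )
    if not candidate.mature_on_one_arm:
        score += weights.malformed_penalty
    return score


@dataclass(frozen=True)
class ExonOverlapCall:
    category: str  # intergenic | intronic | within_exon | contains_exon | overlaps_exon_boundary
    gene_id: str | None = None


def classify_exon_overlap(
    candidate_interval: tuple[str, int, int],
    exons: Sequence[ExonRecord],
    ignore_strand: bool = True,
) -> ExonOverlapCall:
    """Relate a hairpin interval to annotated exons by interval algebra.

    Exon strand is ignored by default.  Precedence when several exons overlap:
    within_exon > contains_exon > overlaps_exon_boundary.  A hairpin inside a
    gene's span (min exon start to max exon end) touching no exon is intronic.
    """
    sc, lo, hi = candidate_interval
    best: str | None = None
    best_gene: str | None = None
    rank = {"within_exon": 0, "contains_exon": 1, "overlaps_exon_boundary": 2}
    gene_spans: dict[str, tuple[int, int]] = {}
    for e in exons:
        if e.scaffold != sc:
            continue
        g_lo, g_hi = gene_spans.get(e.gene_id, (e.start, e.end))
        gene_spans[e.gene_id] = (min(g_lo, e.start), max(g_hi, e.end))
        if hi < e.start or lo > e.end:
            continue
        if lo >= e.start and hi <= e.end:
            cat = "within_exon"
        elif e.start >= lo and e.end <= hi:
            cat = "contains_exon"
        else:
            cat = "overlaps_exon_boundary"
        if best is None or rank[cat] < rank[best]:
            best, best_gene = cat, e.gene_id
    if best is not None:
        return ExonOverlapCall(best, best_gene)
    for gene, (g_lo, g_hi) in gene_spans.items():
        if lo >= g_lo and hi <= g_hi:
            return ExonOverlapCall("intronic", gene)
    return ExonOverlapCall("intergenic", None)


def render_hairpin(candidate: HairpinCandidate) -> str:
    """Text rendering of a candidate: sequence, structure, and an M/L/S track
    marking mature, loop and star segments."""
    seq = candidate.precursor_seq
    track = ["-"] * len(seq)

    def mark(sub: str, ch: str) -> None:
        if not sub:
            return
        pos = seq.find(sub)
        if pos >= 0:
            for i in range(pos, pos + len(sub)):
                track[i] = ch

    mark(candidate.loop_seq, "L")
    mark(candidate.star_seq, "S")
    mark(candidate.mature_seq, "M")
    return "\n".join(
        [
            f"> {candidate.locus_id} score={candidate.score:.2f} "
            f"shuffle_p={candidate.shuffle_p:.3g} mfe_proxy={candidate.mfe_proxy:.1f}",
            seq,
            candidate.structure,
            "".join(track),
        ]
    )
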