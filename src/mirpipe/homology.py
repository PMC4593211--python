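"""Homology triage against a miRNA reference and reciprocal-best-hit orthologs.

Mature queries are compared by shared exact 16-mer followed by ungapped
end-to-end comparison: a perfect match is identical full-length; a
near-perfect match tolerates one mismatch or up to a two-nucleotide length
difference (the iso-miRNA gate).  Hairpin precursors use a seed-and-extend
ungapped local alignment (match +1, mismatch -2, X-drop) with a bit-score
style threshold standing in for a near-identity E-value cutoff, followed by a
coverage rule discarding matches that leave more than 8 query bases
unaligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import revcomp, to_dna

__all__ = [
    "HomologyMatch",
    "OrthologPair",
    "match_mature",
    "match_hairpin",
    "classify_candidates",
    "reciprocal_best_hits",
]


@dataclass(frozen=True)
class HomologyMatch:
    query_id: str
    subject_id: str
    query_len: int
    subject_len: int
    aligned_len: int
    mismatches: int
    match_class: str  # perfect | near_perfect | weak | none
    score: float = 0.0


def _classify(query_len: int, subject_len: int, aligned_len: int, mismatches: int) -> str:
    if mismatches == 0 and query_len == subject_len == aligned_len:
        return "perfect"
    if mismatches <= 1 and abs(query_len - subject_len) <= 2:
        return "near_perfect"
    return "weak"


def _kmers(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i : i + k], []).append(i)
    return out


def match_mature(
    query: str,
    db: Mapping[str, str],
    word: int = 16,
    query_id: str = "query",
) -> HomologyMatch | None:
    """Best mature-sequence match found through a shared exact ``word``-mer.

    Subjects sharing no 16-mer with the query are invisible — the high word
    size is what restricts hits to nearly identical sequences.  Candidate
    offsets are compared ungapped over the full overlap; best hit by fewest
    mismatches, then longest overlap, then subject id.
    """
    q = to_dna(query)
    qk = _kmers(q, word)
    best: HomologyMatch | None = None
    for sid in sorted(db):
        s = to_dna(db[sid])
        offsets: set[int] = set()
        for i in range(len(s) - word + 1):
            w = s[i : i + word]
            for qpos in qk.get(w, ()):
                offsets.add(qpos - i)  # query offset relative to subject
        for off in sorted(offsets):
            # overlap of q aligned at offset `off` along s
            q_lo = max(0, off)
            q_hi = min(len(q), off + len(s))
            if q_hi <= q_lo:
                continue
            aligned = q_hi - q_lo
            mm = sum(
                1 for d in range(q_lo, q_hi) if q[d] != s[d - off]
            )
            cand = HomologyMatch(
                query_id, sid, len(q), len(s), aligned, mm,
                _classify(len(q), len(s), aligned, mm),
            )
            if best is None or (
                (cand.mismatches, -cand.aligned_len, cand.subject_id)
                < (best.mismatches, -best.aligned_len, best.subject_id)
            ):
                best = cand
    return best


def _extend_xdrop(q: str, s: str, qpos: int, spos: int, word: int, xdrop: float = 12.0,
                  match: float = 1.0, mismatch: float = -2.0) -> tuple[int, int, int, float, int]:
    """Ungapped X-drop extension around an exact seed.

    Classic running-max semantics: extend while the running score stays
    within ``xdrop`` of its best; the reported boundary is the best-scoring
    endpoint, with ties broken toward the longer alignment (better query
    coverage).  Returns (q_start, s_start, length, score, mismatches).
    """

    def extend(step: int) -> tuple[int, float]:
        i = qpos + (word if step > 0 else -1)
        j = spos + (word if step > 0 else -1)
        run, best_gain, best_len, n = 0.0, 0.0, 0, 0
        while 0 <= i < len(q) and 0 <= j < len(s):
            run += match if q[i] == s[j] else mismatch
            n += 1
            if run >= best_gain:
                best_gain, best_len = run, n
            elif run < best_gain - xdrop:
                break
            i += step
            j += step
        return best_len, best_gain

    best_r, gain_r = extend(+1)
    best_l, gain_l = extend(-1)
    q0 = qpos - best_l
    s0 = spos - best_l
    length = best_l + word + best_r
    score = word * match + gain_l + gain_r
    mm = sum(1 for d in range(length) if q[q0 + d] != s[s0 + d])
    return q0, s0, length, score, mm


def match_hairpin(
    query: str,
    db: Mapping[str, str],
    word: int = 16,
    min_score: float = 40.0,
    max_unaligned: int = 8,
    query_id: str = "query",
    check_revcomp: bool = True,
) -> HomologyMatch | None:
    """Best local hairpin-precursor match surviving score and coverage gates.

    ``min_score`` (match +1 / mismatch -2 units) stands in for a stringent
    E-value cutoff: a ~45-nt perfect local match passes, anything under 16 nt
    cannot.  Matches leaving more than ``max_unaligned`` query bases outside
    the aligned stretch are discarded.  Both orientations are tried and the
    better one reported.
    """
    q_fwd = to_dna(query)
    orientations = [q_fwd, revcomp(q_fwd)] if check_revcomp else [q_fwd]
    best: HomologyMatch | None = None
    for q in orientations:
        qk = _kmers(q, word)
        for sid in sorted(db):
            s = to_dna(db[sid])
            seen: set[tuple[int, int]] = set()
            for i in range(len(s) - word + 1):
                w = s[i : i + word]
                for qpos in qk.get(w, ()):
                    diag = (qpos - i, 0)
                    if diag in seen:
                        continue
                    seen.add(diag)
                    _, _, length, score, mm = _extend_xdrop(q, s, qpos, i, word)
                    if score < min_score:
                        continue
                    if len(q) - length > max_unaligned:
                        continue
                    cand = HomologyMatch(
                        query_id, sid, len(q), len(s), length, mm,
                        "perfect" if (mm == 0 and length == len(q) == len(s)) else "near_perfect",
                        score,
                    )
                    if best is None or (
                        (-cand.score, cand.mismatches, cand.subject_id)
                        < (-best.score, best.mismatches, best.subject_id)
                    ):
                        best = cand
    return best


def classify_candidates(
    candidates: Mapping[str, tuple[str, str]],
    mature_db: Mapping[str, str],
    hairpin_db: Mapping[str, str],
    word: int = 16,
    hairpin_min_score: float = 40.0,
    hairpin_max_unaligned: int = 8,
) -> dict[str, dict]:
    """Partition candidates into known / iso / novel_candidate.

    ``candidates`` maps candidate id → (mature sequence, precursor sequence).
    known: perfect mature match.  iso: near-perfect mature match, or a
    hairpin-only match surviving the score and coverage filters.
    novel_candidate: neither.  Every candidate receives exactly one label,
    with the supporting matches recorded as evidence.
    """
    out: dict[str, dict] = {}
    for cid in sorted(candidates):
        mature, precursor = candidates[cid]
        m = match_mature(mature, mature_db, word=word, query_id=cid)
        h = match_hairpin(
            precursor, hairpin_db, word=word,
            min_score=hairpin_min_score, max_unaligned=hairpin_max_unaligned,
            query_id=cid,
        )
        if m is not None and m.match_class == "perfect":
            label = "known"
        elif (m is not None and m.match_class == "near_perfect") or h is not None:
            label = "iso"
        else:
            label = "novel_candidate"
        out[cid] = {"label": label, "mature_match": m, "hairpin_match": h}
    return out


@dataclass(frozen=True)
class OrthologPair:
    species_a_id: str
    species_b_id: str
    bidirectional: bool = True


def _best_hits(queries: Mapping[str, str], db: Mapping[str, str], **kw) -> dict[str, HomologyMatch]:
    out = {}
    for qid in sorted(queries):
        hit = match_hairpin(queries[qid], db, query_id=qid, **kw)
        if hit is not None:
            out[qid] = hit
    return out


def reciprocal_best_hits(
    hairpins_a: Mapping[str, str],
    hairpins_b: Mapping[str, str],
    word: int = 16,
    min_score: float = 40.0,
    max_unaligned: int = 8,
) -> list[OrthologPair]:
    """Mutual-best hairpin matches between two species' precursor sets.

    (a, b) is emitted iff b is a's best match and a is b's best; ties inside
    ``match_hairpin`` break by higher score, fewer mismatches, then subject
    id, making the pair set symmetric in A/B.
    """
    kw = dict(word=word, min_score=min_score, max_unaligned=max_unaligned)
    a2b = _best_hits(hairpins_a, hairpins_b, **kw)
    b2a = _best_hits(hairpins_b, hairpins_a, **kw)
    pairs = []
    for aid in sorted(a2b):
        bid = a2b[aid].subject_id
        back = b2a.get(bid)
        if back is not None and back.subject_id == aid:
            pairs.append(OrthologPair(aid, bid))
    return pairs
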