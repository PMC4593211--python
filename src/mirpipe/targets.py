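"""Seed-anchored miRNA target prediction in 3'UTRs.

A candidate site must contain an exact Watson–Crick complement of the miRNA
seed (positions 2–7; extended matches at 2–8 / 1–8 upgrade the class to
7mer / 8mer).  Around each anchor the full miRNA is aligned to the site
band-free and ungapped-first with affine gaps, scoring +5 per WC pair, +2 per
G:U wobble (forbidden in the seed), −3 per mismatch, −8 gap open and −8 gap
extend, with pairs in the miRNA 3' half at half weight.  Raw scores are
rescaled so a perfect 22-mer duplex sits at ~190 on the conventional
pairing-score scale, letting the stringent reporting gates (score > 155,
duplex stability < −7) act on familiar numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import ExonRecord, Scaffold, revcomp

__all__ = ["TargetSite", "extract_utrs", "scan_targets", "duplex_score"]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}

# raw score of a perfect 22-mer duplex under the half-weight rule is 82.5;
# the rescale pins it at ~190, the conventional "strong site" magnitude
RAW_PERFECT_22 = 5.0 * (11 + 11 * 0.5)
SCALE_TO_NOMINAL = 190.0 / RAW_PERFECT_22


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    utr_start: int  # 1-based inclusive on the UTR
    utr_end: int
    pairing_score: float  # rescaled to the nominal range
    energy_proxy: float  # more negative = more stable duplex
    seed_match: str  # 6mer | 7mer | 8mer


def extract_utrs(
    annotation: Sequence[ExonRecord],
    genome: Sequence[Scaffold],
) -> dict[str, str]:
    """Splice three_prime_UTR features per gene into transcript-oriented DNA.

    Minus-strand UTRs are reverse-complemented; multi-segment UTRs are
    concatenated in transcript order.  Segments outside scaffold bounds are
    skipped with a warning.
    """
    import warnings

    scaffolds = {s.name: s for s in genome}
    by_gene: dict[str, list[ExonRecord]] = {}
    for rec in annotation:
        if rec.feature != "three_prime_UTR":
            continue
        by_gene.setdefault(rec.gene_id, []).append(rec)
    out: dict[str, str] = {}
    n_skipped = 0
    for gene in sorted(by_gene):
        segs = sorted(by_gene[gene], key=lambda r: r.start)
        strand = segs[0].strand
        pieces = []
        for seg in segs:
            sc = scaffolds.get(seg.scaffold)
            if sc is None or seg.end > len(sc) or seg.start < 1:
                n_skipped += 1
                continue
            pieces.append(sc.subseq(seg.start, seg.end))
        if not pieces:
            continue
        seq = "".join(pieces)
        out[gene] = revcomp(seq) if strand == "-" else seq
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} UTR segment(s) outside scaffold bounds")
    if not by_gene:
        warnings.warn("annotation contains no three_prime_UTR features")
    return out


def _pair_type(mirna_base: str, target_base: str) -> str:
    """Pairing between a miRNA base and the *sense* target base; the miRNA
    pairs with the target's complement, so WC means complementarity."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}.get(target_base, "N")
    if mirna_base == comp:
        return "wc"
    if (mirna_base, comp) in _GU:
        return "gu"
    return "mm"


def duplex_score(mirna: str, site: str) -> tuple[float, float, int]:
    """Score one miRNA : site duplex (miRNA 5'→3' vs site 3'→5', ungapped).

    ``site`` is the sense target subsequence, reversed so position i of the
    miRNA faces position i of the reversed site.  Returns (raw pairing
    score, energy proxy, n_wc_pairs).  The energy proxy is the negated sum of
    pair weights (GC 3, AU 2, GU 1) — a stability score, not kcal/mol.
    """
    site_rev = site[::-1]
    half = len(mirna) / 2
    raw = 0.0
    energy = 0.0
    n_wc = 0
    for i, mb in enumerate(mirna):
        if i >= len(site_rev):
            break
        tb = site_rev[i]
        kind = _pair_type(mb, tb)
        weight = 0.5 if i >= half else 1.0
        if kind == "wc":
            raw += 5.0 * weight
            n_wc += 1
            energy -= 3.0 if mb in "GC" else 2.0
        elif kind == "gu":
            raw += 2.0 * weight
            energy -= 1.0
        else:
            raw -= 3.0 * weight
    return raw, energy, n_wc


def _seed_class(mirna: str, site_rev: str) -> str | None:
    """Seed anchor test on the reversed site: positions are 0-based miRNA
    indices; seed = 2–7 (indices 1..6), 7mer extends through index 7, 8mer
    through index 0 as well.  Watson–Crick only, no wobble in the seed."""

    def wc(i: int) -> bool:
        return i < len(site_rev) and _pair_type(mirna[i], site_rev[i]) == "wc"

    if not all(wc(i) for i in range(1, 7)):
        return None
    if wc(7):
        return "8mer" if wc(0) else "7mer"
    return "6mer"


def scan_targets(
    mirna_id: str,
    mirna: str,
    utrs: Mapping[str, str],
    score_cut: float = 155.0,
    energy_cut: float = -7.0,
    window_collapse: int = 25,
) -> list[TargetSite]:
    """Scan every UTR for seed-anchored sites passing both gates.

    Anchors are exact complements of the miRNA seed (positions 2–7) on the
    sense UTR; each anchor is extended to a full-length duplex score and an
    energy proxy.  Overlapping hits within ``window_collapse`` nt keep only
    the best score per (miRNA, transcript) pair.
    """
    from .io import to_dna

    m = to_dna(mirna)
    L = len(m)
    # sense-strand anchor: complement of seed (miRNA idx 1..6), reversed
    seed = m[1:7]
    comp = str.maketrans("ACGT", "TGCA")
    anchor = seed.translate(comp)[::-1]  # 6-nt sense motif to search for
    sites: list[TargetSite] = []
    for tid in sorted(utrs):
        utr = to_dna(utrs[tid])
        found: list[TargetSite] = []
        start = utr.find(anchor)
        while start != -1:
            # miRNA position 1 (0-based) pairs with the anchor's last base;
            # the full site spans L bases ending one past the anchor end
            site_end = start + len(anchor) + 1  # 0-based exclusive; +1 covers miRNA pos 0
            site_start = site_end - L
            if site_start >= 0 and site_end <= len(utr):
                site = utr[site_start:site_end]
                raw, energy, _ = duplex_score(m, site)
                cls = _seed_class(m, site[::-1])
                if cls is not None:
                    scaled = raw * SCALE_TO_NOMINAL
                    if scaled > score_cut and energy < energy_cut:
                        found.append(
                            TargetSite(
                                mirna_id, tid, site_start + 1, site_end,
                                round(scaled, 2), energy, cls,
                            )
                        )
            start = utr.find(anchor, start + 1)
        # collapse overlapping windows, best score wins
        found.sort(key=lambda s: (-s.pairing_score, s.utr_start))
        kept: list[TargetSite] = []
        for s in found:
            if all(abs(s.utr_start - k.utr_start) >= window_collapse for k in kept):
                kept.append(s)
        sites.extend(sorted(kept, key=lambda s: s.utr_start))
    return sites
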