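"""Tandem genomic miRNA cluster detection and cross-species arrangement.

A tandem cluster is two or more miRNA loci on the same scaffold and strand
whose consecutive end-to-start gaps are at most ``max_gap`` (default 10 kb).
Cluster arrangement across species is compared on family-label sequences,
after normalizing orientation when the clusters sit on opposite strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MirnaLocus",
    "GenomicCluster",
    "detect_clusters",
    "cluster_span",
    "compare_arrangement",
    "load_bdo_mirna_loci",
]


@dataclass(frozen=True)
class MirnaLocus:
    id: str
    family: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")


@dataclass
class GenomicCluster:
    scaffold: str
    strand: str
    members: list[MirnaLocus]  # ordered by start

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster has at least two members")
        if any(m.scaffold != self.scaffold or m.strand != self.strand for m in self.members):
            raise ValueError("cluster members must share scaffold and strand")
        self.members = sorted(self.members, key=lambda m: (m.start, m.end, m.id))

    @property
    def span_bp(self) -> int:
        return max(m.end for m in self.members) - min(m.start for m in self.members)

    @property
    def span_kb(self) -> float:
        return round(self.span_bp / 1000, 1)

    @property
    def families(self) -> list[str]:
        return [m.family for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def detect_clusters(
    loci: Iterable[MirnaLocus],
    max_gap: int = 10_000,
    gap_mode: str = "end_to_start",
) -> list[GenomicCluster]:
    """Chain same-strand loci into tandem clusters.

    Loci are grouped by (scaffold, strand), sorted by start, and chained
    while the gap between consecutive loci is at most ``max_gap``; the gap is
    end-to-start by default (``gap_mode='start_to_start'`` switches to the
    looser reading).  Chains of length ≥2 become clusters, sorted by
    scaffold then start, so the result is invariant to input order.
    """
    if gap_mode not in {"end_to_start", "start_to_start"}:
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    groups: dict[tuple[str, str], list[MirnaLocus]] = {}
    for locus in loci:
        groups.setdefault((locus.scaffold, locus.strand), []).append(locus)
    clusters: list[GenomicCluster] = []
    for (sc, strand), group in groups.items():
        group.sort(key=lambda m: (m.start, m.end, m.id))
        chain = [group[0]]
        for prev, cur in zip(group, group[1:]):
            gap = (
                cur.start - prev.end
                if gap_mode == "end_to_start"
                else cur.start - prev.start
            )
            if gap <= max_gap:
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    clusters.append(GenomicCluster(sc, strand, chain))
                chain = [cur]
        if len(chain) >= 2:
            clusters.append(GenomicCluster(sc, strand, chain))
    clusters.sort(key=lambda c: (c.scaffold, c.members[0].start, c.strand))
    return clusters


def cluster_span(cluster: GenomicCluster) -> tuple[int, float]:
    """(span_bp, span_kb): distance between the most distant member ends."""
    return cluster.span_bp, cluster.span_kb


def _oriented_families(cluster: GenomicCluster, flip: bool) -> list[str]:
    fams = cluster.families
    return fams[::-1] if flip else fams


def compare_arrangement(
    cluster_a: GenomicCluster,
    cluster_b: GenomicCluster,
    family_map: Mapping[str, str] | None = None,
) -> str:
    """Compare two clusters' member arrangement on family labels.

    Returns one of identical / reversed / rearranged / partial_overlap /
    disjoint.  ``family_map`` optionally renames families onto a common
    namespace first.  Clusters on opposite strands are read in the same
    biological orientation (one is reversed) before comparison.  Equal family
    sets with differing order or multiplicity are "rearranged" (the pattern
    of duplicated-family shuffling seen in fast-evolving clusters); family
    sets that merely intersect are "partial_overlap".
    """

    def fams(cluster: GenomicCluster, flip: bool) -> list[str]:
        out = _oriented_families(cluster, flip)
        if family_map is not None:
            out = [family_map.get(f, f) for f in out]
        return out

    flip_b = cluster_a.strand != cluster_b.strand
    a = fams(cluster_a, False)
    b = fams(cluster_b, flip_b)
    set_a, set_b = set(a), set(b)
    if not (set_a & set_b):
        return "disjoint"
    if set_a != set_b:
        return "partial_overlap"
    if a == b:
        return "identical"
    if a == b[::-1]:
        return "reversed"
    return "rearranged"


def load_bdo_mirna_loci() -> pd.DataFrame:
    """The 31 clustered *B. dorsalis* miRNA loci shipped with the package
    (id, family, scaffold, 1-based coordinates, strand, mature sequence,
    mature read count)."""
    with resources.files("mirpipe.data").joinpath("bdo_mirna_loci.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def loci_from_frame(df: pd.DataFrame) -> list[MirnaLocus]:
    return [
        MirnaLocus(r.id, r.family, r.scaffold, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]
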