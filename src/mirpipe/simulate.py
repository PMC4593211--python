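"""Synthetic genomes, annotations, miRNA truth sets and stage-structured
small-RNA libraries.

The generator emulates the statistical structure of a stage-resolved insect
small-RNA experiment at desk scale: five developmental stages (egg, larva,
male pupa, female pupa, ovary) in three replicates with one replicate
unsequenced; 17–28 nt reads dominated by mature miRNA sequences with minor
star/loop fractions, ±1 nt end wobble, a few percent of reads below the
17-nt cutoff, and decoy reads from random genomic background plus a
multi-copy repeat that trips the mapping-multiplicity filter.  Hairpins are
planted singly and in tandem clusters (one cluster carries duplicated
families, mimicking fast-evolving polycistronic loci), and stage expression
follows three canonical group profiles: rising through development,
larva-peaked, and pupa-depleted/ovary-high.

Every simulated quantity traces to a truth table, and everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExonRecord, Library, SampleSheet, Scaffold, revcomp

__all__ = [
    "SimulationConfig",
    "PlantedMirna",
    "SimulatedGenome",
    "SimulatedLibraries",
    "ReferenceSet",
    "simulate_genome",
    "simulate_libraries",
    "make_reference_dbs",
    "simulate_ortholog_expression",
    "narrative_triage_fixture",
]

DEFAULT_STAGES = {"egg": 3, "larva": 3, "male_pupa": 3, "female_pupa": 3, "ovary": 3}
DEFAULT_MISSING = (("female_pupa", 2),)

# relative stage weights of the three expression group shapes
GROUP_PROFILES = {
    1: {"egg": 30.0, "larva": 120.0, "male_pupa": 260.0, "female_pupa": 260.0, "ovary": 200.0},
    2: {"egg": 40.0, "larva": 400.0, "male_pupa": 40.0, "female_pupa": 40.0, "ovary": 60.0},
    3: {"egg": 400.0, "larva": 250.0, "male_pupa": 4.0, "female_pupa": 4.0, "ovary": 450.0},
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    n_scaffolds: int = 3
    scaffold_len: int = 150_000
    n_known_mirnas: int = 20
    n_novel_mirnas: int = 5
    n_clusters: int = 2
    cluster_members: tuple[int, ...] = (8, 3)
    duplicated_family_cluster: int = 0  # index of the cluster carrying duplicates
    stages: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_STAGES))
    missing: tuple[tuple[str, int], ...] = DEFAULT_MISSING
    depth_per_library: int = 10_000
    mature_fraction: float = 0.77
    star_fraction: float = 0.08
    loop_fraction: float = 0.05
    decoy_fraction: float = 0.10
    short_fraction: float = 0.047  # of total reads, below the 17-nt cutoff
    mature_len: int = 22
    loop_len: int = 15
    singleton_spacing: int = 12_000
    cluster_gap_range: tuple[int, int] = (150, 700)
    repeat_copies: int = 6
    fold_change_grid: tuple[float, ...] = (4.0,)
    dispersion: float = 0.1
    baseline_sigma: float = 0.6

    def __post_init__(self) -> None:
        total = (
            self.mature_fraction + self.star_fraction
            + self.loop_fraction + self.decoy_fraction
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError("read-class fractions must sum to 1")
        if self.n_clusters != len(self.cluster_members):
            raise ValueError("cluster_members must list one size per cluster")

    def sample_sheet(self) -> SampleSheet:
        libs = []
        for stage, n_rep in self.stages.items():
            for rep in range(1, n_rep + 1):
                if (stage, rep) in self.missing:
                    continue
                libs.append(Library(f"{stage}_r{rep}", stage, rep))
        return SampleSheet(libs)


@dataclass
class PlantedMirna:
    id: str
    family: str
    scaffold: str
    start: int  # 1-based precursor coordinates
    end: int
    strand: str
    mature: str  # DNA, 5'->3'
    star: str
    precursor: str
    novel: bool
    cluster_id: int | None
    group: int
    baseline: float = 1.0

    @property
    def mature_genomic(self) -> tuple[int, int]:
        """Genomic interval of the mature arm (always the precursor 5' arm)."""
        L = len(self.mature)
        if self.strand == "+":
            return self.start, self.start + L - 1
        return self.end - L + 1, self.end


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _make_hairpin(rng: np.random.Generator, mature_len: int, loop_len: int) -> tuple[str, str, str]:
    """(mature, star, precursor): a perfect fold-back with the mature on the
    5' arm; one arm mismatch keeps the duplex realistic without breaking it."""
    mature = _random_dna(rng, mature_len)
    star = revcomp(mature)
    pos = int(rng.integers(3, mature_len - 3))
    alt = "ACGT".replace(star[pos], "")[rng.integers(3)]
    star = star[:pos] + alt + star[pos + 1 :]
    loop = _random_dna(rng, loop_len)
    return mature, star, mature + loop + star


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    scaffolds: list[Scaffold]
    exons: list[ExonRecord]
    planted: list[PlantedMirna]
    repeat_seq: str
    utr_target_gene: str  # gene whose 3'UTR carries a planted target site
    utr_target_mirna: str

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": p.id,
                    "family": p.family,
                    "scaffold": p.scaffold,
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                    "mature": p.mature,
                    "novel": p.novel,
                    "cluster_id": p.cluster_id,
                    "group": p.group,
                }
                for p in self.planted
            ]
        )

    def mirna(self, mid: str) -> PlantedMirna:
        return next(p for p in self.planted if p.id == mid)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build the genome: background sequence, planted hairpins (singletons and
    tandem clusters), a multi-copy repeat, and gene/exon/3'UTR features that
    exercise every exon-overlap category."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n_total = config.n_known_mirnas + config.n_novel_mirnas
    n_clustered = sum(config.cluster_members)
    if n_clustered > n_total:
        raise ValueError("more cluster members than planted miRNAs")

    # build hairpins; duplicated-family cluster members share a family/mature
    planted: list[PlantedMirna] = []
    hairpins: list[tuple[str, str, str]] = [
        _make_hairpin(rng, config.mature_len, config.loop_len) for _ in range(n_total)
    ]
    prec_len = 2 * config.mature_len + config.loop_len

    # assign ids, families, groups; novel ones are the tail
    members: list[dict] = []
    for i in range(n_total):
        novel = i >= config.n_known_mirnas
        members.append(
            {
                "id": f"sim-mir-{i + 1:03d}",
                "family": f"simfam-{i + 1:03d}",
                "novel": novel,
                "group": (i % 3) + 1,
                "hp": hairpins[i],
            }
        )

    # duplicated families inside the designated cluster: two further members
    # carry member 0's family, with paralog-style 1–2 nt mature divergence so
    # their reads still map uniquely (as real duplicated families do)
    cluster_assignment: list[list[int]] = []
    idx = 0
    for c, size in enumerate(config.cluster_members):
        cluster_assignment.append(list(range(idx, idx + size)))
        idx += size
    singles = list(range(idx, n_total))
    dup_cluster = config.duplicated_family_cluster
    if 0 <= dup_cluster < len(cluster_assignment) and len(cluster_assignment[dup_cluster]) >= 4:
        c0 = cluster_assignment[dup_cluster][0]
        base_mature = members[c0]["hp"][0]
        for k in (2, 3):
            ci = cluster_assignment[dup_cluster][k]
            members[ci]["family"] = members[c0]["family"]
            mat = list(base_mature)
            for pos in range(4, 4 + (k - 1)):  # 1 or 2 seed-region substitutions
                mat[pos] = "ACGT".replace(mat[pos], "")[rng.integers(3)]
            mat = "".join(mat)
            # one arm mismatch, as in every generated hairpin: a perfect
            # duplex would make the star read map ambiguously to both strands
            star = list(revcomp(mat))
            pos = int(rng.integers(3, len(star) - 3))
            star[pos] = "ACGT".replace(star[pos], "")[rng.integers(3)]
            star = "".join(star)
            members[ci]["hp"] = (mat, star, mat + members[c0]["hp"][2][len(mat):-len(mat)] + star)

    # lay out scaffolds: place clusters and singletons, then genes
    backgrounds = [
        list(_random_dna(rng, config.scaffold_len)) for _ in range(config.n_scaffolds)
    ]
    cursor = [2000] * config.n_scaffolds
    exons: list[ExonRecord] = []

    def plant(sc_idx: int, pos: int, member: dict, strand: str, cluster_id: int | None) -> None:
        mature, star, prec = member["hp"]
        insert = prec if strand == "+" else revcomp(prec)
        backgrounds[sc_idx][pos - 1 : pos - 1 + len(insert)] = list(insert)
        planted.append(
            PlantedMirna(
                id=member["id"],
                family=member["family"],
                scaffold=f"sim_scaffold{sc_idx + 1:02d}",
                start=pos,
                end=pos + len(insert) - 1,
                strand=strand,
                mature=mature,
                star=star,
                precursor=prec,
                novel=member["novel"],
                cluster_id=cluster_id,
                group=member["group"],
            )
        )

    # clusters: one per scaffold (round-robin), same strand within a cluster
    for c, idxs in enumerate(cluster_assignment):
        sc_idx = c % config.n_scaffolds
        strand = "-" if c % 2 else "+"
        pos = cursor[sc_idx]
        for mi in idxs:
            plant(sc_idx, pos, members[mi], strand, c)
            gap = int(rng.integers(*config.cluster_gap_range))
            pos += prec_len + gap
        cursor[sc_idx] = pos + config.singleton_spacing

    # singletons: spaced far enough apart never to chain
    for k, mi in enumerate(singles):
        sc_idx = k % config.n_scaffolds
        if cursor[sc_idx] + prec_len + 200 > config.scaffold_len:
            raise ValueError("scaffold too short for requested insertions")
        plant(sc_idx, cursor[sc_idx], members[mi], "+" if k % 3 else "-", None)
        cursor[sc_idx] += config.singleton_spacing

    # multi-copy repeat: the same 24-mer at `repeat_copies` spots
    repeat = _random_dna(rng, 24)
    for k in range(config.repeat_copies):
        sc_idx = k % config.n_scaffolds
        pos = config.scaffold_len - 3000 - 200 * k
        backgrounds[sc_idx][pos : pos + 24] = list(repeat)

    scaffolds = [
        Scaffold(f"sim_scaffold{i + 1:02d}", "".join(b))
        for i, b in enumerate(backgrounds)
    ]

    # genes exercising the exon-overlap categories, anchored on known singles
    known_singles = [p for p in planted if p.cluster_id is None and not p.novel]
    categories = ["within_exon", "contains_exon", "overlaps_exon_boundary", "intronic"]
    for g, (p, cat) in enumerate(zip(known_singles, categories)):
        gid = f"sim_gene{g + 1:02d}"
        if cat == "within_exon":
            exons.append(ExonRecord(p.scaffold, p.start - 50, p.end + 50, "+", gid))
        elif cat == "contains_exon":
            exons.append(ExonRecord(p.scaffold, p.start + 10, p.start + 30, "+", gid))
        elif cat == "overlaps_exon_boundary":
            exons.append(ExonRecord(p.scaffold, p.start + 20, p.end + 300, "+", gid))
        elif cat == "intronic":
            exons.append(ExonRecord(p.scaffold, p.start - 500, p.start - 400, "+", gid))
            exons.append(ExonRecord(p.scaffold, p.end + 400, p.end + 500, "+", gid))

    # one ordinary gene with a 3'UTR carrying a perfect target site for the
    # first planted miRNA (for target-scan recovery)
    utr_gene = ""
    target_id = ""
    if planted:
        target_mirna = planted[0]
        target_id = target_mirna.id
        utr_gene = "sim_gene_utr"
        sc0 = scaffolds[0]
        utr_start = config.scaffold_len - 1200
        site = revcomp(target_mirna.mature)
        body = list(sc0.sequence)
        body[utr_start + 49 : utr_start + 49 + len(site)] = list(site)
        scaffolds[0] = Scaffold(sc0.name, "".join(body))
        exons.append(
            ExonRecord(scaffolds[0].name, utr_start - 600, utr_start - 1, "+", utr_gene, "exon")
        )
        exons.append(
            ExonRecord(scaffolds[0].name, utr_start, utr_start + 199, "+", utr_gene,
                       "three_prime_UTR")
        )

    # per-miRNA abundance baselines (lognormal), shared across libraries
    baselines = np.exp(rng.normal(0.0, config.baseline_sigma, n_total))
    for p, b in zip(planted, baselines):
        p.baseline = float(b)

    return SimulatedGenome(
        config=config,
        scaffolds=scaffolds,
        exons=exons,
        planted=planted,
        repeat_seq=repeat,
        utr_target_gene=utr_gene,
        utr_target_mirna=target_id,
    )


@dataclass
class SimulatedLibraries:
    sheet: SampleSheet
    reads: dict[str, list[str]]  # library_id -> raw read sequences
    expected_counts: pd.DataFrame  # miRNA x library mature-read counts
    read_truth: pd.DataFrame  # per (library, class): read counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return np.round(mean).astype(int)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))


def simulate_libraries(
    sim: SimulatedGenome, config: SimulationConfig | None = None
) -> SimulatedLibraries:
    """Draw stage-structured read sets for every sequenced library.

    Mature counts are negative-binomial around the group-profile stage means
    (scaled to the usable-read budget); star/loop reads follow their
    configured fractions; decoys are unique random genomic fragments plus
    copies of the planted repeat; a configured fraction of total reads falls
    below 17 nt.  The expected count matrix holds the drawn mature counts —
    what a perfect quantifier would recover.
    """
    config = config or sim.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    sheet = config.sample_sheet()
    planted = sim.planted
    n = len(planted)

    weights = np.array(
        [[GROUP_PROFILES[p.group][s] * p.baseline for s in config.stages] for p in planted]
    )
    stage_names = list(config.stages)

    n_short = int(round(config.depth_per_library * config.short_fraction))
    usable = config.depth_per_library - n_short
    n_mature_budget = config.mature_fraction * usable

    # decoy reads are degradation-like: scattered single-copy genomic
    # fragments on either strand, avoiding planted precursor loci
    occupied: dict[str, list[tuple[int, int]]] = {}
    for p in planted:
        occupied.setdefault(p.scaffold, []).append((p.start, p.end))
    scaff_list = sim.scaffolds

    def draw_decoy(r: np.random.Generator) -> str:
        while True:
            sc = scaff_list[int(r.integers(len(scaff_list)))]
            L = int(r.integers(17, 29))
            pos = int(r.integers(1, len(sc) - L))
            if any(lo - L <= pos <= hi for lo, hi in occupied.get(sc.name, ())):
                continue
            frag = sc.subseq(pos, pos + L - 1)
            return frag if r.integers(2) == 0 else revcomp(frag)

    reads: dict[str, list[str]] = {}
    counts = np.zeros((n, len(sheet)), dtype=int)
    truth_rows = []
    for j, lib in enumerate(sheet):
        s_idx = stage_names.index(lib.stage)
        w = weights[:, s_idx]
        mean_mature = n_mature_budget * w / w.sum()
        c_mature = _nb_draw(rng, mean_mature, config.dispersion)
        counts[:, j] = c_mature
        lib_reads: list[str] = []
        star_ratio = config.star_fraction / config.mature_fraction
        loop_ratio = config.loop_fraction / config.mature_fraction
        for i, p in enumerate(planted):
            cm = int(c_mature[i])
            if cm == 0:
                continue
            # ±1 nt end wobble on the mature read
            n_trim = int(rng.binomial(cm, 0.10))
            n_ext = int(rng.binomial(cm - n_trim, 0.10))
            n_exact = cm - n_trim - n_ext
            mat = p.mature
            ext = p.precursor[: len(mat) + 1]  # one loop-side base appended
            trim = mat[:-1]
            lib_reads += [mat] * n_exact + [trim] * n_trim + [ext] * n_ext
            cs = int(rng.binomial(cm, min(star_ratio, 1.0)))
            cl = int(rng.binomial(cm, min(loop_ratio, 1.0)))
            loop_read = p.precursor[len(mat) - 3 : len(mat) - 3 + 20]
            lib_reads += [p.star] * cs + [loop_read] * cl
            truth_rows.append(
                {"library_id": lib.library_id, "mirna": p.id, "mature": cm,
                 "star": cs, "loop": cl}
            )
        # decoys: scattered unique genomic fragments + a pinch of repeat reads
        n_decoy = max(0, usable - len(lib_reads))
        n_repeat = int(round(n_decoy * 0.02))
        lib_reads += [draw_decoy(rng) for _ in range(n_decoy - n_repeat)]
        lib_reads += [sim.repeat_seq[:22]] * n_repeat
        # short reads (below the length cutoff)
        for _ in range(n_short):
            lib_reads.append(_random_dna(rng, int(rng.integers(12, 17))))
        reads[lib.library_id] = lib_reads

    expected = pd.DataFrame(
        counts, index=[p.id for p in planted], columns=sheet.library_ids
    )
    return SimulatedLibraries(sheet, reads, expected, pd.DataFrame(truth_rows))


@dataclass
class ReferenceSet:
    mature_db: dict[str, str]
    hairpin_db: dict[str, str]
    orthologs: list[tuple[str, str]]  # (sim id, reference id) truth pairs
    mutations: dict[str, int]  # reference id -> number of planted mutations


def make_reference_dbs(
    sim: SimulatedGenome,
    config: SimulationConfig | None = None,
    n_decoy_entries: int = 10,
) -> ReferenceSet:
    """Reference mature/hairpin databases for a pseudo-reference species.

    Known planted miRNAs are emitted with 0–2 substitutions cycling across
    entries (mutations sit near the sequence ends so that one shared 16-mer
    survives — the regime the word-16 search is meant to capture); novel ones
    are omitted; decoy entries are random hairpins matching nothing.
    """
    config = config or sim.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
    mature_db: dict[str, str] = {}
    hairpin_db: dict[str, str] = {}
    orthologs: list[tuple[str, str]] = []
    mutations: dict[str, int] = {}
    known = [p for p in sim.planted if not p.novel]
    seen_fam: set[str] = set()
    for k, p in enumerate(known):
        if p.family in seen_fam:
            continue  # duplicated families share one reference entry
        seen_fam.add(p.family)
        rid = f"ref-mir-{k + 1:03d}"
        n_mut = k % 3
        mat = list(p.mature)
        prec = list(p.precursor)
        ends = [0, 1, len(mat) - 1, len(mat) - 2]
        for m in range(n_mut):
            pos = ends[m]
            mat[pos] = "ACGT".replace(mat[pos], "")[rng.integers(3)]
        for m in range(n_mut):
            pos = [2, len(prec) - 3][m % 2]
            prec[pos] = "ACGT".replace(prec[pos], "")[rng.integers(3)]
        mature_db[rid] = "".join(mat)
        hairpin_db[rid] = "".join(prec)
        orthologs.append((p.id, rid))
        mutations[rid] = n_mut
    for d in range(n_decoy_entries):
        rid = f"ref-decoy-{d + 1:03d}"
        mature_db[rid] = _random_dna(rng, 22)
        hairpin_db[rid] = _random_dna(rng, 90)
    return ReferenceSet(mature_db, hairpin_db, orthologs, mutations)


def simulate_ortholog_expression(
    expr_a: pd.DataFrame,
    rho: float = 0.8,
    seed: int = 0,
    id_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """A second species' expression table rank-correlated with ``expr_a``.

    Each column of ``expr_a`` (stage-level expression of the ortholog set) is
    transformed to normal scores and mixed with Gaussian noise at the Pearson
    correlation 2·sin(π·rho/6) that induces the requested Spearman rho; the
    result is mapped back to a lognormal expression scale.  Row index is
    renamed through ``id_map`` when given.
    """
    from scipy import stats

    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    out = {}
    n = len(expr_a)
    for col in expr_a.columns:
        x = expr_a[col].to_numpy(dtype=float)
        ranks = stats.rankdata(x, method="average")
        z = stats.norm.ppf(ranks / (n + 1))
        zb = r * z + np.sqrt(max(0.0, 1 - r * r)) * rng.normal(size=n)
        out[col] = np.exp(1.2 * zb + 4.0)
    df = pd.DataFrame(out, index=expr_a.index)
    if id_map is not None:
        df.index = [id_map.get(i, i) for i in df.index]
    return df


def narrative_triage_fixture(
    sheet: SampleSheet | None = None,
) -> tuple[dict[str, dict[str, int]], dict[str, int], dict[str, bool]]:
    """The 35-candidate stratified triage fixture.

    Strata: one candidate present in every sequenced library; one absent in a
    single larva replicate only; seven present in egg/larva/ovary but absent
    in both pupa stages — of which three have low counts or no star reads and
    one a malformed hairpin; and twenty-six seen in one replicate of one
    stage, for 35 candidates in total.  Expected outcome: exactly five
    accepts.

    Returns (counts per candidate per library, star counts, hairpin_ok).
    """
    if sheet is None:
        sheet = SimulationConfig().sample_sheet()
    lib_ids = sheet.library_ids
    counts: dict[str, dict[str, int]] = {}
    star: dict[str, int] = {}
    hairpin_ok: dict[str, bool] = {}

    def base(val: int = 0) -> dict[str, int]:
        return {l: val for l in lib_ids}

    counts["cand_all"] = base(30)
    star["cand_all"] = 6
    hairpin_ok["cand_all"] = True

    c = base(15)
    c["larva_r2"] = 0
    counts["cand_one_missing"] = c
    star["cand_one_missing"] = 4
    hairpin_ok["cand_one_missing"] = True

    def stage_restricted(total_scale: int) -> dict[str, int]:
        c = base(0)
        for l in sheet:
            if l.stage in {"egg", "larva", "ovary"}:
                c[l.library_id] = total_scale
        return c

    for k in range(3):  # pass: good counts, star present, clean hairpin
        cid = f"cand_stage_pass_{k + 1}"
        counts[cid] = stage_restricted(20)
        star[cid] = 5
        hairpin_ok[cid] = True
    for k in range(3):  # R3a: low count and/or no star
        cid = f"cand_stage_lowcount_{k + 1}"
        counts[cid] = stage_restricted(1)
        star[cid] = 0
        hairpin_ok[cid] = True
    cid = "cand_stage_badhairpin"
    counts[cid] = stage_restricted(25)
    star[cid] = 6
    hairpin_ok[cid] = False

    stages = sheet.stages
    for k in range(26):  # single replicate of a single stage
        cid = f"cand_single_{k + 1:02d}"
        stage = stages[k % len(stages)]
        lib = sheet.by_stage(stage)[k % len(sheet.by_stage(stage))]
        c = base(0)
        c[lib.library_id] = 3
        counts[cid] = c
        star[cid] = 0
        hairpin_ok[cid] = True

    return counts, star, hairpin_ok
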