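"""Stage orchestration: each stage reads its upstream TSV artifacts from a
working directory and writes its own, with a provenance comment block
(config hash, seed, package version) at the top of every output.  Stages are
resumable: an existing output is left alone unless ``force`` is set."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .expression import (
    CountMatrix,
    all_pairwise_tests,
    cpm,
    hierarchical_cluster,
    log2_ratio_matrix,
    spearman_matrix,
    tmm_factors,
)
from .hairpin import (
    HairpinCandidate,
    ScoreWeights,
    alignments_in_window,
    build_candidate,
    classify_exon_overlap,
    excise_candidates,
    group_alignments,
)
from .homology import classify_candidates, reciprocal_best_hits
from .io import (
    SampleSheet,
    read_annotation,
    read_fasta_dict,
    read_genome,
    read_small_rna_reads,
    to_dna,
    to_rna,
    write_annotation,
    write_fasta,
    write_genome,
)
from .mapping import (
    Alignment,
    CollapsedRead,
    KmerIndex,
    filter_and_collapse,
    map_collapsed_reads,
)
from .clusters import MirnaLocus, compare_arrangement, detect_clusters
from .simulate import (
    SimulationConfig,
    make_reference_dbs,
    simulate_genome,
    simulate_libraries,
    simulate_ortholog_expression,
)
from .targets import extract_utrs, scan_targets
from .triage import build_presence, triage, triage_report

log = logging.getLogger("mirpipe")

STAGES = [
    "simulate", "preprocess", "map", "discover", "homology",
    "triage", "express", "clusters", "targets", "crossspecies",
]

# stage -> (produced files, producing stage of each required upstream file)
_OUTPUTS = {
    "simulate": ["genome.fa", "annotation.gff3", "sample_sheet.tsv",
                 "reference_mature.fa", "reference_hairpin.fa",
                 "truth/mirnas.tsv", "truth/expected_counts.tsv",
                 "species_b_expression.tsv"],
    "preprocess": ["collapsed_reads.tsv", "mapping_summary.tsv"],
    "map": ["alignments.tsv"],
    "discover": ["candidates.tsv"],
    "homology": ["homology.tsv"],
    "triage": ["novel_triage.tsv", "novel_mirnas.fa"],
    "express": ["counts.tsv", "de_results.tsv", "log2_ratios.tsv",
                "cluster_order.txt"],
    "clusters": ["clusters.tsv", "arrangement_report.tsv"],
    "targets": ["targets.tsv"],
    "crossspecies": ["orthologs.tsv", "spearman_grid.tsv"],
}
_UPSTREAM = {
    "preprocess": [("sample_sheet.tsv", "simulate")],
    "map": [("genome.fa", "simulate"), ("collapsed_reads.tsv", "preprocess")],
    "discover": [("alignments.tsv", "map"), ("genome.fa", "simulate"),
                 ("annotation.gff3", "simulate")],
    "homology": [("candidates.tsv", "discover"),
                 ("reference_mature.fa", "simulate"),
                 ("reference_hairpin.fa", "simulate")],
    "triage": [("homology.tsv", "homology"), ("counts.tsv", "express")],
    "express": [("candidates.tsv", "discover"), ("alignments.tsv", "map"),
                ("collapsed_reads.tsv", "preprocess")],
    "clusters": [("candidates.tsv", "discover"), ("homology.tsv", "homology"),
                 ("novel_triage.tsv", "triage")],
    "targets": [("candidates.tsv", "discover"), ("annotation.gff3", "simulate"),
                ("genome.fa", "simulate")],
    "crossspecies": [("candidates.tsv", "discover"),
                     ("reference_hairpin.fa", "simulate"),
                     ("species_b_expression.tsv", "simulate"),
                     ("counts.tsv", "express")],
}
# execution order for `run_all` (triage needs counts from express)
_ORDER = ["simulate", "preprocess", "map", "discover", "homology",
          "express", "triage", "clusters", "targets", "crossspecies"]


class MissingArtifactError(RuntimeError):
    pass


def _require(workdir: Path, stage: str) -> None:
    for fname, producer in _UPSTREAM.get(stage, []):
        if not (workdir / fname).exists():
            raise MissingArtifactError(
                f"stage {stage!r} needs {fname}, produced by stage {producer!r}; "
                f"run that stage first"
            )


def _provenance(config: PipelineConfig) -> str:
    return (
        f"# mirpipe {__version__}\n"
        f"# config_hash={config.hash} seed={config.seed}\n"
    )


def _write_tsv(path: Path, df: pd.DataFrame, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def _done(workdir: Path, stage: str, force: bool) -> bool:
    return not force and all((workdir / f).exists() for f in _OUTPUTS[stage])


def stage_simulate(workdir: Path, config: PipelineConfig,
                   sim_config: SimulationConfig | None = None,
                   force: bool = False) -> None:
    if _done(workdir, "simulate", force):
        return
    sc = sim_config or SimulationConfig(seed=config.seed)
    sim = simulate_genome(sc)
    libs = simulate_libraries(sim, sc)
    ref = make_reference_dbs(sim, sc)
    workdir.mkdir(parents=True, exist_ok=True)
    (workdir / "truth").mkdir(exist_ok=True)
    (workdir / "reads").mkdir(exist_ok=True)
    write_genome(workdir / "genome.fa", sim.scaffolds)
    write_annotation(workdir / "annotation.gff3", sim.exons)
    sheet = libs.sheet
    for lib in sheet.libraries:
        fq = workdir / "reads" / f"{lib.library_id}.fastq"
        with open(fq, "w") as fh:
            for i, r in enumerate(libs.reads[lib.library_id]):
                fh.write(f"@{lib.library_id}_{i}\n{r}\n+\n{'I' * len(r)}\n")
    sheet_df = pd.DataFrame(
        [
            {"library_id": lib.library_id, "stage": lib.stage,
             "replicate": lib.replicate,
             "path": f"reads/{lib.library_id}.fastq"}
            for lib in sheet.libraries
        ]
    )
    _write_tsv(workdir / "sample_sheet.tsv", sheet_df, config)
    write_fasta(workdir / "reference_mature.fa", ref.mature_db, rna=True)
    write_fasta(workdir / "reference_hairpin.fa", ref.hairpin_db, rna=True)
    _write_tsv(workdir / "truth" / "mirnas.tsv", sim.truth, config)
    _write_tsv(
        workdir / "truth" / "expected_counts.tsv",
        libs.expected_counts.reset_index(names="mirna"), config,
    )
    pd.DataFrame(ref.orthologs, columns=["sim_id", "ref_id"]).pipe(
        lambda df: _write_tsv(workdir / "truth" / "orthologs.tsv", df, config)
    )
    expr_a = np.log1p(
        libs.expected_counts.T.groupby(sheet_stage_map(sheet)).mean().T
    )
    known_ids = [a for a, _ in ref.orthologs]
    expr_b = simulate_ortholog_expression(
        expr_a.loc[known_ids], rho=0.8, seed=config.seed,
        id_map=dict(ref.orthologs),
    )
    _write_tsv(workdir / "species_b_expression.tsv",
               expr_b.reset_index(names="mirna"), config)


def sheet_stage_map(sheet: SampleSheet) -> dict[str, str]:
    return {lib.library_id: lib.stage for lib in sheet.libraries}


def _load_collapsed(workdir: Path) -> tuple[dict[str, CollapsedRead], list[str]]:
    df = read_tsv(workdir / "collapsed_reads.tsv")
    lib_cols = [c for c in df.columns if c != "sequence"]
    reads = {}
    for row in df.itertuples(index=False):
        counts = {c: int(getattr(row, c)) for c in lib_cols if getattr(row, c) > 0}
        reads[row.sequence] = CollapsedRead(row.sequence, counts)
    return reads, lib_cols


def stage_preprocess(workdir: Path, config: PipelineConfig, force: bool = False) -> None:
    _require(workdir, "preprocess")
    if _done(workdir, "preprocess", force):
        return
    sheet = SampleSheet.read(workdir / "sample_sheet.tsv")
    reads_by_lib = {
        lib.library_id: read_small_rna_reads(
            lib.path if Path(lib.path).is_absolute() else workdir / lib.path
        )
        for lib in sheet.libraries
    }
    collapsed, summary = filter_and_collapse(reads_by_lib, min_len=config.min_len)
    rows = []
    for cr in collapsed:
        row = {"sequence": cr.sequence}
        for lib in sheet.libraries:
            row[lib.library_id] = cr.counts.get(lib.library_id, 0)
        rows.append(row)
    _write_tsv(workdir / "collapsed_reads.tsv", pd.DataFrame(rows), config)
    _write_tsv(workdir / "mapping_summary.tsv", summary, config)


def stage_map(workdir: Path, config: PipelineConfig, force: bool = False) -> None:
    _require(workdir, "map")
    if _done(workdir, "map", force):
        return
    genome = read_genome(workdir / "genome.fa")
    reads, _ = _load_collapsed(workdir)
    index = KmerIndex(genome, word=min(config.index_word, config.seed_len))
    result = map_collapsed_reads(
        reads.values(), index,
        seed_len=config.seed_len,
        max_tail_mismatch=config.max_tail_mismatch,
        max_hits=config.max_hits,
    )
    df = pd.DataFrame(
        [
            {"sequence": a.sequence, "scaffold": a.scaffold, "start": a.start,
             "strand": a.strand, "mismatches": a.mismatches, "n_hits": a.n_hits}
            for a in result.alignments
        ]
    )
    _write_tsv(workdir / "alignments.tsv", df, config)
    # extend the preprocessing summary with mapping counts
    summary = read_tsv(workdir / "mapping_summary.tsv")
    mapped_counts = {}
    for a in result.alignments:
        for lib, c in reads[a.sequence].counts.items():
            mapped_counts[lib] = mapped_counts.get(lib, 0) + c
    uniq_mapped: dict[str, int] = {}
    for a in result.alignments:
        for lib in reads[a.sequence].counts:
            uniq_mapped[lib] = uniq_mapped.get(lib, 0) + 1
    summary["mapped_reads"] = summary["library_id"].map(mapped_counts).fillna(0).astype(int)
    summary["unique_mapped"] = summary["library_id"].map(uniq_mapped).fillna(0).astype(int)
    _write_tsv(workdir / "mapping_summary.tsv", summary, config)


def _alignments_from_tsv(df: pd.DataFrame) -> list[Alignment]:
    return [
        Alignment(r.sequence, r.scaffold, int(r.start), r.strand,
                  int(r.mismatches), int(r.n_hits))
        for r in df.itertuples(index=False)
    ]


def dedup_candidates(cands: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """One candidate per locus: overlapping same-strand candidates (the two
    excision windows of a stack in particular) collapse onto one.

    A window with star-read support models the true precursor side of the
    stack, so star evidence ranks above the raw score."""
    ordered = sorted(
        cands,
        key=lambda c: (-c.star_count, -c.score, c.scaffold, c.start, c.strand),
    )
    kept: list[HairpinCandidate] = []
    for c in ordered:
        if any(
            k.scaffold == c.scaffold and k.strand == c.strand
            and not (c.end < k.start or c.start > k.end)
            for k in kept
        ):
            continue
        kept.append(c)
    kept.sort(key=lambda c: (c.scaffold, c.start, c.strand))
    return kept


def build_all_candidates(
    windows: Sequence[tuple[str, int, int, str]],
    alignments: Sequence[Alignment],
    reads: dict[str, CollapsedRead],
    genome: Sequence,
    config: PipelineConfig,
) -> list[HairpinCandidate]:
    """Fold, stack-assign and score every excised window, keeping candidates
    above the retention threshold, deduplicated per locus."""
    grouped = group_alignments(alignments)
    cands: list[HairpinCandidate] = []
    for k, w in enumerate(windows):
        cand = build_candidate(
            w, alignments_in_window(w, grouped), reads, genome,
            n_shuffles=config.n_shuffles,
            shuffle_seed=config.seed + k,
            score_prefilter=config.score_keep,
        )
        if cand is None or cand.score <= config.score_keep:
            continue
        cands.append(cand)
    return dedup_candidates(cands)


def discover_in_memory(
    genome: Sequence,
    reads_by_library: dict[str, list[str]],
    config: PipelineConfig,
) -> tuple[list[HairpinCandidate], "MappingResult", dict[str, CollapsedRead], pd.DataFrame]:
    """The collapse → map → excise → fold/score chain without file I/O.

    Returns (deduplicated candidates, mapping result, collapsed reads by
    sequence, per-library summary).
    """
    collapsed, summary = filter_and_collapse(reads_by_library, min_len=config.min_len)
    index = KmerIndex(genome, word=min(config.index_word, config.seed_len))
    result = map_collapsed_reads(
        collapsed, index,
        seed_len=config.seed_len,
        max_tail_mismatch=config.max_tail_mismatch,
        max_hits=config.max_hits,
    )
    reads = {c.sequence: c for c in collapsed}
    totals = {s: r.total_count for s, r in reads.items()}
    windows = excise_candidates(
        result.alignments, totals, genome,
        min_stack=config.min_stack,
        flank_up=config.flank_up, flank_down=config.flank_down,
    )
    cands = build_all_candidates(windows, result.alignments, reads, genome, config)
    return cands, result, reads, summary


def quantify_in_memory(
    cands: Sequence[HairpinCandidate],
    alignments: Sequence[Alignment],
    reads: dict[str, CollapsedRead],
    lib_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-candidate per-library counts of reads aligned inside each window."""
    grouped = group_alignments(alignments)
    rows = {}
    for c in cands:
        counts = dict.fromkeys(lib_ids, 0)
        for a in alignments_in_window((c.scaffold, c.start, c.end, c.strand), grouped):
            for lib, n in reads[a.sequence].counts.items():
                if lib in counts:
                    counts[lib] += n
        rows[c.locus_id] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(lib_ids))


def identify_in_memory(
    cands: Sequence[HairpinCandidate],
    alignments: Sequence[Alignment],
    reads: dict[str, CollapsedRead],
    sheet: SampleSheet,
    mature_db: dict[str, str],
    hairpin_db: dict[str, str],
    config: PipelineConfig,
) -> tuple[dict, dict, list[HairpinCandidate]]:
    """Homology-classify reported candidates and triage the unmatched ones.

    Returns (homology labels, triage verdicts for novel candidates, the final
    identified miRNA set: known/iso plus accepted novels).
    """
    from .triage import build_presence, triage

    reported = [c for c in cands if c.score > config.score_report]
    queries = {
        c.locus_id: (to_dna(c.mature_seq), to_dna(c.hairpin_seq)) for c in reported
    }
    labels = classify_candidates(
        queries, mature_db, hairpin_db,
        word=config.homology_word,
        hairpin_min_score=config.hairpin_min_score,
        hairpin_max_unaligned=config.hairpin_max_unaligned,
    )
    counts = quantify_in_memory(reported, alignments, reads, sheet.library_ids)
    final: list[HairpinCandidate] = []
    verdicts: dict[str, object] = {}
    for c in reported:
        if labels[c.locus_id]["label"] != "novel_candidate":
            final.append(c)
            continue
        presence = build_presence(counts.loc[c.locus_id].to_dict(), sheet)
        v = triage(
            presence,
            star_count=c.star_count,
            hairpin_ok=c.mature_on_one_arm,
            min_total_count=config.min_total_count,
            mature_count=c.mature_count,
        )
        verdicts[c.locus_id] = v
        if v.decision == "accept":
            final.append(c)
    return labels, verdicts, final


def stage_discover(workdir: Path, config: PipelineConfig, force: bool = False) -> None:
    _require(workdir, "discover")
    if _done(workdir, "discover", force):
        return
    genome = read_genome(workdir / "genome.fa")
    exons = read_annotation(workdir / "annotation.gff3", {"exon", "three_prime_UTR"})
    reads, _ = _load_collapsed(workdir)
    alignments = _alignments_from_tsv(read_tsv(workdir / "alignments.tsv"))
    totals = {s: r.total_count for s, r in reads.items()}
    windows = excise_candidates(
        alignments, totals, genome,
        min_stack=config.min_stack,
        flank_up=config.flank_up, flank_down=config.flank_down,
    )
    kept = build_all_candidates(windows, alignments, reads, genome, config)
    rows = []
    for k, cand in enumerate(kept):
        call = classify_exon_overlap((cand.scaffold, cand.start, cand.end), exons)
        rows.append(
            {
                "candidate": f"cand_{k + 1:04d}",
                "scaffold": cand.scaffold, "start": cand.start, "end": cand.end,
                "strand": cand.strand,
                "precursor": cand.precursor_seq,
                "hairpin": cand.hairpin_seq,
                "structure": cand.structure,
                "mature": cand.mature_seq, "star": cand.star_seq,
                "mature_count": cand.mature_count, "star_count": cand.star_count,
                "loop_count": cand.loop_count, "other_count": cand.other_count,
                "mfe_proxy": round(cand.mfe_proxy, 2),
                "shuffle_p": cand.shuffle_p,
                "score": round(cand.score, 3),
                "reported": cand.score > config.score_report,
                "mature_on_one_arm": cand.mature_on_one_arm,
                "exon_overlap": call.category,
                "gene_id": call.gene_id or "",
            }
        )
    _write_tsv(workdir / "candidates.tsv", pd.DataFrame(rows), config)


def _reported_candidates(workdir: Path) -> pd.DataFrame:
    df = read_tsv(workdir / "candidates.tsv")
    return df[df["reported"]].reset_index(drop=True)


def stage_homology(workdir: Path, config: PipelineConfig, force: bool = False) -> None:
    _require(workdir, "homology")
    if _done(workdir, "homology", force):
        return
    cands = _reported_candidates(workdir)
    mature_db = read_fasta_dict(workdir / "reference_mature.fa")
    hairpin_db = read_fasta_dict(workdir / "reference_hairpin.fa")
    queries = {
        r.candidate: (to_dna(str(r.mature)), to_dna(str(r.hairpin)))
        for r in cands.itertuples(index=False)
    }
    labels = classify_candidates(
        queries, mature_db, hairpin_db,
        word=config.homology_word,
        hairpin_min_score=config.hairpin_min_score,
        hairpin_max_unaligned=config.hairpin_max_unaligned,
    )
    rows = []
    for cid, info in labels.items():
        m, h = info["mature_match"], info["hairpin_match"]
        rows.append(
            {
                "candidate": cid, "label": info["label"],
                "mature_subject": m.subject_id if m else "",
                "mature_class": m.match_class if m else "none",
                "mature_mismatches": m.mismatches if m else -1,
                "hairpin_subject": h.subject_id if h else "",
                "hairpin_score": h.score if h else 0.0,
            }
        )
    _write_tsv(workdir / "homology.tsv", pd.DataFrame(rows), config)


def quantify_candidates(
    cands: pd.DataFrame,
    alignments: Sequence[Alignment],
    reads: dict[str, CollapsedRead],
    lib_ids: Sequence[str],
) -> pd.DataFrame:
    """Counts per reported candidate per library: every read whose best
    alignment falls inside the candidate window on its strand."""
    counts = pd.DataFrame(0, index=list(cands["candidate"]), columns=list(lib_ids))
    rows = list(cands.itertuples(index=False))
    for a in alignments:
        for r in rows:
            if (a.scaffold == r.scaffold and a.strand == r.strand
                    and a.start >= r.start and a.end <= r.end):
                for lib, c in reads[a.sequence].counts.items():
                    counts.at[r.candidate, lib] += c
                break
    return counts


def stage_express(workdir: Path, config: PipelineConfig, force: bool = False) -> None:
    _require(workdir, "express")
    if _done(workdir, "express", force):
        return
    sheet = SampleSheet.read(workdir / "sample_sheet.tsv")
    cands = _reported_candidates(workdir)
    reads, lib_ids = _load_collapsed(workdir)
    alignments = _alignments_from_tsv(read_tsv(workdir / "alignments.tsv"))
    counts = quantify_candidates(cands, alignments, reads, lib_ids)
    _write_tsv(workdir / "counts.tsv", counts.reset_index(names="mirna"), config)
    matrix = CountMatrix(counts, sheet).with_tmm()
    de = all_pairwise_tests(matrix, dispersion=config.dispersion)
    _write_tsv(workdir / "de_results.tsv", de, config)
    ratios = log2_ratio_matrix(matrix)
    _write_tsv(workdir / "log2_ratios.tsv", ratios.reset_index(names="mirna"), config)
    if len(ratios) >= 2:
        order, _ = hierarchical_cluster(ratios)
    else:
        order = list(ratios.index)
    with open(workdir / "cluster_order.txt", "w") as fh:
        fh.write(_provenance(config))
        fh.write("\n".join(order) + "\n")


def stage_triage(workdir: Path, config: PipelineConfig, force: bool = False) -> None:
    _require(workdir, "triage")
    if _done(workdir, "triage", force):
        return
    sheet = SampleSheet.read(workdir / "sample_sheet.tsv")
    cands = _reported_candidates(workdir).set_index("candidate")
    labels = read_tsv(workdir / "homology.tsv").set_index("candidate")
    counts = read_tsv(workdir / "counts.tsv").set_index("mirna")
    verdicts, presences, loci, matures = {}, {}, {}, {}
    for cid, row in labels.iterrows():
        if row["label"] != "novel_candidate" or cid not in counts.index:
            continue
        presence = build_presence(counts.loc[cid].to_dict(), sheet)
        c = cands.loc[cid]
        verdicts[cid] = triage(
            presence,
            star_count=int(c["star_count"]),
            hairpin_ok=bool(c["mature_on_one_arm"]),
            min_total_count=config.min_total_count,
            mature_count=int(c["mature_count"]),
        )
        presences[cid] = presence
        loci[cid] = f"{c['scaffold']}:{c['start']}-{c['end']}({c['strand']})"
        matures[cid] = to_dna(str(c["mature"]))
    report = triage_report(verdicts, presences, loci, matures)
    _write_tsv(workdir / "novel_triage.tsv", report, config)
    accepted = {
        cid: to_dna(str(cands.loc[cid]["mature"]))
        for cid, v in verdicts.items() if v.decision == "accept"
    }
    write_fasta(workdir / "novel_mirnas.fa", accepted, rna=True)


def stage_clusters(workdir: Path, config: PipelineConfig, force: bool = False) -> None:
    _require(workdir, "clusters")
    if _done(workdir, "clusters", force):
        return
    cands = _reported_candidates(workdir)
    labels = read_tsv(workdir / "homology.tsv").set_index("candidate")
    tri = read_tsv(workdir / "novel_triage.tsv")
    accepted = set(tri[tri.decision == "accept"].candidate) if len(tri) else set()
    loci = []
    for r in cands.itertuples(index=False):
        # clusters are built on the identified miRNA set: database-matched
        # candidates plus triage-accepted novels
        if labels.loc[r.candidate, "label"] == "novel_candidate" and r.candidate not in accepted:
            continue
        fam = labels.loc[r.candidate, "mature_subject"] or r.candidate
        loci.append(
            MirnaLocus(r.candidate, str(fam) if fam else r.candidate,
                       r.scaffold, int(r.start), int(r.end), r.strand)
        )
    found = detect_clusters(loci, max_gap=config.max_gap)
    rows = []
    for k, cl in enumerate(found):
        for m in cl.members:
            rows.append(
                {"cluster": k + 1, "id": m.id, "family": m.family,
                 "scaffold": m.scaffold, "start": m.start, "end": m.end,
                 "strand": m.strand, "span_bp": cl.span_bp, "span_kb": cl.span_kb}
            )
    _write_tsv(workdir / "clusters.tsv", pd.DataFrame(rows), config)
    arr_rows = []
    for i in range(len(found)):
        for j in range(i + 1, len(found)):
            arr_rows.append(
                {"cluster_a": i + 1, "cluster_b": j + 1,
                 "relation": compare_arrangement(found[i], found[j])}
            )
    _write_tsv(workdir / "arrangement_report.tsv", pd.DataFrame(arr_rows), config)


def stage_targets(workdir: Path, config: PipelineConfig, force: bool = False) -> None:
    _require(workdir, "targets")
    if _done(workdir, "targets", force):
        return
    genome = read_genome(workdir / "genome.fa")
    annot = read_annotation(workdir / "annotation.gff3", {"three_prime_UTR"})
    utrs = extract_utrs(annot, genome)
    cands = _reported_candidates(workdir)
    rows = []
    for r in cands.itertuples(index=False):
        for site in scan_targets(
            r.candidate, to_dna(str(r.mature)), utrs,
            score_cut=config.target_score_cut,
            energy_cut=config.target_energy_cut,
        ):
            rows.append(
                {"mirna": site.mirna_id, "transcript": site.transcript_id,
                 "utr_start": site.utr_start, "utr_end": site.utr_end,
                 "pairing_score": site.pairing_score,
                 "energy_proxy": site.energy_proxy,
                 "seed_match": site.seed_match}
            )
    _write_tsv(workdir / "targets.tsv", pd.DataFrame(rows), config)


def stage_crossspecies(workdir: Path, config: PipelineConfig, force: bool = False) -> None:
    _require(workdir, "crossspecies")
    if _done(workdir, "crossspecies", force):
        return
    sheet = SampleSheet.read(workdir / "sample_sheet.tsv")
    cands = _reported_candidates(workdir)
    hairpin_db = read_fasta_dict(workdir / "reference_hairpin.fa")
    ours = {r.candidate: to_dna(str(r.hairpin)) for r in cands.itertuples(index=False)}
    pairs = reciprocal_best_hits(
        ours, hairpin_db,
        word=config.homology_word,
        min_score=config.hairpin_min_score,
        max_unaligned=config.hairpin_max_unaligned,
    )
    _write_tsv(
        workdir / "orthologs.tsv",
        pd.DataFrame([(p.species_a_id, p.species_b_id) for p in pairs],
                     columns=["id_a", "id_b"]),
        config,
    )
    counts = read_tsv(workdir / "counts.tsv").set_index("mirna")
    matrix = CountMatrix(counts, sheet).with_tmm()
    cpm_a = cpm(matrix)
    stage_of = sheet_stage_map(sheet)
    cpm_a_stage = cpm_a.T.groupby(stage_of).mean().T
    expr_b = read_tsv(workdir / "species_b_expression.tsv").set_index("mirna")
    grid = spearman_matrix(np.log1p(cpm_a_stage), np.log1p(expr_b), pairs)
    _write_tsv(workdir / "spearman_grid.tsv", grid, config)


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "map": stage_map,
    "discover": stage_discover,
    "homology": stage_homology,
    "triage": stage_triage,
    "express": stage_express,
    "clusters": stage_clusters,
    "targets": stage_targets,
    "crossspecies": stage_crossspecies,
}


def run(stage: str, workdir: str | Path, config: PipelineConfig | None = None,
        force: bool = False, sim_config: SimulationConfig | None = None) -> None:
    """Run one stage, or ``all`` for the full chain in dependency order."""
    config = config or PipelineConfig()
    workdir = Path(workdir)
    if stage == "all":
        for s in _ORDER:
            log.info("stage %s", s)
            if s == "simulate":
                stage_simulate(workdir, config, sim_config=sim_config, force=force)
            else:
                _STAGE_FN[s](workdir, config, force=force)
        return
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ['all']}")
    if stage == "simulate":
        stage_simulate(workdir, config, sim_config=sim_config, force=force)
    else:
        _STAGE_FN[stage](workdir, config, force=force)
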