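"""Decision tree promoting unmatched candidates to novel miRNAs.

A candidate with no database homology is judged purely on its expression
footprint across the stage × replicate design plus two pieces of hairpin
evidence (star-read support and a well-formed fold).  The rules, evaluated in
order, encode the reasoning a curator applies: consistent detection across
the design is believable; detection in a single replicate of a single stage
is not; stage-restricted candidates need star reads, adequate counts and a
clean hairpin; and in every accepted case the mature read must dominate its
star.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import SampleSheet, to_rna

__all__ = ["PresenceMatrix", "TriageVerdict", "build_presence", "triage", "triage_report"]


@dataclass
class PresenceMatrix:
    """Per-candidate counts over the sequenced (stage, replicate) design."""

    counts: dict[tuple[str, int], int]  # (stage, replicate) -> count
    stages: list[str]  # stage order from the sample sheet

    @property
    def present(self) -> dict[tuple[str, int], bool]:
        return {k: v > 0 for k, v in self.counts.items()}

    @property
    def present_in_all_libraries(self) -> bool:
        return all(v > 0 for v in self.counts.values())

    @property
    def stages_absent(self) -> set[str]:
        out = set()
        for stage in self.stages:
            libs = [v for (s, _), v in self.counts.items() if s == stage]
            if libs and all(v == 0 for v in libs):
                out.add(stage)
        return out

    @property
    def n_replicates_detected(self) -> int:
        return sum(1 for v in self.counts.values() if v > 0)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def stages_detected(self) -> set[str]:
        return {s for (s, _), v in self.counts.items() if v > 0}


def build_presence(
    counts_per_library: Mapping[str, int], sheet: SampleSheet
) -> PresenceMatrix:
    """Arrange one candidate's per-library counts on the design.

    Only sequenced libraries enter the matrix, so a missing replicate shrinks
    every "all libraries" denominator instead of counting as an absence.
    """
    table: dict[tuple[str, int], int] = {}
    for lib in sheet:
        if lib.library_id not in counts_per_library:
            raise KeyError(f"no count for sequenced library {lib.library_id!r}")
        table[(lib.stage, lib.replicate)] = int(counts_per_library[lib.library_id])
    return PresenceMatrix(table, sheet.stages)


@dataclass(frozen=True)
class TriageVerdict:
    decision: str  # accept | reject
    rule_fired: str
    notes: str = ""


def triage(
    presence: PresenceMatrix,
    star_count: int,
    hairpin_ok: bool,
    min_total_count: int = 10,
    mature_count: int | None = None,
) -> TriageVerdict:
    """Apply the novel-miRNA decision rules to one unmatched candidate.

    R1  present in every sequenced library → accept.
    R2  absent in exactly one replicate of one stage, present everywhere
        else → accept.
    R3  present in ≥2 stages with ≥2 replicates each while absent in ≥1
        whole stage → accept, unless the total count is below
        ``min_total_count`` or no star reads exist (R3a) or the hairpin is
        malformed (R3b).
    R4  detected in only one replicate of a single stage → reject.
    R5  any accept is vetoed when the mature read does not dominate its star.

    ``mature_count`` defaults to the presence total (all stack reads mature).
    """
    if mature_count is None:
        mature_count = presence.total_count

    def guard(verdict: TriageVerdict) -> TriageVerdict:
        if verdict.decision == "accept" and mature_count <= star_count:
            return TriageVerdict("reject", "R5_star_dominant",
                                 "mature read does not dominate the star read")
        return verdict

    if presence.present_in_all_libraries:
        return guard(TriageVerdict("accept", "R1_all_libraries"))

    absent = [k for k, v in presence.counts.items() if v == 0]
    if len(absent) == 1:
        return guard(
            TriageVerdict(
                "accept", "R2_one_missing_replicate",
                f"absent only in {absent[0][0]} replicate {absent[0][1]}",
            )
        )

    detected = presence.stages_detected()
    reps_per_detected = {
        s: sum(1 for (st, _), v in presence.counts.items() if st == s and v > 0)
        for s in detected
    }
    if len(detected) == 1 and presence.n_replicates_detected == 1:
        return TriageVerdict("reject", "R4_single_replicate",
                             f"seen once, in {next(iter(detected))}")

    stage_restricted = (
        len(detected) >= 2
        and all(r >= 2 for r in reps_per_detected.values())
        and len(presence.stages_absent) >= 1
    )
    if stage_restricted:
        if presence.total_count < min_total_count or star_count == 0:
            return TriageVerdict(
                "reject", "R3a_low_count_or_no_star",
                f"total {presence.total_count}, star {star_count}",
            )
        if not hairpin_ok:
            return TriageVerdict("reject", "R3b_bad_hairpin",
                                 "unusual secondary structure")
        return guard(
            TriageVerdict(
                "accept", "R3_stage_restricted_pass",
                f"absent in {sorted(presence.stages_absent)}",
            )
        )

    # fall-through: too sparse or inconsistent to fit any accept pattern
    return TriageVerdict(
        "reject", "R4_single_replicate",
        "detection too sparse for any accept rule",
    )


def triage_report(
    verdicts: Mapping[str, TriageVerdict],
    presences: Mapping[str, PresenceMatrix] | None = None,
    loci: Mapping[str, str] | None = None,
    mature_seqs: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-candidate verdict table, shaped like a novel-miRNA summary:
    genomic location, total read count, consensus mature sequence (RNA), and
    per-stage presence flags for accepted candidates."""
    rows = []
    for cid in sorted(verdicts):
        v = verdicts[cid]
        row: dict = {
            "candidate": cid,
            "decision": v.decision,
            "rule_fired": v.rule_fired,
            "notes": v.notes,
        }
        if loci is not None:
            row["genomic_location"] = loci.get(cid, "")
        if mature_seqs is not None:
            row["mature_sequence"] = to_rna(mature_seqs.get(cid, ""))
        if presences is not None and cid in presences:
            p = presences[cid]
            row["total_read_count"] = p.total_count
            for stage in p.stages:
                libs = [v_ for (s, _), v_ in p.counts.items() if s == stage]
                row[f"present_{stage}"] = "yes" if any(x > 0 for x in libs) else "no"
        rows.append(row)
    return pd.DataFrame(rows)
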