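"""Readers and writers for the external formats the pipeline touches.

Everything downstream of this module works on a single in-memory data model:
DNA sequences over ``{A,C,G,T,N}`` (``U`` is normalized to ``T`` on input) and
1-based inclusive coordinates, the GFF3 convention.  Mature miRNA sequences are
rendered back as RNA (``U``) only at output boundaries, matching how miRNA
databases print them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Scaffold",
    "ExonRecord",
    "Library",
    "SampleSheet",
    "to_dna",
    "to_rna",
    "revcomp",
    "read_genome",
    "write_genome",
    "read_annotation",
    "write_annotation",
    "read_small_rna_reads",
    "read_fasta_dict",
    "write_fasta",
]

_DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def to_dna(seq: str) -> str:
    """Uppercase a nucleotide string and normalize RNA ``U`` to DNA ``T``."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a DNA string as lowercase RNA (the miRNA-database convention)."""
    return seq.upper().replace("T", "U").lower()


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Scaffold:
    """A genome scaffold: a named DNA sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("scaffold name must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"scaffold {self.name!r} has an empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"scaffold {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice; the only place coordinates meet offsets."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise IndexError(
                f"window {start}..{end} outside scaffold {self.name} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class ExonRecord:
    """One exon or three_prime_UTR feature from a GFF3 annotation."""

    scaffold: str
    start: int
    end: int
    strand: str
    gene_id: str
    feature: str = "exon"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end} for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")


def read_genome(path: str | Path) -> list[Scaffold]:
    """Read a multi-FASTA genome into scaffolds, preserving file order.

    Sequences are uppercased and U→T normalized.  Duplicate scaffold names and
    empty files are hard errors: downstream coordinates would be ambiguous.
    """
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold name {rec.id!r} in {path}")
        seen.add(rec.id)
        scaffolds.append(Scaffold(rec.id, to_dna(str(rec.seq))))
    if not scaffolds:
        raise ValueError(f"no FASTA records in {path}")
    return scaffolds


def write_genome(path: str | Path, scaffolds: Iterable[Scaffold]) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.name, description="") for s in scaffolds]
    SeqIO.write(records, str(path), "fasta")


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_annotation(
    path: str | Path,
    features: Iterable[str] = ("exon", "three_prime_UTR"),
    genome: Sequence[Scaffold] | None = None,
) -> list[ExonRecord]:
    """Read the requested feature types from a GFF3 file.

    Records with malformed or inverted coordinates are skipped with a single
    summary warning rather than aborting the run (draft gene sets routinely
    contain a few).  An absent feature type yields an empty result, not an
    error.  When a genome is supplied, features outside scaffold bounds are
    also skipped.
    """
    wanted = set(features)
    lengths = {s.name: len(s) for s in genome} if genome is not None else None
    records: list[ExonRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9 or cols[2] not in wanted:
                if len(cols) >= 3 and cols[2] in wanted:
                    n_skipped += 1
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                n_skipped += 1
                continue
            if start > end or cols[6] not in {"+", "-"}:
                n_skipped += 1
                continue
            if lengths is not None and (
                cols[0] not in lengths or end > lengths[cols[0]] or start < 1
            ):
                n_skipped += 1
                continue
            gene_id = (
                _gff3_attr(cols[8], "gene_id")
                or _gff3_attr(cols[8], "Parent")
                or _gff3_attr(cols[8], "ID")
                or "."
            )
            records.append(ExonRecord(cols[0], start, end, cols[6], gene_id, cols[2]))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} malformed GFF3 record(s) in {path}")
    return records


def write_annotation(path: str | Path, records: Iterable[ExonRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                f"{r.scaffold}\tmirpipe\t{r.feature}\t{r.start}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID={r.gene_id};gene_id={r.gene_id}\n"
            )


def read_small_rna_reads(path: str | Path, fmt: str | None = None) -> list[str]:
    """Read raw small-RNA reads from FASTQ or FASTA (auto-sniffed).

    Reads are returned verbatim apart from case/U→T normalization; adapter
    trimming is assumed to have happened upstream and qualities are ignored.
    Reads with characters outside ``{A,C,G,T,N}`` are dropped with a warning.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.read(1)
        if first == "@":
            fmt = "fastq"
        elif first == ">":
            fmt = "fasta"
        elif first == "":
            return []
        else:
            raise ValueError(f"cannot sniff read format of {path}")
    reads: list[str] = []
    n_bad = 0
    for rec in SeqIO.parse(str(path), fmt):
        seq = to_dna(str(rec.seq))
        if set(seq) - _DNA_ALPHABET:
            n_bad += 1
            continue
        reads.append(seq)
    if n_bad:
        warnings.warn(f"dropped {n_bad} read(s) with non-nucleotide characters")
    return reads


def read_fasta_dict(path: str | Path, as_dna: bool = True) -> dict[str, str]:
    """Read a FASTA file (e.g. a mature/hairpin reference) as id → sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        out[rec.id] = to_dna(str(rec.seq)) if as_dna else str(rec.seq)
    return out


def write_fasta(path: str | Path, entries: dict[str, str], rna: bool = False) -> None:
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n{to_rna(seq) if rna else seq}\n")


@dataclass(frozen=True)
class Library:
    """One sequenced small-RNA library: a (stage, replicate) sample."""

    library_id: str
    stage: str
    replicate: int
    path: str = ""

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate numbers are positive integers")


@dataclass
class SampleSheet:
    """The per-library design: stage and replicate for every sequenced library.

    Missing replicates are simply absent rows (the design tolerates e.g. a
    stage sequenced in two of three intended replicates); ``(stage,
    replicate)`` pairs must be unique.
    """

    libraries: list[Library] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [(lib.stage, lib.replicate) for lib in self.libraries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (stage, replicate) pair in sample sheet")
        ids = [lib.library_id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate library_id in sample sheet")

    @property
    def stages(self) -> list[str]:
        """Stage labels in first-appearance order."""
        out: list[str] = []
        for lib in self.libraries:
            if lib.stage not in out:
                out.append(lib.stage)
        return out

    @property
    def library_ids(self) -> list[str]:
        return [lib.library_id for lib in self.libraries]

    def by_stage(self, stage: str) -> list[Library]:
        return [lib for lib in self.libraries if lib.stage == stage]

    def __iter__(self):
        return iter(self.libraries)

    def __len__(self) -> int:
        return len(self.libraries)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"library_id": str, "stage": str})
        required = {"library_id", "stage", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
        libs = [
            Library(
                row.library_id,
                row.stage,
                int(row.replicate),
                str(getattr(row, "path", "")),
            )
            for row in df.itertuples()
        ]
        return cls(libs)

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "library_id": l.library_id,
                    "stage": l.stage,
                    "replicate": l.replicate,
                    "path": l.path,
                }
                for l in self.libraries
            ]
        ).to_csv(path, sep="\t", index=False)
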