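"""Pipeline configuration: every stage's thresholds in one round-trippable
object.  Defaults are the discovery pipeline's published stringency values."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 1

    # read filtering / mapping
    min_len: int = 17
    seed_len: int = 18
    max_tail_mismatch: int = 2
    max_hits: int = 5
    index_word: int = 17  # <= min read length so 17-nt reads stay mappable

    # hairpin discovery
    min_stack: int = 5
    flank_up: int = 70
    flank_down: int = 70
    n_shuffles: int = 19
    score_keep: float = -50.0  # candidates below are discarded outright
    score_report: float = 2.0  # candidates at or below are rejected

    # homology
    homology_word: int = 16
    near_perfect_mismatches: int = 1
    near_perfect_len_diff: int = 2
    hairpin_min_score: float = 40.0
    hairpin_max_unaligned: int = 8

    # triage
    min_total_count: int = 10

    # expression
    fdr_alpha: float = 0.05
    dispersion: str | float = "auto"

    # genomic clusters
    max_gap: int = 10_000

    # target scan
    target_score_cut: float = 155.0
    target_energy_cut: float = -7.0
    target_gap_open: float = -8.0
    target_gap_extend: float = -8.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
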