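"""Run configuration: every tunable parameter of the pipeline in one
place, with the canonical defaults (20 kb window, 1 kb step, density 20,
e-value 1e-7, 10-nt Ping-Pong overlap, 26-32 nt length range, top 200)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # alignment filtering
    evalue_max: float = 1e-7
    max_mismatch: int = 0
    max_gaps: int = 0
    require_full_length: bool = True
    # cluster calling
    window_length: int = 20_000
    step: int = 1_000
    min_density: int = 20
    extension_step: int = 1_000
    bidir_min_fraction: float = 0.2
    unique_only: bool = False
    # Ping-Pong
    pingpong_overlap: int = 10
    require_signature: bool = False
    # piRNA length gate
    length_min: int = 26
    length_max: int = 32
    # expression
    top_n: int = 200
    # misc
    seed: int = 1
    log_level: str = "INFO"
    # inputs (paths); optional tracks may stay None
    blast: str | None = None
    fasta: str | None = None
    genome: str | None = None
    genes: str | None = None
    gene_dialect: str = "gtf"
    repeats: str | None = None
    pseudogenes: str | None = None
    promoters: str | None = None
    blacklist: str | None = None
    reads: str | None = None
    catalogue: str | None = None
    out_dir: str = "pirnakit_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
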