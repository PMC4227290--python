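"""Per-sample piRNA abundance and top-N ranking.

Reads are assigned to catalogue piRNAs by exact sequence identity (U/T
equivalent, case-insensitive); catalogue entries are collapsed read
sequences, so no mismatch tolerance applies.  Reads matching no catalogue
entry are tallied as unassigned, preserving read-count conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pirnakit.seq_tools import _normalize

DEFAULT_TOP_N = 200


@dataclass
class ExpressionProfile:
    """Read counts per piRNA for one sample (tissue/stage)."""

    sample: str
    counts: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())

    @property
    def total_reads(self) -> int:
        return self.total_assigned + self.unassigned


def count_abundance(
    reads: Iterable[str], catalogue: Mapping[str, str], sample: str = "sample"
) -> ExpressionProfile:
    """Count reads per catalogue piRNA by exact sequence match.

    A read increments the count of every catalogue entry with that exact
    sequence (distinct ids sharing one sequence each get the read).
    """
    if not catalogue:
        raise ValueError("empty piRNA catalogue")
    by_seq: dict[str, list[str]] = {}
    for pid, seq in catalogue.items():
        by_seq.setdefault(_normalize(seq), []).append(pid)
    profile = ExpressionProfile(sample, {pid: 0 for pid in catalogue})
    for read in reads:
        ids = by_seq.get(_normalize(read))
        if ids is None:
            profile.unassigned += 1
        else:
            for pid in ids:
                profile.counts[pid] += 1
    return profile


def top_n(profile: ExpressionProfile, n: int = DEFAULT_TOP_N) -> list[tuple[str, int]]:
    """The n most abundant piRNAs, count-descending, ties broken by id.

    Zero-count entries are excluded; fewer than n rows are returned when
    fewer piRNAs were observed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        ((pid, c) for pid, c in profile.counts.items() if c > 0),
        key=lambda pc: (-pc[1], pc[0]),
    )
    return ranked[:n]
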