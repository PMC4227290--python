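"""From raw BLAST alignments to the curated genomic hit set.

The filtering contract follows the strict piRNA mapping convention:
perfect alignments only (no mismatches, no gap opens, alignment length
equal to the query length) at a significant e-value (<= 1e-7, inclusive).
Hits overlapping a non-piRNA ncRNA blacklist (rRNA, tRNA, snoRNA, miRNA
loci) are subtracted, and each piRNA is flagged as a unique mapper when it
retains exactly one genomic hit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from collections import Counter
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from pirnakit.genomic_io import AlignmentRow, GenomicInterval

DEFAULT_EVALUE_MAX = 1e-7


@dataclass(frozen=True)
class GenomicHit:
    """A filtered full-length alignment of one piRNA to the genome."""

    pirna_id: str
    interval: GenomicInterval
    e_value: float
    is_unique: bool = False


def filter_alignments(
    rows: Sequence[AlignmentRow],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    max_mismatch: int = 0,
    max_gaps: int = 0,
    require_full_length: bool = True,
) -> list[GenomicHit]:
    """Keep alignments passing the perfect-match filters, in input order.

    A row survives iff mismatches <= max_mismatch, gap opens <= max_gaps,
    e-value <= evalue_max (cutoff inclusive) and — unless
    ``require_full_length`` is off — alignment length equals query length.
    The percent-identity column is ignored: it is redundant with the
    mismatch count under full-length gap-free filtering.
    """
    if evalue_max < 0 or max_mismatch < 0 or max_gaps < 0:
        raise ValueError("filter thresholds must be non-negative")
    hits: list[GenomicHit] = []
    for row in rows:
        if row.mismatches > max_mismatch:
            continue
        if row.gap_opens > max_gaps:
            continue
        if require_full_length and row.aln_length != row.query_length:
            continue
        if row.e_value > evalue_max:
            continue
        hits.append(GenomicHit(row.query_id, row.subject_interval, row.e_value))
    return hits


def subtract_ncrna(
    hits: Sequence[GenomicHit], blacklist: Sequence[GenomicInterval]
) -> list[GenomicHit]:
    """Drop every hit overlapping a blacklist interval by >= 1 bp.

    Overlap is strand-blind; order of surviving hits is preserved.
    """
    if not blacklist:
        return list(hits)
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out: list[GenomicHit] = []
    for hit in hits:
        tree = trees.get(hit.interval.chrom)
        if tree is not None and tree.overlaps(hit.interval.start, hit.interval.end):
            continue
        out.append(hit)
    return out


def flag_unique_mappers(hits: Sequence[GenomicHit]) -> list[GenomicHit]:
    """Set ``is_unique`` on hits of piRNAs with exactly one genome-wide hit."""
    counts = Counter(h.pirna_id for h in hits)
    return [
        dataclasses.replace(h, is_unique=(counts[h.pirna_id] == 1)) for h in hits
    ]


HITS_TSV_HEADER = ("pirna_id", "chrom", "start", "end", "strand", "e_value", "is_unique")


def write_hits_tsv(hits: Iterable[GenomicHit], path) -> None:
    from pirnakit.genomic_io import write_tsv

    write_tsv(
        path,
        HITS_TSV_HEADER,
        (
            (h.pirna_id, h.interval.chrom, h.interval.start, h.interval.end,
             h.interval.strand, f"{h.e_value:g}", int(h.is_unique))
            for h in hits
        ),
    )


def read_hits_tsv(path) -> list[GenomicHit]:
    from pirnakit.genomic_io import read_tsv

    _header, rows = read_tsv(path)
    return [
        GenomicHit(
            r[0],
            GenomicInterval(r[1], int(r[2]), int(r[3]), r[4]),
            float(r[5]),
            bool(int(r[6])),
        )
        for r in rows
    ]


def unique_fraction(hits: Iterable[GenomicHit]) -> float:
    """Fraction of distinct piRNA ids that map uniquely (0 when no hits)."""
    counts = Counter(h.pirna_id for h in hits)
    if not counts:
        return 0.0
    return sum(1 for c in counts.values() if c == 1) / len(counts)
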