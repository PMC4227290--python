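"""Sliding-window piRNA cluster calling, scoring and cross-annotation.

piRNA clusters are genomic hotspots producing many piRNAs.  They are
detected by sliding a fixed-length window (default 20 kb) along each
chromosome in fixed increments (default 1 kb) and counting the piRNA hits
whose 5'-most genomic coordinate (interval start) falls inside the window.
When a window reaches the density threshold (default 20 hits) its right
edge is extended progressively in 1 kb steps for as long as the hit
density over the whole extended window — hits per window-length of span —
stays at or above the threshold.  The cluster is then trimmed to the span
from the first nucleotide of its first hit to the last nucleotide of its
last hit, and scanning resumes at the first window position at or beyond
the cluster end, so emitted clusters are disjoint and serially numbered
per chromosome (id ``chrom.serial``).

The cluster score is the per-kb hit density scaled by the constant
``min_density / window_length_kb`` (1 under default parameters), so a
higher score always means a denser cluster.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pirnakit.genomic_io import GenomicInterval, SyntenyBlock
from pirnakit.hit_processing import GenomicHit
from pirnakit.seq_tools import gc_percent


@dataclass(frozen=True)
class ClusterParams:
    """Window-scan parameters.

    window_length: scanning window size in bp.
    step: window increment in bp (must not exceed window_length).
    min_density: minimum piRNA hits per window to seed a cluster.
    extension_step: right-edge extension increment in bp.
    """

    window_length: int = 20_000
    step: int = 1_000
    min_density: int = 20
    extension_step: int = 1_000

    def __post_init__(self) -> None:
        for name in ("window_length", "step", "min_density", "extension_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.step > self.window_length:
            raise ValueError("step must not exceed window_length")


@dataclass
class ClusterRecord:
    """A called piRNA cluster.

    Boundaries are hit-bounded: start is the first base of the first
    contained hit, end the (exclusive) end of the last.  ``cluster_id`` is
    ``chrom.serial`` with serial the 1-based start-order rank within the
    chromosome.
    """

    cluster_id: str
    interval: GenomicInterval
    n_pirnas: int
    plus_count: int
    minus_count: int
    directionality: str
    score: float
    gc_percent: float | None = None
    member_ids: tuple[str, ...] = ()
    gene_ids: list[str] = field(default_factory=list)
    repeat_names: list[str] = field(default_factory=list)
    promoter_ids: list[str] = field(default_factory=list)
    pseudogene_ids: list[str] = field(default_factory=list)


def score_cluster(
    n_pirnas: int, length_bp: int, params: ClusterParams = ClusterParams()
) -> float:
    """Cluster score: hits per kb of cluster × min_density/window_kb.

    With default parameters the scale constant is 1, so the score is the
    hit density in hits per kb; it increases with hit count and decreases
    with cluster length.
    """
    if length_bp < 1:
        raise ValueError("cluster length must be >= 1 bp")
    window_kb = params.window_length / 1000.0
    return (n_pirnas * 1000.0 / length_bp) * (params.min_density / window_kb)


def classify_directionality(
    plus_count: int, minus_count: int, bidir_min_fraction: float = 0.2
) -> str:
    """mono_plus / mono_minus / bidirectional by minority-strand fraction.

    Bidirectional when the minority strand contributes at least
    ``bidir_min_fraction`` of the hits; otherwise mono with the majority
    strand (ties at fraction 0.5 are bidirectional for any valid cutoff).
    """
    if not 0 < bidir_min_fraction <= 0.5:
        raise ValueError("bidir_min_fraction must be in (0, 0.5]")
    total = plus_count + minus_count
    if total == 0:
        raise ValueError("cluster with no hits")
    if min(plus_count, minus_count) / total >= bidir_min_fraction:
        return "bidirectional"
    return "mono_plus" if plus_count >= minus_count else "mono_minus"


def call_clusters(
    hits: Sequence[GenomicHit],
    params: ClusterParams = ClusterParams(),
    bidir_min_fraction: float = 0.2,
) -> list[ClusterRecord]:
    """Call piRNA clusters from a hit list sorted by (chrom, start).

    See the module docstring for the scan/extend/trim procedure.  Window
    membership is by hit start position, making density integer-valued.
    Raises on unsorted input; empty input yields an empty list.
    """
    keys = [(h.interval.chrom, h.interval.start) for h in hits]
    if keys != sorted(keys):
        raise ValueError("hits must be sorted by (chrom, start)")
    by_chrom: dict[str, list[GenomicHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h)

    clusters: list[ClusterRecord] = []
    for chrom in by_chrom:
        chrom_hits = by_chrom[chrom]
        starts = [h.interval.start for h in chrom_hits]
        last_start = starts[-1]
        L, step, d, ext = (
            params.window_length,
            params.step,
            params.min_density,
            params.extension_step,
        )
        serial = 0
        w = 0
        while w <= last_start:
            lo = bisect_left(starts, w)
            hi = bisect_left(starts, w + L)
            if hi - lo < d:
                w += step
                continue
            # extend right edge while whole-window density stays >= d
            right = w + L
            while True:
                cand = right + ext
                c = bisect_left(starts, cand) - lo
                if c * L >= d * (cand - w):
                    right = cand
                else:
                    break
            # trim to hit bounds; closure so every hit inside the reported
            # interval is a member
            hi = bisect_left(starts, right)
            end = max(h.interval.end for h in chrom_hits[lo:hi])
            while True:
                hi2 = bisect_left(starts, end)
                if hi2 <= hi:
                    break
                hi = hi2
                end = max(end, max(h.interval.end for h in chrom_hits[lo:hi]))
            members = chrom_hits[lo:hi]
            start = members[0].interval.start
            plus = sum(1 for h in members if h.interval.strand == "+")
            minus = sum(1 for h in members if h.interval.strand == "-")
            serial += 1
            clusters.append(
                ClusterRecord(
                    cluster_id=f"{chrom}.{serial}",
                    interval=GenomicInterval(chrom, start, end),
                    n_pirnas=len(members),
                    plus_count=plus,
                    minus_count=minus,
                    directionality=classify_directionality(
                        plus, minus, bidir_min_fraction
                    ),
                    score=score_cluster(len(members), end - start, params),
                    member_ids=tuple(h.pirna_id for h in members),
                )
            )
            w = math.ceil(end / step) * step
    return clusters


def cluster_gc(cluster: ClusterRecord, genome: Mapping[str, str]) -> float:
    """GC% of the genomic subsequence spanned by the cluster."""
    iv = cluster.interval
    if iv.chrom not in genome:
        raise KeyError(f"chromosome {iv.chrom} not in genome")
    seq = genome[iv.chrom]
    if iv.end > len(seq):
        raise ValueError(
            f"cluster {cluster.cluster_id} exceeds chromosome {iv.chrom} "
            f"({iv.end} > {len(seq)})"
        )
    return gc_percent(seq[iv.start : iv.end])


_KIND_FIELDS = {
    "gene": "gene_ids",
    "repeat": "repeat_names",
    "promoter": "promoter_ids",
    "pseudogene": "pseudogene_ids",
}


def overlap_clusters(
    clusters: Sequence[ClusterRecord],
    features: Sequence[tuple[GenomicInterval, str]],
    kind: str,
) -> list[ClusterRecord]:
    """Attach ids of features overlapping each cluster by >= 1 bp.

    ``kind`` selects the target list field: gene, repeat, promoter or
    pseudogene.  Updates the records in place and returns the list.
    """
    if kind not in _KIND_FIELDS:
        raise ValueError(f"unknown feature kind: {kind!r}")
    attr = _KIND_FIELDS[kind]
    for cluster in clusters:
        found = sorted(
            {name for iv, name in features if cluster.interval.overlaps(iv)}
        )
        getattr(cluster, attr).extend(found)
    return list(clusters)


def project_through_block(
    interval: GenomicInterval, block: SyntenyBlock
) -> GenomicInterval:
    """Linear projection of a source-genome interval into a block's target.

    Offsets within the source interval map proportionally onto the target;
    inverted blocks reverse the axis.  The projection is rounded outward
    (floor on start, ceil on end) so it always covers the exact image.
    """
    s, t = block.source, block.target
    scale = t.length / s.length
    if block.orientation == "same":
        lo = t.start + math.floor((interval.start - s.start) * scale)
        hi = t.start + math.ceil((interval.end - s.start) * scale)
    else:
        lo = t.start + math.floor((s.end - interval.end) * scale)
        hi = t.start + math.ceil((s.end - interval.start) * scale)
    return GenomicInterval(t.chrom, lo, max(hi, lo + 1))


CLUSTERS_TSV_HEADER = (
    "cluster_id", "chrom", "start", "end", "n_pirnas", "plus", "minus",
    "directionality", "score", "gc_percent", "gene_ids", "repeat_names",
    "promoter_ids", "pseudogene_ids", "member_ids",
)


def write_clusters_tsv(clusters: Sequence[ClusterRecord], path) -> None:
    from pirnakit.genomic_io import write_tsv

    def row(c: ClusterRecord):
        gc = "NA" if c.gc_percent is None else f"{c.gc_percent:.4f}"
        return (
            c.cluster_id, c.interval.chrom, c.interval.start, c.interval.end,
            c.n_pirnas, c.plus_count, c.minus_count, c.directionality,
            f"{c.score:.6g}", gc,
            ";".join(c.gene_ids), ";".join(c.repeat_names),
            ";".join(c.promoter_ids), ";".join(c.pseudogene_ids),
            ",".join(c.member_ids),
        )

    write_tsv(path, CLUSTERS_TSV_HEADER, (row(c) for c in clusters))


def read_clusters_tsv(path) -> list[ClusterRecord]:
    from pirnakit.genomic_io import read_tsv

    _header, rows = read_tsv(path)
    out: list[ClusterRecord] = []
    for r in rows:
        out.append(
            ClusterRecord(
                cluster_id=r[0],
                interval=GenomicInterval(r[1], int(r[2]), int(r[3])),
                n_pirnas=int(r[4]),
                plus_count=int(r[5]),
                minus_count=int(r[6]),
                directionality=r[7],
                score=float(r[8]),
                gc_percent=None if r[9] == "NA" else float(r[9]),
                gene_ids=r[10].split(";") if r[10] else [],
                repeat_names=r[11].split(";") if r[11] else [],
                promoter_ids=r[12].split(";") if r[12] else [],
                pseudogene_ids=r[13].split(";") if r[13] else [],
                member_ids=tuple(r[14].split(",")) if r[14] else (),
            )
        )
    return out


def map_to_synteny(
    clusters_src: Sequence[ClusterRecord],
    blocks: Sequence[SyntenyBlock],
    clusters_tgt: Sequence[ClusterRecord],
) -> list[tuple[str, str, SyntenyBlock]]:
    """Conserved cluster pairs across two genomes via synteny projection.

    A source cluster contained in a block's source interval is projected
    into the target genome; every target cluster overlapping the projected
    interval by >= 1 bp yields one (src_id, tgt_id, block) record.
    """
    pairs: list[tuple[str, str, SyntenyBlock]] = []
    for src in clusters_src:
        for block in blocks:
            siv = block.source
            civ = src.interval
            if civ.chrom != siv.chrom or civ.start < siv.start or civ.end > siv.end:
                continue
            projected = project_through_block(civ, block)
            for tgt in clusters_tgt:
                if tgt.interval.overlaps(projected):
                    pairs.append((src.cluster_id, tgt.cluster_id, block))
    return pairs
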