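"""Genomic-context classification of piRNA hits.

Each hit is labelled by the features it overlaps: GENE when it touches any
transcript span (>= 1 bp, strand-blind), plus any of INTRON / CDS / UTR5 /
UTR3 whose per-transcript intervals it overlaps; a hit touching no gene is
exactly INTERGENIC.  Labels from different transcripts accumulate, so a hit
can be simultaneously intronic in one isoform and CDS in another; a
priority-collapsed single label is also provided for mutually-exclusive
summaries.  Repeat and pseudogene association is recorded alongside with
the overlap width in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from pirnakit.genomic_io import GeneModel, GenomicInterval, RepeatFeature
from pirnakit.hit_processing import GenomicHit

LABELS = ("GENE", "INTRON", "CDS", "UTR5", "UTR3", "INTERGENIC")
SUBGENE_LABELS = ("INTRON", "CDS", "UTR5", "UTR3")

# single-label collapse order for mutually-exclusive summaries
DEFAULT_PRIORITY = ("CDS", "UTR5", "UTR3", "INTRON")


@dataclass
class ContextAnnotation:
    """Accumulated context labels and feature associations for one hit."""

    hit: GenomicHit
    labels: set[str] = field(default_factory=set)
    gene_ids: list[str] = field(default_factory=list)
    repeat_hits: list[tuple[str, str, int]] = field(default_factory=list)
    pseudogene_ids: list[str] = field(default_factory=list)

    @property
    def is_repeat_associated(self) -> bool:
        return bool(self.repeat_hits)

    def collapsed_label(self, priority: Sequence[str] = DEFAULT_PRIORITY) -> str:
        """Single mutually-exclusive category per hit.

        INTERGENIC if no gene overlap; otherwise the highest-priority
        sub-gene label present, falling back to GENE for hits that overlap
        a gene span without touching any sub-feature (possible for hits in
        a transcript whose exons do not cover the whole span edge cases).
        """
        if "INTERGENIC" in self.labels:
            return "INTERGENIC"
        for lab in priority:
            if lab in self.labels:
                return lab
        return "GENE"


def _feature_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    """One interval tree per chromosome; payload = (gene, feature label)."""
    trees: dict[str, IntervalTree] = {}

    def add(iv: GenomicInterval, payload) -> None:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)

    for gene in genes:
        add(gene.span, (gene.gene_id, "GENE"))
        for iv in gene.introns:
            add(iv, (gene.gene_id, "INTRON"))
        for iv in gene.cds:
            add(iv, (gene.gene_id, "CDS"))
        for iv in gene.utr5:
            add(iv, (gene.gene_id, "UTR5"))
        for iv in gene.utr3:
            add(iv, (gene.gene_id, "UTR3"))
    return trees


def classify_hits(
    hits: Sequence[GenomicHit], genes: Sequence[GeneModel]
) -> list[ContextAnnotation]:
    """Label every hit by the gene features it overlaps (>= 1 bp, strand-blind)."""
    trees = _feature_trees(genes)
    annotations: list[ContextAnnotation] = []
    for hit in hits:
        ann = ContextAnnotation(hit)
        tree = trees.get(hit.interval.chrom)
        gene_ids: set[str] = set()
        if tree is not None:
            for node in tree.overlap(hit.interval.start, hit.interval.end):
                gene_id, label = node.data
                ann.labels.add(label)
                if label == "GENE":
                    gene_ids.add(gene_id)
        if gene_ids:
            ann.gene_ids = sorted(gene_ids)
        else:
            ann.labels = {"INTERGENIC"}
        annotations.append(ann)
    return annotations


def annotate_repeats(
    annotations: Sequence[ContextAnnotation],
    repeats: Sequence[RepeatFeature],
    min_overlap_bp: int = 1,
) -> list[ContextAnnotation]:
    """Attach (repeat_name, repeat_family, overlap_bp) for every repeat a
    hit overlaps by at least ``min_overlap_bp``; updates in place and
    returns the list for chaining."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        trees.setdefault(rep.interval.chrom, IntervalTree()).addi(
            rep.interval.start, rep.interval.end, rep
        )
    for ann in annotations:
        iv = ann.hit.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        found: list[tuple[str, str, int]] = []
        for node in tree.overlap(iv.start, iv.end):
            rep: RepeatFeature = node.data
            ov = iv.overlap_bp(rep.interval)
            if ov >= min_overlap_bp:
                found.append((rep.repeat_name, rep.repeat_family, ov))
        ann.repeat_hits.extend(sorted(found))
    return list(annotations)


def annotate_pseudogenes(
    annotations: Sequence[ContextAnnotation],
    pseudogenes: Sequence[tuple[GenomicInterval, str]],
    min_overlap_bp: int = 1,
) -> list[ContextAnnotation]:
    """Attach ids of pseudogene intervals each hit overlaps (>= min_overlap_bp)."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for iv, name in pseudogenes:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, name)
    for ann in annotations:
        iv = ann.hit.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        found = []
        for node in tree.overlap(iv.start, iv.end):
            if iv.overlap_bp(GenomicInterval(iv.chrom, node.begin, node.end)) >= min_overlap_bp:
                found.append(node.data)
        ann.pseudogene_ids.extend(sorted(found))
    return list(annotations)


def repeat_family_counts(annotations: Iterable[ContextAnnotation]) -> Counter:
    """Hits per repeat family (a hit overlapping k families counts once in
    each; multiple repeats of one family count the hit once)."""
    counts: Counter = Counter()
    for ann in annotations:
        for fam in {fam for _name, fam, _ov in ann.repeat_hits}:
            counts[fam] += 1
    return counts


def summarize_contexts(
    annotations: Sequence[ContextAnnotation],
) -> dict[str, dict[str, int]]:
    """Per-category hit counts split by repeat association.

    Categories are UTR5, UTR3, CDS, INTRON and INTERGENIC; a hit carrying
    k of these labels contributes to all k rows (multi-counting), so
    column sums can exceed the hit count.
    """
    categories = ("UTR5", "UTR3", "CDS", "INTRON", "INTERGENIC")
    table = {
        cat: {"total": 0, "repeat": 0, "non_repeat": 0} for cat in categories
    }
    for ann in annotations:
        for cat in categories:
            if cat in ann.labels:
                table[cat]["total"] += 1
                key = "repeat" if ann.is_repeat_associated else "non_repeat"
                table[cat][key] += 1
    return table
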