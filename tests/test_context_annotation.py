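"""Genomic-context classification against a per-base brute-force oracle,
plus repeat/pseudogene association and the category summary."""

import numpy as np
import pytest

from conftest import random_hits
from oracles import per_base_context
from pirnakit.context_annotation import (
    annotate_pseudogenes,
    annotate_repeats,
    classify_hits,
    repeat_family_counts,
    summarize_contexts,
)
from pirnakit.genomic_io import GenomicInterval, RepeatFeature, build_gene_model
from pirnakit.hit_processing import GenomicHit


def random_gene_models(rng: np.random.Generator, n: int, chrom="chrT",
                       chrom_len=100_000):
    """Random transcript models with 1-4 exons and optional CDS whose
    extent endpoints are guaranteed exonic."""
    genes = []
    for i in range(n):
        span_len = int(rng.integers(1_000, 15_000))
        start = int(rng.integers(0, chrom_len - span_len))
        n_exons = int(rng.integers(1, 5))
        cuts = sorted(rng.choice(np.arange(1, span_len), size=2 * n_exons - 2,
                                 replace=False).tolist()) if n_exons > 1 else []
        bounds = [0] + cuts + [span_len]
        exons = [(start + bounds[2 * k], start + bounds[2 * k + 1])
                 for k in range(n_exons)]
        cds_extent = None
        if rng.random() < 0.7:
            lo_exon = exons[0]
            hi_exon = exons[-1]
            lo = int(rng.integers(lo_exon[0], lo_exon[1]))
            hi = int(rng.integers(max(lo + 1, hi_exon[0] + 1), hi_exon[1] + 1))
            if hi > lo:
                cds_extent = (lo, hi)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            build_gene_model(f"g{i}", f"G{i}", chrom, strand,
                             start, start + span_len, exons, cds_extent)
        )
    return genes


class TestClassifyHits:
    def _gene(self):
        # span [1000,9000), exons [1000,3000)+[6000,9000), CDS [2000,8000)
        return build_gene_model("g1", "G1", "chr1", "+", 1000, 9000,
                                [(1000, 3000), (6000, 9000)], (2000, 8000))

    def _hit(self, start, end, chrom="chr1"):
        return GenomicHit("h", GenomicInterval(chrom, start, end, "+"), 0.0)

    def test_intronic_hit(self):
        (ann,) = classify_hits([self._hit(4000, 4030)], [self._gene()])
        assert ann.labels == {"GENE", "INTRON"}
        assert ann.gene_ids == ["g1"]

    def test_exon_intron_boundary_in_cds(self):
        (ann,) = classify_hits([self._hit(2990, 3020)], [self._gene()])
        assert ann.labels == {"GENE", "INTRON", "CDS"}

    def test_intergenic_hit(self):
        (ann,) = classify_hits([self._hit(20_000, 20_030)], [self._gene()])
        assert ann.labels == {"INTERGENIC"}
        assert ann.collapsed_label() == "INTERGENIC"

    def test_collapse_priority(self):
        (ann,) = classify_hits([self._hit(2990, 3020)], [self._gene()])
        assert ann.collapsed_label() == "CDS"
        assert ann.collapsed_label(priority=("INTRON", "CDS")) == "INTRON"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = random_gene_models(rng, 10)
        hits = random_hits(rng, 200)
        annotations = classify_hits(hits, genes)
        for ann, hit in zip(annotations, hits):
            assert ann.labels == per_base_context(hit, genes), hit

    def test_gene_intergenic_partition(self):
        rng = np.random.default_rng(99)
        genes = random_gene_models(rng, 8)
        hits = random_hits(rng, 150)
        annotations = classify_hits(hits, genes)
        n_gene = sum("GENE" in a.labels for a in annotations)
        n_inter = sum("INTERGENIC" in a.labels for a in annotations)
        assert n_gene + n_inter == len(hits)
        assert all(("GENE" in a.labels) != ("INTERGENIC" in a.labels)
                   for a in annotations)

    def test_adding_gene_never_creates_intergenic(self):
        rng = np.random.default_rng(5)
        genes = random_gene_models(rng, 6)
        hits = random_hits(rng, 100)
        before = classify_hits(hits, genes[:3])
        after = classify_hits(hits, genes)
        for b, a in zip(before, after):
            if "GENE" in b.labels:
                assert "GENE" in a.labels

    def test_fixture_truth_labels(self, fixture_bundle):
        bundle, truth = fixture_bundle
        annotations = classify_hits(bundle.hits_a, bundle.genes)
        by_id = {a.hit.pirna_id: a for a in annotations}
        for pid, labels in truth.context_labels.items():
            assert by_id[pid].labels == set(labels), pid


class TestRepeatAssociation:
    def _repeat(self, start, end, name="AluY", family="Alu", cls="SINE"):
        return RepeatFeature(GenomicInterval("chr1", start, end, "+"),
                             name, family, cls)

    def _ann(self, start, end):
        hit = GenomicHit("h", GenomicInterval("chr1", start, end, "+"), 0.0)
        return classify_hits([hit], [])[0]

    def test_overlap_width_recorded(self):
        ann = self._ann(100, 130)
        annotate_repeats([ann], [self._repeat(120, 300)])
        assert ann.repeat_hits == [("AluY", "Alu", 10)]
        assert ann.is_repeat_associated

    def test_min_overlap_threshold(self):
        ann = self._ann(100, 130)
        annotate_repeats([ann], [self._repeat(120, 300)], min_overlap_bp=15)
        assert not ann.is_repeat_associated

    def test_fixture_truth_memberships(self, fixture_bundle):
        bundle, truth = fixture_bundle
        annotations = classify_hits(bundle.hits_a, bundle.genes)
        annotate_repeats(annotations, bundle.repeats)
        by_id = {a.hit.pirna_id: a for a in annotations}
        for pid, names in truth.repeat_members.items():
            got = tuple(sorted({n for n, _f, _o in by_id[pid].repeat_hits}))
            assert got == tuple(sorted(names)), pid

    def test_family_counts_match_brute_force(self, fixture_bundle):
        bundle, _ = fixture_bundle
        annotations = classify_hits(bundle.hits_a, bundle.genes)
        annotate_repeats(annotations, bundle.repeats)
        counts = repeat_family_counts(annotations)
        expected = {}
        for h in bundle.hits_a:
            fams = {r.repeat_family for r in bundle.repeats
                    if h.interval.overlap_bp(r.interval) >= 1}
            for fam in fams:
                expected[fam] = expected.get(fam, 0) + 1
        assert dict(counts) == expected


class TestPseudogenes:
    def test_contained_and_double_overlap(self, fixture_bundle):
        bundle, truth = fixture_bundle
        annotations = classify_hits(bundle.hits_a, bundle.genes)
        annotate_pseudogenes(annotations, bundle.pseudogenes)
        by_id = {a.hit.pirna_id: a for a in annotations}
        for pid, names in truth.pseudogene_members.items():
            assert tuple(sorted(by_id[pid].pseudogene_ids)) == tuple(sorted(names))


class TestSummary:
    def test_small_example(self):
        hits = [
            GenomicHit("a", GenomicInterval("c", 0, 30, "+"), 0.0),
            GenomicHit("b", GenomicInterval("c", 100, 130, "+"), 0.0),
            GenomicHit("d", GenomicInterval("c", 200, 230, "+"), 0.0),
        ]
        gene = build_gene_model("g", "G", "c", "+", 90, 150, [(90, 100), (140, 150)], None)
        annotations = classify_hits(hits, [gene])
        annotate_repeats(
            annotations,
            [RepeatFeature(GenomicInterval("c", 0, 50, "+"), "R", "F", "K")],
        )
        table = summarize_contexts(annotations)
        assert table["INTERGENIC"] == {"total": 2, "repeat": 1, "non_repeat": 1}
        assert table["INTRON"] == {"total": 1, "repeat": 0, "non_repeat": 1}

    def test_empty_input_all_zero(self):
        table = summarize_contexts([])
        assert all(v == {"total": 0, "repeat": 0, "non_repeat": 0}
                   for v in table.values())
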