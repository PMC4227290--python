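"""Cluster calling against the exhaustive window-scan oracle, score and
directionality closed forms, GC profiling, track overlap and synteny
projection."""

import numpy as np
import pytest

from conftest import random_hits
from oracles import exhaustive_clusters
from pirnakit.cluster_calling import (
    ClusterParams,
    call_clusters,
    classify_directionality,
    cluster_gc,
    map_to_synteny,
    overlap_clusters,
    project_through_block,
    read_clusters_tsv,
    score_cluster,
    write_clusters_tsv,
)
from pirnakit.genomic_io import GenomicInterval, SyntenyBlock
from pirnakit.hit_processing import GenomicHit


def _hits(positions, chrom="chrT", strand="+", length=30):
    return [
        GenomicHit(f"h{i}", GenomicInterval(chrom, p, p + length, strand), 0.0)
        for i, p in enumerate(sorted(positions))
    ]


def _as_tuples(clusters):
    return [
        (c.interval.chrom, c.interval.start, c.interval.end,
         c.n_pirnas, c.plus_count, c.minus_count, c.member_ids)
        for c in clusters
    ]


class TestCallClusters:
    def test_isolated_dense_block(self):
        positions = list(np.linspace(0, 4970, 25).astype(int)) + [60_000]
        clusters = call_clusters(_hits(positions))
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_pirnas == 25
        assert c.interval.start == positions[0]
        assert c.interval.end == positions[24] + 30
        assert c.cluster_id == "chrT.1"

    def test_below_threshold_no_cluster(self):
        positions = np.linspace(0, 19_000, 19).astype(int)
        assert call_clusters(_hits(positions)) == []

    def test_unsorted_input_rejected(self):
        hits = _hits([100, 50])
        hits.reverse()
        with pytest.raises(ValueError, match="sorted"):
            call_clusters(hits)

    def test_empty_input(self):
        assert call_clusters([]) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 301))
        hits = random_hits(rng, n)
        got = _as_tuples(call_clusters(hits))
        expected = exhaustive_clusters(hits)
        assert got == expected

    def test_clusters_disjoint_and_dense(self):
        rng = np.random.default_rng(42)
        hits = random_hits(rng, 300, chrom_len=60_000)  # dense instance
        clusters = call_clusters(hits)
        assert clusters
        for c in clusters:
            assert c.n_pirnas >= 20
            assert c.plus_count + c.minus_count == c.n_pirnas
        for a, b in zip(clusters, clusters[1:]):
            assert a.interval.end <= b.interval.start

    def test_every_hit_in_cluster_interval_is_counted(self):
        rng = np.random.default_rng(17)
        hits = random_hits(rng, 250, chrom_len=50_000)
        clusters = call_clusters(hits)
        for c in clusters:
            inside = [h for h in hits
                      if c.interval.start <= h.interval.start < c.interval.end]
            assert len(inside) == c.n_pirnas

    def test_raising_density_never_adds_clusters(self):
        rng = np.random.default_rng(8)
        hits = random_hits(rng, 300, chrom_len=80_000)
        n_by_density = [
            len(call_clusters(hits, ClusterParams(min_density=d)))
            for d in (10, 20, 30, 40)
        ]
        assert n_by_density == sorted(n_by_density, reverse=True)

    def test_planted_fixture_recovery(self, fixture_bundle):
        bundle, truth = fixture_bundle
        clusters = call_clusters(bundle.hits_a)
        called = {(c.interval.chrom, c.interval.start, c.interval.end,
                   c.n_pirnas, c.plus_count, c.minus_count) for c in clusters}
        for p in truth.planted_clusters:
            assert (p.chrom, p.start, p.end, p.n_hits,
                    p.plus_count, p.minus_count) in called


class TestScore:
    def test_closed_forms(self):
        params = ClusterParams()
        assert score_cluster(20, 1000, params) == pytest.approx(20.0)
        assert score_cluster(40, 1000, params) == pytest.approx(40.0)
        assert score_cluster(20, 2000, params) == pytest.approx(10.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            score_cluster(20, 0)

    def test_monotonicity(self):
        params = ClusterParams()
        assert score_cluster(21, 1000, params) > score_cluster(20, 1000, params)
        assert score_cluster(20, 1001, params) < score_cluster(20, 1000, params)


class TestDirectionality:
    @pytest.mark.parametrize(
        "plus,minus,fraction,expected",
        [
            (30, 0, 0.2, "mono_plus"),
            (0, 30, 0.2, "mono_minus"),
            (15, 15, 0.2, "bidirectional"),
            (15, 15, 0.5, "bidirectional"),
            (27, 3, 0.2, "mono_plus"),
            (27, 3, 0.1, "bidirectional"),
        ],
    )
    def test_threshold_behaviour(self, plus, minus, fraction, expected):
        assert classify_directionality(plus, minus, fraction) == expected

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            classify_directionality(1, 1, 0.6)


class TestClusterGc:
    def _cluster(self, start, end, chrom="c"):
        from pirnakit.cluster_calling import ClusterRecord
        return ClusterRecord(f"{chrom}.1", GenomicInterval(chrom, start, end),
                             20, 20, 0, "mono_plus", 1.0)

    def test_extreme_slices(self):
        genome = {"c": "GGCC" * 10 + "AATT" * 10}
        assert cluster_gc(self._cluster(0, 40), genome) == pytest.approx(100.0)
        assert cluster_gc(self._cluster(40, 80), genome) == pytest.approx(0.0)

    def test_recount_on_random_slice(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        expected = 100.0 * sum(b in "GC" for b in seq[100:400]) / 300
        assert cluster_gc(self._cluster(100, 400), {"c": seq}) == pytest.approx(expected)

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            cluster_gc(self._cluster(0, 100), {"c": "ACGT"})

    def test_fixture_gc_extremes(self, fixture_bundle):
        bundle, truth = fixture_bundle
        from pirnakit.seq_tools import gc_percent
        s, e = truth.gc_extreme["all_gc"]
        assert gc_percent(bundle.genome_a["chr1"][s:e]) == 100.0
        s, e = truth.gc_extreme["all_at"]
        assert gc_percent(bundle.genome_a["chr1"][s:e]) == 0.0


class TestOverlapClusters:
    def test_boundary_semantics(self):
        from pirnakit.cluster_calling import ClusterRecord
        c = ClusterRecord("c.1", GenomicInterval("c", 100, 200), 20, 20, 0,
                          "mono_plus", 1.0)
        overlap_clusters([c], [(GenomicInterval("c", 199, 300), "geneA"),
                               (GenomicInterval("c", 200, 300), "geneB")], "gene")
        assert c.gene_ids == ["geneA"]
        with pytest.raises(ValueError):
            overlap_clusters([c], [], "enhancer")

    def test_fixture_promoters_attach(self, fixture_bundle):
        bundle, truth = fixture_bundle
        clusters = call_clusters(bundle.hits_a)
        overlap_clusters(clusters, bundle.promoters, "promoter")
        planted = {(p.chrom, p.start) for p in truth.planted_clusters}
        for c in clusters:
            if (c.interval.chrom, c.interval.start) in planted:
                assert c.promoter_ids, c.cluster_id


class TestSynteny:
    def test_same_orientation_projection(self):
        block = SyntenyBlock(GenomicInterval("chr1", 0, 10_000),
                             GenomicInterval("chrB", 50_000, 60_000), "same")
        proj = project_through_block(GenomicInterval("chr1", 2000, 3000), block)
        assert (proj.chrom, proj.start, proj.end) == ("chrB", 52_000, 53_000)

    def test_inverted_projection_reflects(self):
        block = SyntenyBlock(GenomicInterval("chr1", 0, 10_000),
                             GenomicInterval("chrB", 50_000, 60_000), "inverted")
        proj = project_through_block(GenomicInterval("chr1", 2000, 3000), block)
        assert (proj.start, proj.end) == (57_000, 58_000)

    def test_projected_pair_reported(self):
        from pirnakit.cluster_calling import ClusterRecord
        block = SyntenyBlock(GenomicInterval("chr1", 0, 10_000),
                             GenomicInterval("chrB", 50_000, 60_000), "same")
        src = ClusterRecord("chr1.1", GenomicInterval("chr1", 2000, 3000),
                            20, 20, 0, "mono_plus", 1.0)
        tgt = ClusterRecord("chrB.1", GenomicInterval("chrB", 52_500, 54_000),
                            20, 20, 0, "mono_plus", 1.0)
        assert [(s, t) for s, t, _b in map_to_synteny([src], [block], [tgt])] == \
            [("chr1.1", "chrB.1")]

    def test_fixture_conserved_pairs_match_truth(self, fixture_bundle):
        bundle, truth = fixture_bundle
        src_clusters = call_clusters(bundle.hits_a)
        tgt_clusters = call_clusters(bundle.hits_b)
        pairs = map_to_synteny(src_clusters, bundle.synteny_blocks, tgt_clusters)
        got = {(s, t) for s, t, _b in pairs}

        def find(clusters, planted):
            return next(c.cluster_id for c in clusters
                        if (c.interval.chrom, c.interval.start) ==
                        (planted.chrom, planted.start))

        expected = {
            (find(src_clusters, truth.planted_clusters[i]),
             find(tgt_clusters, truth.planted_clusters_target[j]))
            for i, j, _block in truth.conserved_pairs
        }
        assert got == expected


def test_clusters_tsv_roundtrip(tmp_path, fixture_bundle):
    bundle, _ = fixture_bundle
    clusters = call_clusters(bundle.hits_a)
    for c in clusters:
        c.gc_percent = cluster_gc(c, bundle.genome_a)
    overlap_clusters(clusters, bundle.promoters, "promoter")
    path = tmp_path / "clusters.tsv"
    write_clusters_tsv(clusters, path)
    back = read_clusters_tsv(path)
    assert [c.cluster_id for c in back] == [c.cluster_id for c in clusters]
    assert [c.member_ids for c in back] == [c.member_ids for c in clusters]
    for a, b in zip(clusters, back):
        assert b.gc_percent == pytest.approx(a.gc_percent, abs=1e-3)
        assert b.promoter_ids == a.promoter_ids
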