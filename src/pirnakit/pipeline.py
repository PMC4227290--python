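"""End-to-end pipeline: filter -> blacklist -> uniqueness -> context /
repeat / pseudogene annotation -> Ping-Pong partners -> clusters (score,
directionality, GC, track overlaps) -> expression ranking.

Every stage writes one diff-able TSV; a ``manifest.json`` records the
package version, all parameters and the SHA-256 of every input, so a run
is reproducible from the manifest alone.  Partial outputs are removed if
any stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pirnakit
from pirnakit import context_annotation as ctx
from pirnakit import cluster_calling as cc
from pirnakit import expression_profiles as expr
from pirnakit import genomic_io as gio
from pirnakit import hit_processing as hp
from pirnakit import pingpong as pp
from pirnakit.config import RunConfig

log = logging.getLogger("pirnakit")

PAIRS_TSV_HEADER = (
    "chrom", "plus_id", "plus_start", "minus_id", "minus_end",
    "overlap", "sense_1U", "antisense_10A",
)

ANNOT_TSV_HEADER = (
    "pirna_id", "chrom", "start", "end", "strand", "labels", "collapsed",
    "gene_ids", "repeat_names", "pseudogene_ids", "is_repeat_associated",
)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_pairs_tsv(pairs, path) -> None:
    gio.write_tsv(
        path,
        PAIRS_TSV_HEADER,
        (
            (
                p.sense_hit.interval.chrom,
                p.sense_hit.pirna_id, p.sense_hit.interval.start,
                p.antisense_hit.pirna_id, p.antisense_hit.interval.end,
                p.five_prime_overlap,
                int(p.sense_has_1U), int(p.antisense_has_10A),
            )
            for p in pairs
        ),
    )


def write_annotations_tsv(annotations, path) -> None:
    def row(a: ctx.ContextAnnotation):
        iv = a.hit.interval
        return (
            a.hit.pirna_id, iv.chrom, iv.start, iv.end, iv.strand,
            ";".join(sorted(a.labels)), a.collapsed_label(),
            ";".join(a.gene_ids),
            ";".join(sorted({name for name, _f, _o in a.repeat_hits})),
            ";".join(sorted(set(a.pseudogene_ids))),
            int(a.is_repeat_associated),
        )

    gio.write_tsv(path, ANNOT_TSV_HEADER, (row(a) for a in annotations))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns the manifest dictionary.

    Requires ``blast`` and ``fasta`` inputs; every other track is
    optional and simply skips its stage when absent.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    for required in ("blast", "fasta"):
        if getattr(config, required) is None:
            raise ValueError(f"pipeline requires the {required!r} input")
    input_paths = {
        name: getattr(config, name)
        for name in ("blast", "fasta", "genome", "genes", "repeats",
                     "pseudogenes", "promoters", "blacklist", "reads", "catalogue")
        if getattr(config, name) is not None
    }
    for name, path in input_paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"missing {name} input: {path}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        path = out_dir / name
        written.append(path)
        return path

    try:
        sequences = gio.read_fasta(config.fasta)
        rows = gio.read_blast_tabular(
            config.blast, {pid: len(s) for pid, s in sequences.items()}
        )
        hits = hp.filter_alignments(
            rows,
            evalue_max=config.evalue_max,
            max_mismatch=config.max_mismatch,
            max_gaps=config.max_gaps,
            require_full_length=config.require_full_length,
        )
        log.info("filtered alignments: %d of %d survive", len(hits), len(rows))
        if config.blacklist:
            blacklist = [iv for iv, _name in gio.read_bed4(config.blacklist)]
            hits = hp.subtract_ncrna(hits, blacklist)
            log.info("after ncRNA blacklist: %d hits", len(hits))
        hits = hp.flag_unique_mappers(hits)
        hp.write_hits_tsv(hits, out("hits.tsv"))

        annotations = None
        if config.genes:
            genes = gio.read_gene_models(config.genes, config.gene_dialect)
            annotations = ctx.classify_hits(hits, genes)
            if config.repeats:
                ctx.annotate_repeats(annotations, gio.read_repeatmasker(config.repeats))
            if config.pseudogenes:
                ctx.annotate_pseudogenes(annotations, gio.read_bed4(config.pseudogenes))
            write_annotations_tsv(annotations, out("annotations.tsv"))
            summary = ctx.summarize_contexts(annotations)
            gio.write_tsv(
                out("context_summary.tsv"),
                ("category", "total", "repeat", "non_repeat"),
                ((cat, v["total"], v["repeat"], v["non_repeat"])
                 for cat, v in summary.items()),
            )

        pairs = pp.find_partners(
            hits, sequences,
            overlap=config.pingpong_overlap,
            require_signature=config.require_signature,
        )
        write_pairs_tsv(pairs, out("pingpong_pairs.tsv"))

        params = cc.ClusterParams(
            window_length=config.window_length,
            step=config.step,
            min_density=config.min_density,
            extension_step=config.extension_step,
        )
        cluster_input = [h for h in hits if h.is_unique] if config.unique_only else hits
        cluster_input = sorted(
            cluster_input, key=lambda h: (h.interval.chrom, h.interval.start)
        )
        clusters = cc.call_clusters(
            cluster_input, params, bidir_min_fraction=config.bidir_min_fraction
        )
        if config.genome:
            genome = gio.read_fasta(config.genome)
            for cluster in clusters:
                cluster.gc_percent = cc.cluster_gc(cluster, genome)
        if config.genes:
            gene_feats = [(g.span, g.gene_id) for g in gio.read_gene_models(
                config.genes, config.gene_dialect)]
            cc.overlap_clusters(clusters, gene_feats, "gene")
        if config.repeats:
            rep_feats = [(r.interval, r.repeat_name)
                         for r in gio.read_repeatmasker(config.repeats)]
            cc.overlap_clusters(clusters, rep_feats, "repeat")
        if config.promoters:
            cc.overlap_clusters(clusters, gio.read_bed4(config.promoters), "promoter")
        if config.pseudogenes:
            cc.overlap_clusters(clusters, gio.read_bed4(config.pseudogenes), "pseudogene")
        cc.write_clusters_tsv(clusters, out("clusters.tsv"))

        if config.reads and config.catalogue:
            catalogue = gio.read_fasta(config.catalogue)
            reads = gio.read_read_sequences(config.reads)
            profile = expr.count_abundance(reads, catalogue)
            ranked = expr.top_n(profile, config.top_n)
            gio.write_tsv(
                out("expression_top.tsv"),
                ("rank", "pirna_id", "count"),
                ((i + 1, pid, c) for i, (pid, c) in enumerate(ranked)),
            )

        manifest = {
            "pirnakit_version": pirnakit.__version__,
            "parameters": config.to_dict(),
            "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                       for name, p in input_paths.items()},
            "outputs": [p.name for p in written],
        }
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
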