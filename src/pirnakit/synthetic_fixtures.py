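"""Deterministic synthetic fixture generator.

Builds a toy two-genome study — a "source" genome with three chromosomes
and a single-chromosome "target" genome — together with every annotation
track the toolkit consumes and machine-readable truth tables:

* planted piRNA clusters of known boundaries, hit counts and strand mix,
  separated so that window scanning recovers them unambiguously;
* planted Ping-Pong pairs with exact 10-nt 5' overlaps and genome-
  consistent sequences (sense 1U forced, so antisense 10A follows from
  complementarity), plus decoy pairs at overlaps 8/9/11/12 bracketing the
  true offset on both sides;
* gene models (GTF) with exon/CDS/UTR structure and hits planted at
  engineered positions with known context labels;
* repeat, pseudogene, promoter and ncRNA-blacklist tracks with truth
  memberships;
* a BLAST-tabular alignment table whose rows are consistent with the
  genome (hit sequence equals the genomic slice, reverse-complemented on
  the minus strand), including rows that deliberately fail the alignment
  filters;
* a small-RNA read set drawn from a recorded multinomial, and synteny
  blocks carrying planted conserved cluster pairs.

Every random draw flows from one seeded generator, so regeneration with
the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pirnakit.genomic_io import (
    AlignmentRow,
    GeneModel,
    GenomicInterval,
    RepeatFeature,
    SyntenyBlock,
    build_gene_model,
    reverse_complement,
    write_bed4,
    write_fasta,
    write_synteny,
    write_tsv,
)
from pirnakit.hit_processing import GenomicHit

MAX_GENOME_BP = 1_000_000
MAX_CHROMS = 5

# chromosome lengths, bp
CHR_LENGTHS_A = {"chr1": 200_000, "chr2": 150_000, "chr3": 200_000}
CHR_LENGTHS_B = {"chrB1": 150_000}

# piRNA length range used for all planted hits
HIT_LEN_LO, HIT_LEN_HI = 26, 32

# planted cluster layout: (chrom, plus_zone, n_plus, minus_zone, n_minus)
CLUSTER_SPECS_A = (
    ("chr1", (10_000, 14_000), 25, None, 0),
    ("chr1", (60_000, 62_800), 25, (63_000, 66_000), 15),
    ("chr2", (20_000, 20_900), 3, (21_100, 25_000), 27),
)
CLUSTER_SPECS_B = (
    ("chrB1", (30_000, 34_000), 25, None, 0),
    ("chrB1", (100_000, 103_000), 18, (103_200, 105_000), 12),
)

PINGPONG_CHROM = "chr3"
PINGPONG_START = 2_000
PINGPONG_SPACING = 2_500  # keeps chr3 density below the cluster threshold
DECOY_OFFSETS = (8, 9, 11, 12)


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the generator; defaults define the packaged study conditions."""

    n_pingpong_pairs: int = 30
    n_decoy_pairs_per_offset: int = 12
    n_multimapper_ids: int = 16
    n_catalogue: int = 50
    n_reads: int = 600
    n_junk_reads: int = 25
    gc_fraction: float = 0.40

    def __post_init__(self) -> None:
        total = sum(CHR_LENGTHS_A.values()) + sum(CHR_LENGTHS_B.values())
        if total > MAX_GENOME_BP:
            raise ValueError("fixture genome exceeds 1 Mb bound")
        if len(CHR_LENGTHS_A) > MAX_CHROMS or len(CHR_LENGTHS_B) > MAX_CHROMS:
            raise ValueError("fixture genome exceeds chromosome bound")
        n_pp_regions = self.n_pingpong_pairs + 4 * self.n_decoy_pairs_per_offset
        if PINGPONG_START + n_pp_regions * PINGPONG_SPACING > CHR_LENGTHS_A[PINGPONG_CHROM]:
            raise ValueError("too many Ping-Pong pairs for chr3")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")


@dataclass
class PlantedCluster:
    chrom: str
    start: int       # first hit start
    end: int         # last hit end (exclusive)
    n_hits: int
    plus_count: int
    minus_count: int
    hit_ids: tuple[str, ...]


@dataclass
class FixtureTruth:
    """Ground truth for everything the generator planted."""

    seed: int
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    planted_clusters_target: list[PlantedCluster] = field(default_factory=list)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    decoy_pair_ids: list[tuple[str, str, int]] = field(default_factory=list)
    context_labels: dict[str, frozenset[str]] = field(default_factory=dict)
    repeat_members: dict[str, tuple[str, ...]] = field(default_factory=dict)
    pseudogene_members: dict[str, tuple[str, ...]] = field(default_factory=dict)
    blacklisted_ids: frozenset[str] = frozenset()
    failing_alignment_ids: frozenset[str] = frozenset()
    multiplicity: dict[str, int] = field(default_factory=dict)
    expression_draws: dict[str, int] = field(default_factory=dict)
    n_junk_reads: int = 0
    conserved_pairs: list[tuple[int, int, int]] = field(default_factory=list)
    gc_extreme: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class FixtureBundle:
    """In-memory fixture: genomes, tracks, hits, sequences and reads."""

    genome_a: dict[str, str]
    genome_b: dict[str, str]
    sequences_a: dict[str, str]
    sequences_b: dict[str, str]
    alignments_a: list[AlignmentRow]
    alignments_b: list[AlignmentRow]
    hits_a: list[GenomicHit]
    hits_b: list[GenomicHit]
    genes: list[GeneModel]
    repeats: list[RepeatFeature]
    pseudogenes: list[tuple[GenomicInterval, str]]
    promoters: list[tuple[GenomicInterval, str]]
    blacklist: list[tuple[GenomicInterval, str]]
    synteny_blocks: list[SyntenyBlock]
    reads: list[str]
    catalogue: dict[str, str]


class _IdCounter:
    def __init__(self, org: str) -> None:
        self.org = org
        self.n = 0

    def next(self) -> str:
        self.n += 1
        return f"{self.org}_piRNA_{self.n}"


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _place_starts(
    rng: np.random.Generator, zone: tuple[int, int], n: int
) -> list[int]:
    lo, hi = zone
    candidates = np.arange(lo, hi - HIT_LEN_HI)
    starts = rng.choice(candidates, size=n, replace=False)
    return sorted(int(s) for s in starts)


def _plant_cluster(
    rng: np.random.Generator,
    counter: _IdCounter,
    spec: tuple,
    records: list[dict],
) -> PlantedCluster:
    chrom, plus_zone, n_plus, minus_zone, n_minus = spec
    hit_ids: list[str] = []
    placed: list[tuple[int, int, str]] = []
    for zone, n, strand in ((plus_zone, n_plus, "+"), (minus_zone, n_minus, "-")):
        if zone is None or n == 0:
            continue
        for s in _place_starts(rng, zone, n):
            length = int(rng.integers(HIT_LEN_LO, HIT_LEN_HI + 1))
            placed.append((s, s + length, strand))
    placed.sort()
    for s, e, strand in placed:
        pid = counter.next()
        hit_ids.append(pid)
        records.append({"id": pid, "chrom": chrom, "start": s, "end": e, "strand": strand})
    return PlantedCluster(
        chrom=chrom,
        start=placed[0][0],
        end=max(e for _s, e, _str in placed),
        n_hits=len(placed),
        plus_count=sum(1 for p in placed if p[2] == "+"),
        minus_count=sum(1 for p in placed if p[2] == "-"),
        hit_ids=tuple(hit_ids),
    )


def _gene_models() -> list[GeneModel]:
    gene_a = build_gene_model(
        "TX_A", "GENA", "chr1", "+", 110_000, 120_000,
        [(110_000, 112_000), (115_000, 117_000), (119_000, 120_000)],
        (111_000, 119_500),
    )
    gene_b = build_gene_model(
        "TX_B", "GENB", "chr1", "-", 130_000, 138_000,
        [(130_000, 131_000), (136_000, 138_000)],
        (130_500, 137_000),
    )
    gene_c = build_gene_model(
        "TX_C", "GENC", "chr1", "+", 150_000, 151_000,
        [(150_000, 151_000)], None,
    )
    return [gene_a, gene_b, gene_c]


# (start, length, truth label set) for context-truth hits on chr1
_CONTEXT_HITS = (
    (113_000, 30, {"GENE", "INTRON"}),
    (115_100, 30, {"GENE", "CDS"}),
    (110_200, 30, {"GENE", "UTR5"}),
    (119_600, 30, {"GENE", "UTR3"}),
    (111_990, 30, {"GENE", "CDS", "INTRON"}),
    (144_000, 30, {"INTERGENIC"}),
    (137_100, 30, {"GENE", "UTR5"}),
    (150_400, 30, {"GENE"}),
    (109_980, 30, {"GENE", "UTR5"}),
)


def _repeat_track() -> list[RepeatFeature]:
    mk = lambda c, s, e, n, f, k, strand="+": RepeatFeature(
        GenomicInterval(c, s, e, strand), n, f, k
    )
    return [
        mk("chr1", 165_000, 165_300, "AluY", "Alu", "SINE"),
        mk("chr1", 170_000, 176_000, "L1MA4", "L1", "LINE", "-"),
        mk("chr1", 180_000, 181_500, "ERVK-int", "ERVK", "LTR"),
        mk("chr1", 185_000, 185_100, "(AT)n", "Simple_repeat", "Simple_repeat"),
    ]


# (start, length, truth repeat names)
_REPEAT_HITS = (
    (165_100, 30, ("AluY",)),
    (165_290, 30, ("AluY",)),       # 10 bp edge overlap
    (172_000, 30, ("L1MA4",)),
    (178_000, 30, ()),
    (185_020, 30, ("(AT)n",)),
)

_PSEUDOGENES = (
    ("chr1", 187_000, 188_000, "PG1"),
    ("chr1", 187_500, 188_500, "PG2"),
)

# (start, length, truth pseudogene ids)
_PSEUDOGENE_HITS = (
    (187_100, 30, ("PG1",)),
    (187_600, 30, ("PG1", "PG2")),
    (189_000, 30, ()),
)

_BLACKLIST = (
    ("chr2", 125_000, 125_500, "rRNA_1"),
    ("chr2", 130_000, 130_200, "tRNA_1"),
    ("chr2", 140_000, 140_100, "snoRNA_1"),
)

# (start, length, is_blacklisted)
_BLACKLIST_HITS = (
    (125_480, 30, True),    # 20 bp overlap with rRNA_1
    (130_050, 30, True),
    (125_500, 30, False),   # starts exactly at the half-open blacklist end
    (140_070, 30, True),
    (126_500, 30, False),
    (139_900, 30, False),
)

# spacing keeps any 20 kb window on the multimapper zone below the
# cluster density threshold even at the maximum locus count (16 ids x 4)
MULTIMAPPER_ZONE = (48_000, 120_000)   # chr2
MULTIMAPPER_SPACING = 1_125


def generate_fixture(
    seed: int,
    config: FixtureConfig = FixtureConfig(),
    out_dir: str | Path | None = None,
) -> tuple[FixtureBundle, FixtureTruth]:
    """Generate the fixture bundle (and optionally write it to ``out_dir``)."""
    rng = np.random.default_rng(seed)
    truth = FixtureTruth(seed=seed)

    genome_a = {c: _random_genome(rng, n, config.gc_fraction) for c, n in CHR_LENGTHS_A.items()}
    genome_b = {c: _random_genome(rng, n, config.gc_fraction) for c, n in CHR_LENGTHS_B.items()}

    # GC-extreme segments on chr1 for GC-content edge tests
    genome_a["chr1"][195_000:195_100] = list("GC" * 50)
    genome_a["chr1"][195_100:195_200] = list("AT" * 50)
    truth.gc_extreme = {"all_gc": (195_000, 195_100), "all_at": (195_100, 195_200)}

    counter_a = _IdCounter("hsa")
    counter_b = _IdCounter("mmu")
    records_a: list[dict] = []
    records_b: list[dict] = []

    # --- planted clusters -------------------------------------------------
    for spec in CLUSTER_SPECS_A:
        truth.planted_clusters.append(_plant_cluster(rng, counter_a, spec, records_a))
    for spec in CLUSTER_SPECS_B:
        truth.planted_clusters_target.append(_plant_cluster(rng, counter_b, spec, records_b))

    # --- Ping-Pong pairs and decoys on chr3 -------------------------------
    chr3 = genome_a[PINGPONG_CHROM]
    region = 0

    def plant_pair(offset: int) -> tuple[str, str]:
        nonlocal region
        p = PINGPONG_START + region * PINGPONG_SPACING
        region += 1
        lp = int(rng.integers(HIT_LEN_LO, HIT_LEN_HI + 1))
        lm = int(rng.integers(HIT_LEN_LO, HIT_LEN_HI + 1))
        chr3[p] = "T"  # force sense 1U; antisense 10A follows by complementarity
        plus_id = counter_a.next()
        minus_id = counter_a.next()
        records_a.append({"id": plus_id, "chrom": PINGPONG_CHROM,
                          "start": p, "end": p + lp, "strand": "+"})
        records_a.append({"id": minus_id, "chrom": PINGPONG_CHROM,
                          "start": p + offset - lm, "end": p + offset, "strand": "-"})
        return plus_id, minus_id

    for _ in range(config.n_pingpong_pairs):
        truth.planted_pairs.append(plant_pair(10))
    for offset in DECOY_OFFSETS:
        for _ in range(config.n_decoy_pairs_per_offset):
            pid, mid = plant_pair(offset)
            truth.decoy_pair_ids.append((pid, mid, offset))

    # --- context / repeat / pseudogene / blacklist truth hits -------------
    for start, length, labels in _CONTEXT_HITS:
        pid = counter_a.next()
        records_a.append({"id": pid, "chrom": "chr1", "start": start,
                          "end": start + length, "strand": "+"})
        truth.context_labels[pid] = frozenset(labels)
    for start, length, names in _REPEAT_HITS:
        pid = counter_a.next()
        records_a.append({"id": pid, "chrom": "chr1", "start": start,
                          "end": start + length, "strand": "+"})
        truth.repeat_members[pid] = tuple(names)
    for start, length, names in _PSEUDOGENE_HITS:
        pid = counter_a.next()
        records_a.append({"id": pid, "chrom": "chr1", "start": start,
                          "end": start + length, "strand": "+"})
        truth.pseudogene_members[pid] = tuple(names)
    blacklisted: set[str] = set()
    for start, length, is_bl in _BLACKLIST_HITS:
        pid = counter_a.next()
        records_a.append({"id": pid, "chrom": "chr2", "start": start,
                          "end": start + length, "strand": "+"})
        if is_bl:
            blacklisted.add(pid)
    truth.blacklisted_ids = frozenset(blacklisted)

    # --- multimappers on chr2 --------------------------------------------
    loci = list(range(MULTIMAPPER_ZONE[0], MULTIMAPPER_ZONE[1], MULTIMAPPER_SPACING))
    locus_idx = 0
    for _ in range(config.n_multimapper_ids):
        mult = int(rng.integers(1, 5))
        length = int(rng.integers(HIT_LEN_LO, HIT_LEN_HI + 1))
        pid = counter_a.next()
        truth.multiplicity[pid] = mult
        if locus_idx + mult > len(loci):
            raise ValueError("multimapper zone exhausted; reduce n_multimapper_ids")
        first = loci[locus_idx]
        for k in range(mult):
            pos = loci[locus_idx]
            locus_idx += 1
            if k > 0:  # stamp the first locus sequence for genome consistency
                genome_a["chr2"][pos : pos + length] = genome_a["chr2"][first : first + length]
            records_a.append({"id": pid, "chrom": "chr2", "start": pos,
                              "end": pos + length, "strand": "+"})

    # --- extract sequences (after all genome stamps) ----------------------
    genome_a_str = {c: "".join(arr) for c, arr in genome_a.items()}
    genome_b_str = {c: "".join(arr) for c, arr in genome_b.items()}

    def hit_sequence(genome: dict[str, str], rec: dict) -> str:
        s = genome[rec["chrom"]][rec["start"] : rec["end"]]
        return reverse_complement(s) if rec["strand"] == "-" else s

    sequences_a: dict[str, str] = {}
    for rec in records_a:
        seq = hit_sequence(genome_a_str, rec)
        if rec["id"] in sequences_a and sequences_a[rec["id"]] != seq:
            raise AssertionError(f"inconsistent multimapper stamp for {rec['id']}")
        sequences_a[rec["id"]] = seq
    sequences_b = {rec["id"]: hit_sequence(genome_b_str, rec) for rec in records_b}

    # --- alignment tables (including deliberately failing rows) -----------
    def to_alignment(rec: dict, seqs: dict[str, str]) -> AlignmentRow:
        length = rec["end"] - rec["start"]
        if rec["strand"] == "+":
            s_start, s_end = rec["start"] + 1, rec["end"]
        else:
            s_start, s_end = rec["end"], rec["start"] + 1
        return AlignmentRow(
            query_id=rec["id"], subject_chrom=rec["chrom"],
            percent_identity=100.0, aln_length=length,
            mismatches=0, gap_opens=0, q_start=1, q_end=length,
            s_start=s_start, s_end=s_end, e_value=1e-12, bit_score=60.0,
            query_length=len(seqs[rec["id"]]),
        )

    alignments_a = [to_alignment(r, sequences_a) for r in records_a]
    alignments_b = [to_alignment(r, sequences_b) for r in records_b]

    failing: list[str] = []
    fail_specs = (
        {"mismatches": 1, "percent_identity": 96.7, "e_value": 1e-9},
        {"gap_opens": 1, "e_value": 1e-9},
        {"e_value": 1e-6},
        {"aln_length_delta": -1, "e_value": 1e-9},
    )
    pos = 121_000
    for spec in fail_specs:
        pid = counter_a.next()
        length = 30
        seq = genome_a_str["chr2"][pos : pos + length]
        sequences_a[pid] = seq
        aln_len = length + spec.get("aln_length_delta", 0)
        alignments_a.append(
            AlignmentRow(
                query_id=pid, subject_chrom="chr2",
                percent_identity=spec.get("percent_identity", 100.0),
                aln_length=aln_len,
                mismatches=spec.get("mismatches", 0),
                gap_opens=spec.get("gap_opens", 0),
                q_start=1, q_end=aln_len,
                s_start=pos + 1, s_end=pos + aln_len,
                e_value=spec["e_value"], bit_score=55.0,
                query_length=length,
            )
        )
        failing.append(pid)
        pos += 500
    truth.failing_alignment_ids = frozenset(failing)

    def to_hits(records: list[dict]) -> list[GenomicHit]:
        hits = [
            GenomicHit(r["id"], GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]), 1e-12)
            for r in records
        ]
        hits.sort(key=lambda h: (h.interval.chrom, h.interval.start))
        return hits

    hits_a = to_hits(records_a)
    hits_b = to_hits(records_b)

    # --- genome-consistency self-check ------------------------------------
    for h in hits_a:
        iv = h.interval
        slice_ = genome_a_str[iv.chrom][iv.start : iv.end]
        expect = reverse_complement(slice_) if iv.strand == "-" else slice_
        if sequences_a[h.pirna_id] != expect:
            raise AssertionError(f"genome-inconsistent hit {h.pirna_id}")

    # --- tracks ------------------------------------------------------------
    genes = _gene_models()
    repeats = _repeat_track()
    pseudogenes = [
        (GenomicInterval(c, s, e), name) for c, s, e, name in _PSEUDOGENES
    ]
    blacklist = [
        (GenomicInterval(c, s, e), name) for c, s, e, name in _BLACKLIST
    ]
    promoters = [
        (GenomicInterval(pc.chrom, pc.start - 900, pc.start + 100), f"PROM{i + 1}")
        for i, pc in enumerate(truth.planted_clusters)
    ]
    promoters.append((GenomicInterval("chr1", 148_000, 149_000), "PROM_decoy"))

    # --- synteny -----------------------------------------------------------
    synteny_blocks = [
        SyntenyBlock(GenomicInterval("chr1", 5_000, 45_000),
                     GenomicInterval("chrB1", 25_000, 65_000), "same"),
        SyntenyBlock(GenomicInterval("chr2", 15_000, 30_000),
                     GenomicInterval("chrB1", 95_000, 110_000), "inverted"),
        SyntenyBlock(GenomicInterval("chr1", 150_000, 160_000),
                     GenomicInterval("chrB1", 130_000, 140_000), "same"),
    ]
    # planted conserved pairs: (source planted idx, target planted idx, block idx)
    truth.conserved_pairs = [(0, 0, 0), (2, 1, 1)]

    # --- expression --------------------------------------------------------
    catalogue_ids = [f"hsa_piRNA_{i + 1}" for i in range(config.n_catalogue)]
    catalogue = {pid: sequences_a[pid] for pid in catalogue_ids}
    probs = rng.dirichlet(np.ones(config.n_catalogue))
    draws = rng.multinomial(config.n_reads, probs)
    truth.expression_draws = {pid: int(n) for pid, n in zip(catalogue_ids, draws)}
    truth.n_junk_reads = config.n_junk_reads
    cat_seqs = set(catalogue.values())
    reads: list[str] = []
    for pid in catalogue_ids:
        reads.extend([catalogue[pid]] * truth.expression_draws[pid])
    junk = 0
    while junk < config.n_junk_reads:
        j = "".join(rng.choice(np.array(list("ACGT")), size=28))
        if j in cat_seqs:
            continue
        reads.append(j)
        junk += 1

    bundle = FixtureBundle(
        genome_a=genome_a_str, genome_b=genome_b_str,
        sequences_a=sequences_a, sequences_b=sequences_b,
        alignments_a=alignments_a, alignments_b=alignments_b,
        hits_a=hits_a, hits_b=hits_b,
        genes=genes, repeats=repeats,
        pseudogenes=pseudogenes, promoters=promoters, blacklist=blacklist,
        synteny_blocks=synteny_blocks, reads=reads, catalogue=catalogue,
    )
    if out_dir is not None:
        write_bundle(bundle, truth, out_dir)
    return bundle, truth


# ---------------------------------------------------------------------------
# serialisation


def _write_gtf(genes: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = (f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}"; '
                     f'gene_name "{g.symbol}";')
            rows = [(g.span, "transcript")]
            rows += [(iv, "exon") for iv in g.exons]
            rows += [(iv, "CDS") for iv in g.cds]
            for iv, feat in rows:
                fh.write(
                    f"{iv.chrom}\tpirnakit\t{feat}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{g.span.strand}\t.\t{attrs}\n"
                )


def _write_rmsk(repeats: list[RepeatFeature], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("   SW   perc perc perc  query     position in query    "
                 "matching repeat\n")
        fh.write("score   div. del. ins.  sequence  begin end   (left)   "
                 "repeat        class/family\n")
        fh.write("\n")
        for i, rep in enumerate(repeats, start=1):
            iv = rep.interval
            strand = "C" if iv.strand == "-" else "+"
            cf = (rep.repeat_class if rep.repeat_class == rep.repeat_family
                  else f"{rep.repeat_class}/{rep.repeat_family}")
            fh.write(
                f"1000 0.0 0.0 0.0 {iv.chrom} {iv.start + 1} {iv.end} (0) "
                f"{strand} {rep.repeat_name} {cf} 1 {iv.length} (0) {i}\n"
            )


def _write_alignments(rows: list[AlignmentRow], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# qseqid sseqid pident length mismatch gapopen "
                 "qstart qend sstart send evalue bitscore\n")
        for r in rows:
            fh.write(
                f"{r.query_id}\t{r.subject_chrom}\t{r.percent_identity:.2f}\t"
                f"{r.aln_length}\t{r.mismatches}\t{r.gap_opens}\t{r.q_start}\t"
                f"{r.q_end}\t{r.s_start}\t{r.s_end}\t{r.e_value:g}\t"
                f"{r.bit_score:.1f}\n"
            )


def write_bundle(bundle: FixtureBundle, truth: FixtureTruth, out_dir: str | Path) -> None:
    """Write the full fixture bundle plus truth tables to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome_a, out / "genome.fa")
    write_fasta(bundle.genome_b, out / "genome_b.fa")
    write_fasta(bundle.sequences_a, out / "pirnas.fa")
    write_fasta(bundle.sequences_b, out / "pirnas_b.fa")
    _write_alignments(bundle.alignments_a, out / "alignments.tsv")
    _write_alignments(bundle.alignments_b, out / "alignments_b.tsv")
    _write_gtf(bundle.genes, out / "genes.gtf")
    _write_rmsk(bundle.repeats, out / "repeats.out")
    write_bed4(bundle.pseudogenes, out / "pseudogenes.bed")
    write_bed4(bundle.promoters, out / "promoters.bed")
    write_bed4(bundle.blacklist, out / "blacklist.bed")
    write_synteny(bundle.synteny_blocks, out / "synteny.tsv")
    write_fasta(
        {f"read_{i + 1}": seq for i, seq in enumerate(bundle.reads)},
        out / "reads.fa",
    )
    write_fasta(bundle.catalogue, out / "catalogue.fa")

    def cluster_rows(clusters: list[PlantedCluster]):
        return [
            (c.chrom, c.start, c.end, c.n_hits, c.plus_count, c.minus_count,
             ",".join(c.hit_ids))
            for c in clusters
        ]

    header = ("chrom", "start", "end", "n_hits", "plus", "minus", "hit_ids")
    write_tsv(out / "truth_clusters.tsv", header, cluster_rows(truth.planted_clusters))
    write_tsv(out / "truth_clusters_b.tsv", header,
              cluster_rows(truth.planted_clusters_target))
    write_tsv(out / "truth_pairs.tsv", ("plus_id", "minus_id"), truth.planted_pairs)
    write_tsv(out / "truth_decoy_pairs.tsv", ("plus_id", "minus_id", "offset"),
              truth.decoy_pair_ids)
    write_tsv(out / "truth_contexts.tsv", ("hit_id", "labels"),
              [(pid, ";".join(sorted(labs))) for pid, labs in truth.context_labels.items()])
    write_tsv(out / "truth_repeats.tsv", ("hit_id", "repeat_names"),
              [(pid, ";".join(names)) for pid, names in truth.repeat_members.items()])
    write_tsv(out / "truth_pseudogenes.tsv", ("hit_id", "pseudogene_ids"),
              [(pid, ";".join(names)) for pid, names in truth.pseudogene_members.items()])
    write_tsv(out / "truth_blacklist.tsv", ("hit_id",),
              [(pid,) for pid in sorted(truth.blacklisted_ids)])
    write_tsv(out / "truth_failing_alignments.tsv", ("query_id",),
              [(pid,) for pid in sorted(truth.failing_alignment_ids)])
    write_tsv(out / "truth_multiplicity.tsv", ("pirna_id", "n_hits"),
              sorted(truth.multiplicity.items()))
    write_tsv(out / "truth_expression.tsv", ("pirna_id", "count"),
              list(truth.expression_draws.items()) + [("__junk__", truth.n_junk_reads)])
    write_tsv(out / "truth_conserved.tsv",
              ("source_cluster_idx", "target_cluster_idx", "block_idx"),
              truth.conserved_pairs)
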