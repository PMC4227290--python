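"""Readers and writers for the external formats the toolkit touches.

All genomic intervals are stored 0-based half-open (BED convention)
regardless of the input dialect; 1-based inputs (BLAST tabular, GTF,
RepeatMasker) are converted at the boundary, once, here.  Minus-strand
BLAST hits are normalised so that start < end and the strand is recorded
separately, giving every downstream overlap computation a single interval
representation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``start`` is inclusive, ``end`` exclusive; ``strand`` is ``+``, ``-``
    or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind overlap of at least 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignmentRow:
    """One row of a 12-column BLAST tabular (outfmt 6) alignment.

    Subject coordinates are kept 1-based as printed; ``subject_interval``
    exposes the normalised 0-based half-open form with the strand inferred
    from the s_start/s_end order (s_start > s_end encodes minus strand).
    ``query_length`` is joined from the query FASTA so that the full-length
    filter can compare it with ``aln_length``.
    """

    query_id: str
    subject_chrom: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    query_length: int

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1: {self.aln_length}")
        if self.e_value < 0:
            raise ValueError(f"negative e-value: {self.e_value}")
        if self.q_start > self.q_end:
            raise ValueError("q_start must not exceed q_end")

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def subject_interval(self) -> GenomicInterval:
        lo, hi = sorted((self.s_start, self.s_end))
        return GenomicInterval(self.subject_chrom, lo - 1, hi, self.strand)


@dataclass(frozen=True)
class GeneModel:
    """A transcript-level gene model with derived UTRs and introns.

    All sub-feature lists are 0-based half-open and contained in ``span``.
    Introns are derived per transcript as the span minus the merged exons.
    """

    gene_id: str
    symbol: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...]
    utr5: tuple[GenomicInterval, ...]
    utr3: tuple[GenomicInterval, ...]

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        merged = merge_intervals(self.exons)
        out: list[GenomicInterval] = []
        cursor = self.span.start
        for ex in merged:
            if ex.start > cursor:
                out.append(
                    GenomicInterval(self.span.chrom, cursor, ex.start, self.span.strand)
                )
            cursor = max(cursor, ex.end)
        if cursor < self.span.end:
            out.append(
                GenomicInterval(self.span.chrom, cursor, self.span.end, self.span.strand)
            )
        return tuple(out)


@dataclass(frozen=True)
class RepeatFeature:
    """A repeat-annotation row (RepeatMasker-style)."""

    interval: GenomicInterval
    repeat_name: str
    repeat_family: str
    repeat_class: str

    def __post_init__(self) -> None:
        if not self.repeat_name or not self.repeat_family:
            raise ValueError("repeat name and family must be non-empty")


@dataclass(frozen=True)
class SyntenyBlock:
    """A pair of corresponding intervals in two genomes.

    ``orientation`` is ``same`` or ``inverted``; inverted blocks reverse
    the coordinate axis when projecting source loci into the target.
    """

    source: GenomicInterval
    target: GenomicInterval
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"orientation must be same/inverted: {self.orientation!r}")


# ---------------------------------------------------------------------------
# interval helpers


def merge_intervals(intervals: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Merge overlapping or touching intervals on the same chromosome."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = dataclasses.replace(last, end=iv.end)
        else:
            merged.append(iv)
    return tuple(merged)


def _subtract_extent(
    exons: Sequence[GenomicInterval], lo: int, hi: int
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[GenomicInterval]]:
    """Split exon pieces into (before lo, inside [lo,hi), after hi)."""
    before: list[GenomicInterval] = []
    inside: list[GenomicInterval] = []
    after: list[GenomicInterval] = []
    for ex in exons:
        if ex.start < lo:
            before.append(dataclasses.replace(ex, end=min(ex.end, lo)))
        if ex.end > lo and ex.start < hi:
            inside.append(
                dataclasses.replace(ex, start=max(ex.start, lo), end=min(ex.end, hi))
            )
        if ex.end > hi:
            after.append(dataclasses.replace(ex, start=max(ex.start, hi)))
    return before, inside, after


def build_gene_model(
    gene_id: str,
    symbol: str,
    chrom: str,
    strand: str,
    tx_start: int,
    tx_end: int,
    exons: Sequence[tuple[int, int]],
    cds_extent: tuple[int, int] | None,
) -> GeneModel:
    """Assemble a :class:`GeneModel` from half-open transcript coordinates.

    ``cds_extent`` is the genomic (cds_start, cds_end) span or ``None`` for
    non-coding transcripts; per-exon CDS pieces and the 5'/3' UTRs are
    derived here with strand awareness.
    """
    span = GenomicInterval(chrom, tx_start, tx_end, strand)
    exon_ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons))
    for ex in exon_ivs:
        if ex.start < span.start or ex.end > span.end:
            raise ValueError(f"exon {ex} outside transcript span of {gene_id}")
    if cds_extent is None:
        return GeneModel(gene_id, symbol, span, exon_ivs, (), (), ())
    lo, hi = cds_extent
    if hi <= lo:
        return GeneModel(gene_id, symbol, span, exon_ivs, (), (), ())
    merged = merge_intervals(exon_ivs)
    if not _extent_covered(merged, lo, hi):
        raise ValueError(f"CDS [{lo},{hi}) of {gene_id} not contained in exon union")
    before, inside, after = _subtract_extent(exon_ivs, lo, hi)
    if strand == "-":
        utr5, utr3 = tuple(after), tuple(before)
    else:
        utr5, utr3 = tuple(before), tuple(after)
    return GeneModel(gene_id, symbol, span, exon_ivs, tuple(inside), utr5, utr3)


def _extent_covered(merged: Sequence[GenomicInterval], lo: int, hi: int) -> bool:
    """True when both CDS extent endpoints fall inside the exon union."""
    def covered(pos: int) -> bool:
        return any(ex.start <= pos < ex.end for ex in merged)

    return covered(lo) and covered(hi - 1)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record, possibly wrapped) FASTA into an ordered dict.

    Sequences are upper-cased and U mapped to T so that RNA- and
    DNA-spelled inputs compare equal internally.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_seq(str(rec.seq))
    return out


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences (only) from a FASTQ file, normalised like FASTA."""
    return [normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_read_sequences(path: str | Path) -> list[str]:
    """Read a small-RNA read set from FASTA or FASTQ (sniffed from the file)."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return [normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tabular(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[AlignmentRow]:
    """Parse a 12-column BLAST outfmt-6 table.

    ``query_lengths`` maps query id to its sequence length (normally taken
    from the query FASTA); every query id in the table must be present.
    Lines starting with ``#`` are comments.
    """
    rows: list[AlignmentRow] = []
    missing: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            qid = fields[0]
            if qid not in query_lengths:
                missing.add(qid)
                continue
            rows.append(
                AlignmentRow(
                    query_id=qid,
                    subject_chrom=fields[1],
                    percent_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                    query_length=query_lengths[qid],
                )
            )
    if missing:
        raise KeyError(
            "query ids absent from query_lengths: " + ", ".join(sorted(missing))
        )
    return rows


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, dialect: str = "gtf") -> list[GeneModel]:
    """Read transcript models from GTF or refFlat, normalised to half-open.

    GTF uses 1-based inclusive coordinates; refFlat already uses 0-based
    starts with exclusive ends.  UTRs are derived from the CDS extent
    versus the exon structure, strand-aware.
    """
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "refflat":
        return _read_refflat(path)
    raise ValueError(f"unknown gene-model dialect: {dialect!r}")


def _gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _read_gtf(path: str | Path) -> list[GeneModel]:
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS", "transcript"):
                continue
            a = _gtf_attributes(attrs)
            tid = a.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}: line {lineno}: missing transcript_id")
            rec = transcripts.get(tid)
            if rec is None:
                rec = {
                    "chrom": chrom,
                    "strand": strand,
                    "symbol": a.get("gene_name", a.get("gene_id", tid)),
                    "exons": [],
                    "cds": [],
                    "span": None,
                }
                transcripts[tid] = rec
                order.append(tid)
            start0, end = int(start1) - 1, int(end1)
            if feature == "transcript":
                rec["span"] = (start0, end)
            elif feature == "exon":
                rec["exons"].append((start0, end))
            else:
                rec["cds"].append((start0, end))
    models: list[GeneModel] = []
    for tid in order:
        rec = transcripts[tid]
        exons = sorted(rec["exons"])
        if not exons:
            continue
        span = rec["span"] or (exons[0][0], exons[-1][1])
        cds_extent = None
        if rec["cds"]:
            cds_extent = (min(s for s, _ in rec["cds"]), max(e for _, e in rec["cds"]))
        models.append(
            build_gene_model(
                tid, rec["symbol"], rec["chrom"], rec["strand"],
                span[0], span[1], exons, cds_extent,
            )
        )
    return models


def _read_refflat(path: str | Path) -> list[GeneModel]:
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}: line {lineno}: expected 11 refFlat columns")
            (symbol, tid, chrom, strand, tx_start, tx_end,
             cds_start, cds_end, _exon_count, exon_starts, exon_ends) = fields[:11]
            starts = [int(x) for x in exon_starts.rstrip(",").split(",")]
            ends = [int(x) for x in exon_ends.rstrip(",").split(",")]
            if len(starts) != len(ends):
                raise ValueError(f"{path}: line {lineno}: exon start/end count mismatch")
            cds = (int(cds_start), int(cds_end))
            cds_extent = None if cds[0] >= cds[1] else cds
            models.append(
                build_gene_model(
                    tid, symbol, chrom, strand,
                    int(tx_start), int(tx_end),
                    list(zip(starts, ends)), cds_extent,
                )
            )
    return models


# ---------------------------------------------------------------------------
# repeats


def read_repeatmasker(path: str | Path) -> list[RepeatFeature]:
    """Read repeats from a RepeatMasker ``.out`` file or a BED6+2 table.

    The ``class/family`` string is split on ``/``; when there is no slash
    (e.g. ``Simple_repeat``) the family equals the class.
    """
    with open(path) as fh:
        head = fh.readline()
    if head.lstrip().startswith("SW") or "score" in head.lower().split()[:2]:
        return _read_rmsk_out(path)
    return _read_repeat_bed(path)


def _split_class_family(cf: str) -> tuple[str, str]:
    if "/" in cf:
        cls, fam = cf.split("/", 1)
        return cls, fam
    return cf, cf


def _read_rmsk_out(path: str | Path) -> list[RepeatFeature]:
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):  # 3 header lines
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ValueError(f"{path}: line {lineno}: unparsable RepeatMasker row")
        try:
            chrom = fields[4]
            begin1, end1 = int(fields[5]), int(fields[6])
            strand = "-" if fields[8] == "C" else "+"
            name = fields[9]
            cls, fam = _split_class_family(fields[10])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: line {lineno}: unparsable RepeatMasker row") from exc
        feats.append(
            RepeatFeature(GenomicInterval(chrom, begin1 - 1, end1, strand), name, fam, cls)
        )
    return feats


def _read_repeat_bed(path: str | Path) -> list[RepeatFeature]:
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}: line {lineno}: expected BED6+1 repeat row")
            chrom, start, end, name, _score, strand = fields[:6]
            cls, fam = _split_class_family(fields[6])
            feats.append(
                RepeatFeature(
                    GenomicInterval(chrom, int(start), int(end), strand), name, fam, cls
                )
            )
    return feats


# ---------------------------------------------------------------------------
# BED4 (pseudogenes, promoters, blacklists)


def read_bed4(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED4 (chrom, start, end, name); BED6 strand used if present."""
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            name = fields[3] if len(fields) > 3 else f"feature_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            out.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand), name)
            )
    return out


def write_bed4(features: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, name in features:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# synteny TSV


def read_synteny(path: str | Path) -> list[SyntenyBlock]:
    """Read synteny blocks from a 7-column TSV, 0-based half-open.

    Columns: source_chrom, source_start, source_end, target_chrom,
    target_start, target_end, orientation (``+`` for same, ``-`` inverted).
    """
    blocks: list[SyntenyBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 synteny columns")
            orientation = "inverted" if fields[6] == "-" else "same"
            blocks.append(
                SyntenyBlock(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    GenomicInterval(fields[3], int(fields[4]), int(fields[5])),
                    orientation,
                )
            )
    return blocks


def write_synteny(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#source_chrom\tsource_start\tsource_end\t"
                 "target_chrom\ttarget_start\ttarget_end\torientation\n")
        for b in blocks:
            sign = "-" if b.orientation == "inverted" else "+"
            fh.write(
                f"{b.source.chrom}\t{b.source.start}\t{b.source.end}\t"
                f"{b.target.chrom}\t{b.target.start}\t{b.target.end}\t{sign}\n"
            )


# ---------------------------------------------------------------------------
# generic single-header TSV table


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Write a TSV table with a single '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a single-header TSV written by :func:`write_tsv`."""
    header: list[str] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if not header:
                    header = line[1:].split("\t")
                continue
            rows.append(line.split("\t"))
    return header, rows
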