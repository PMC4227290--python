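"""Small packaged text fixtures."""

from importlib import resources
from pathlib import Path

from pirnakit.genomic_io import AlignmentRow, read_blast_tabular, read_fasta


def _data_path(name: str) -> Path:
    return Path(resources.files(__package__) / name)


def toy_alignment_table() -> list[AlignmentRow]:
    """The packaged 10-row toy BLAST table used to exercise the alignment
    filters: 4 perfect full-length rows at e-values 1e-12..1e-7, two
    mismatch rows, two gapped rows, one full-length row at e = 1e-6 and
    one perfect 29/30-length row."""
    lengths = {pid: len(seq) for pid, seq in toy_pirna_fasta().items()}
    return read_blast_tabular(_data_path("toy_alignments.tsv"), lengths)


def toy_pirna_fasta() -> dict[str, str]:
    """Query sequences for the toy alignment table (all 30-mers)."""
    return read_fasta(_data_path("toy_pirnas.fa"))
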