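"""Ping-Pong signature and partner detection.

The Ping-Pong amplification cycle leaves a geometric fingerprint: the 5'
end of the responder piRNA sits exactly 10 nt inside the 5' end of the
guide on the opposite genomic strand, and sequence biases follow — uracil
at position 1 of the guide (1U) and adenine at position 10 of the
responder (10A).  In 0-based half-open genome coordinates the 5' end of a
plus-strand hit is its start and the 5' end of a minus-strand hit is its
end, so a partner pair satisfies ``minus.end - plus.start == overlap``
(default 10) while the two intervals genuinely overlap.

Signature flags annotate pairs rather than filter them: pairs lacking
1U/10A are still reported with their flags set false.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from pirnakit.hit_processing import GenomicHit
from pirnakit.seq_tools import first_base_is_u, tenth_base_is_a

DEFAULT_OVERLAP = 10


def signature_flags(sequence: str) -> tuple[bool, bool]:
    """(has_1U, has_10A) for a piRNA sequence, 1-based from the 5' end.

    has_10A is False for sequences shorter than 10 nt.
    """
    return first_base_is_u(sequence), tenth_base_is_a(sequence)


@dataclass(frozen=True)
class PingPongPair:
    """An opposite-strand hit pair with the configured 5'-end overlap."""

    sense_hit: GenomicHit       # plus strand
    antisense_hit: GenomicHit   # minus strand
    five_prime_overlap: int
    sense_has_1U: bool
    antisense_has_10A: bool


def find_partners(
    hits: Sequence[GenomicHit],
    sequences: Mapping[str, str],
    overlap: int = DEFAULT_OVERLAP,
    require_signature: bool = False,
) -> list[PingPongPair]:
    """Enumerate every Ping-Pong partner pair in a hit set.

    A pair is a (plus, minus) hit couple on the same chromosome with
    ``minus.end - plus.start == overlap`` and genuine interval overlap
    (``minus.start < plus.end``).  Pairs are sorted by
    (chrom, plus.start, minus.start).  With ``require_signature`` only
    pairs showing both 1U (sense) and 10A (antisense) are kept.
    """
    if overlap < 1:
        raise ValueError("overlap must be >= 1")
    minus_by_end: dict[tuple[str, int], list[GenomicHit]] = defaultdict(list)
    for h in hits:
        if h.interval.strand == "-":
            minus_by_end[(h.interval.chrom, h.interval.end)].append(h)
    pairs: list[PingPongPair] = []
    for plus in hits:
        if plus.interval.strand != "+":
            continue
        key = (plus.interval.chrom, plus.interval.start + overlap)
        for minus in minus_by_end.get(key, ()):
            if not (minus.interval.end > plus.interval.start
                    and minus.interval.start < plus.interval.end):
                continue
            has_1u = first_base_is_u(sequences[plus.pirna_id])
            has_10a = tenth_base_is_a(sequences[minus.pirna_id])
            if require_signature and not (has_1u and has_10a):
                continue
            pairs.append(PingPongPair(plus, minus, overlap, has_1u, has_10a))
    pairs.sort(
        key=lambda p: (
            p.sense_hit.interval.chrom,
            p.sense_hit.interval.start,
            p.antisense_hit.interval.start,
            p.sense_hit.pirna_id,
            p.antisense_hit.pirna_id,
        )
    )
    return pairs
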