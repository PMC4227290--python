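"""Sequence-level utilities: GC/AT content, length gating, Ping-Pong
signature nucleotides and wildcard pattern search.

piRNAs are reported in the literature in both RNA and DNA spelling, so all
comparisons here treat U and T as the same base and are case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_BASES = frozenset("ACGTUN")
_ACGT = frozenset("ACGT")

# canonical piRNA length range, nucleotides
PIRNA_MIN_LEN = 26
PIRNA_MAX_LEN = 32


def _normalize(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def _validate(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = _normalize(sequence)
    bad = set(seq) - frozenset("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def gc_percent(sequence: str) -> float:
    """GC content of a nucleotide sequence, as a percentage 0-100.

    N bases count toward the length but toward neither GC nor AT.
    """
    seq = _validate(sequence)
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


def at_percent(sequence: str) -> float:
    """AT (equivalently AU) content as a percentage; complements gc_percent
    so that gc + at = 100 for N-free sequences."""
    seq = _validate(sequence)
    at = seq.count("A") + seq.count("T")
    return 100.0 * at / len(seq)


def length_in_range(sequence: str, lo: int = PIRNA_MIN_LEN, hi: int = PIRNA_MAX_LEN) -> bool:
    """True iff lo <= len(sequence) <= hi (both bounds inclusive)."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) exceeds hi ({hi})")
    return lo <= len(sequence) <= hi


def first_base_is_u(sequence: str) -> bool:
    """Ping-Pong 1U signature: 5'-most base is uracil (thymine in DNA)."""
    seq = _validate(sequence)
    return seq[0] == "T"


def tenth_base_is_a(sequence: str) -> bool:
    """Ping-Pong 10A signature: adenine at the 10th base from the 5' end
    (1-based); False for sequences shorter than 10 nt."""
    seq = _validate(sequence)
    return len(seq) >= 10 and seq[9] == "A"


@dataclass(frozen=True)
class PiRNARecord:
    """A piRNA sequence record with derived signature properties.

    Identifiers follow the ``<org>_piRNA_<n>`` convention, e.g.
    ``hsa_piRNA_6754``.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        _validate(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc_percent(self) -> float:
        return gc_percent(self.sequence)

    @property
    def has_1U(self) -> bool:
        return first_base_is_u(self.sequence)

    @property
    def has_10A(self) -> bool:
        return tenth_base_is_a(self.sequence)


def make_pirna_id(org: str, serial: int) -> str:
    return f"{org}_piRNA_{serial}"


# ---------------------------------------------------------------------------
# pattern search


def compile_pattern(pattern: str) -> list[frozenset[str]]:
    """Compile a wildcard pattern into a per-position allowed-base list.

    Grammar: literal bases A/C/G/T/U; ``*`` matches exactly one arbitrary
    nucleotide; ``[XY...]`` matches one position against any listed base.
    U is equivalent to T throughout.
    """
    if not pattern:
        raise ValueError("empty pattern")
    positions: list[frozenset[str]] = []
    i = 0
    pat = pattern.upper()
    while i < len(pat):
        ch = pat[i]
        if ch == "*":
            positions.append(_ACGT)
            i += 1
        elif ch == "[":
            j = pat.find("]", i)
            if j < 0:
                raise ValueError(f"unbalanced bracket in pattern: {pattern!r}")
            members = pat[i + 1 : j].replace("U", "T")
            if not members:
                raise ValueError(f"empty character class in pattern: {pattern!r}")
            bad = set(members) - _ACGT
            if bad:
                raise ValueError(f"invalid bases {sorted(bad)} in class of {pattern!r}")
            positions.append(frozenset(members))
            i = j + 1
        elif ch == "]":
            raise ValueError(f"unbalanced bracket in pattern: {pattern!r}")
        else:
            base = "T" if ch == "U" else ch
            if base not in _ACGT:
                raise ValueError(f"invalid pattern character {ch!r} in {pattern!r}")
            positions.append(frozenset((base,)))
            i += 1
    return positions


def match_offset(pattern: str | list[frozenset[str]], sequence: str) -> int | None:
    """0-based offset of the leftmost occurrence of the pattern, or None.

    An ``N`` in the sequence matches no pattern position (conservative).
    """
    positions = compile_pattern(pattern) if isinstance(pattern, str) else pattern
    seq = _normalize(sequence)
    m = len(positions)
    for off in range(len(seq) - m + 1):
        if all(seq[off + k] in positions[k] for k in range(m)):
            return off
    return None


def pattern_search(
    pattern: str, records: Iterable[PiRNARecord]
) -> list[tuple[str, int]]:
    """Find every record containing the pattern; report the leftmost match.

    Returns (record id, 0-based offset) pairs in input order.
    """
    compiled = compile_pattern(pattern)
    out: list[tuple[str, int]] = []
    for rec in records:
        off = match_offset(compiled, rec.sequence)
        if off is not None:
            out.append((rec.id, off))
    return out
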