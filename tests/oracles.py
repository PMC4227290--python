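"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — plain loops, per-base enumeration,
all-pairs scans — and shares no code path with the package internals it
checks.
"""

from __future__ import annotations


# --- pattern search --------------------------------------------------------


def naive_pattern_positions(pattern: str) -> list[set[str]]:
    """Parse the wildcard grammar with a minimal character loop."""
    out: list[set[str]] = []
    i = 0
    pat = pattern.upper().replace("U", "T")
    while i < len(pat):
        ch = pat[i]
        if ch == "*":
            out.append(set("ACGT"))
            i += 1
        elif ch == "[":
            j = pat.index("]", i)
            out.append(set(pat[i + 1 : j]))
            i = j + 1
        else:
            out.append({ch})
            i += 1
    return out


def naive_scan(pattern: str, sequence: str) -> int | None:
    """Position-by-position O(n*m) substring scan; leftmost match or None."""
    pos = naive_pattern_positions(pattern)
    seq = sequence.upper().replace("U", "T")
    for off in range(len(seq) - len(pos) + 1):
        ok = True
        for k in range(len(pos)):
            if seq[off + k] not in pos[k]:
                ok = False
                break
        if ok:
            return off
    return None


# --- interval subtraction --------------------------------------------------


def naive_subtract(hits, blacklist):
    """Per-pair overlap check; keeps hits overlapping no blacklist interval."""
    kept = []
    for h in hits:
        removed = False
        for iv in blacklist:
            if (h.interval.chrom == iv.chrom
                    and h.interval.start < iv.end and iv.start < h.interval.end):
                removed = True
                break
        if not removed:
            kept.append(h)
    return kept


# --- genomic context -------------------------------------------------------


def per_base_context(hit, genes) -> set[str]:
    """Classify a hit by enumerating every base against every feature."""
    labels: set[str] = set()
    for pos in range(hit.interval.start, hit.interval.end):
        for gene in genes:
            if gene.span.chrom != hit.interval.chrom:
                continue
            if gene.span.start <= pos < gene.span.end:
                labels.add("GENE")
            for name, ivs in (
                ("INTRON", gene.introns), ("CDS", gene.cds),
                ("UTR5", gene.utr5), ("UTR3", gene.utr3),
            ):
                for iv in ivs:
                    if iv.start <= pos < iv.end:
                        labels.add(name)
    return labels if labels else {"INTERGENIC"}


# --- Ping-Pong -------------------------------------------------------------


def all_pairs_pingpong(hits, overlap: int = 10):
    """Every (plus, minus) hit pair with the 5'-end relation, O(n^2)."""
    pairs = []
    for plus in hits:
        if plus.interval.strand != "+":
            continue
        for minus in hits:
            if minus.interval.strand != "-":
                continue
            if minus.interval.chrom != plus.interval.chrom:
                continue
            if minus.interval.end - plus.interval.start != overlap:
                continue
            if not (minus.interval.end > plus.interval.start
                    and minus.interval.start < plus.interval.end):
                continue
            pairs.append((plus, minus))
    return pairs


# --- cluster calling -------------------------------------------------------


def exhaustive_clusters(hits, window_length=20_000, step=1_000,
                        min_density=20, extension_step=1_000):
    """Naive window-scan reference: evaluates every window start with a
    full list scan, applies the density-preserving extension, hit-bounded
    trimming and the membership closure, and resumes past each cluster.

    Returns (chrom, start, end, n, plus, minus, member_id_tuple) records.
    """
    by_chrom: dict[str, list] = {}
    for h in hits:
        by_chrom.setdefault(h.interval.chrom, []).append(h)
    out = []
    for chrom, chrom_hits in by_chrom.items():
        chrom_hits = sorted(chrom_hits, key=lambda h: h.interval.start)
        last_start = max(h.interval.start for h in chrom_hits)
        w = 0
        while w <= last_start:
            in_window = [h for h in chrom_hits
                         if w <= h.interval.start < w + window_length]
            if len(in_window) < min_density:
                w += step
                continue
            right = w + window_length
            while True:
                cand = right + extension_step
                count = sum(1 for h in chrom_hits if w <= h.interval.start < cand)
                # whole-window density (hits per window_length of span)
                if count * window_length >= min_density * (cand - w):
                    right = cand
                else:
                    break
            members = [h for h in chrom_hits if w <= h.interval.start < right]
            end = max(h.interval.end for h in members)
            while True:
                bigger = [h for h in chrom_hits if w <= h.interval.start < end]
                if len(bigger) == len(members):
                    break
                members = bigger
                end = max(h.interval.end for h in members)
            start = min(h.interval.start for h in members)
            plus = sum(1 for h in members if h.interval.strand == "+")
            out.append((chrom, start, end, len(members), plus,
                        len(members) - plus,
                        tuple(h.pirna_id for h in members)))
            w = ((end + step - 1) // step) * step
    return out
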