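# Methods

## Scope and model

`pirnakit` annotates PIWI-interacting RNA (piRNA) loci on a reference
genome. piRNAs are 26–32 nt germline small RNAs; their loci are
characterised by where they fall (genes, introns, CDS, UTRs, intergenic
space, repeats, pseudogenes), by clustering into genomic "hotspots", and
by the Ping-Pong amplification geometry that links sense and antisense
piRNAs. The toolkit implements each of these analyses as a pure function
over explicit in-memory records, with thin file readers/writers and a CLI
around them.

All genomic intervals are stored 0-based half-open (BED convention).
1-based inputs — BLAST tabular, GTF, RepeatMasker — are converted once at
the parsing boundary. Minus-strand BLAST hits (encoded by
`s_start > s_end`) are normalised to `start < end` with the strand kept
separately. Sequences are upper-cased and U is mapped to T on input, so
RNA- and DNA-spelled piRNAs compare equal; overlap logic is strand-blind
everywhere except Ping-Pong pairing, which is intrinsically stranded.

## Alignment filtering

A genome alignment becomes a *hit* when it is perfect and full length:
no mismatches, no gap opens, alignment length equal to the query length,
and e-value ≤ 1e-7. The e-value cutoff is **inclusive** — a borderline
1e-7 alignment passes — and is tested explicitly. The percent-identity
column is ignored because it is fully determined by the mismatch count
under full-length, gap-free filtering. Hits overlapping an ncRNA
blacklist (rRNA/tRNA/snoRNA/miRNA intervals) by ≥ 1 bp are subtracted,
strand-blind. A piRNA is a *unique mapper* when exactly one hit survives
genome-wide; uniqueness is flagged after blacklist subtraction (the two
stages are separate functions, so the other order is one line of user
code).

## Context classification

A hit is `GENE` when it overlaps any transcript span by ≥ 1 bp, and
additionally carries each of `INTRON` / `CDS` / `UTR5` / `UTR3` whose
per-transcript feature intervals it touches; labels from different
transcripts accumulate. A hit overlapping no transcript is exactly
`INTERGENIC`, so `GENE`/`INTERGENIC` partition every hit set — a
conservation law the tests assert on every random instance. Introns are
derived per transcript (span minus that transcript's merged exons), and
UTRs from the CDS extent versus the exon structure with strand awareness,
matching transcript-level UCSC-style tables. Because published summaries
usually show mutually exclusive categories, a collapsed single label is
also provided with priority `CDS > UTR5 > UTR3 > INTRON` (configurable);
both the full label set and the collapsed label appear in the output.

Repeat and pseudogene association attach (name, family, overlap-bp)
records for every feature overlapped by ≥ `min_overlap_bp` (default 1).
Interval queries use an interval tree per chromosome; correctness is
checked against a per-base brute-force enumerator.

## Ping-Pong detection

In half-open coordinates the 5′ end of a plus-strand hit is its `start`;
the 5′ end of a minus-strand hit is its `end` (highest genomic
coordinate). A partner pair is a (plus, minus) hit pair on one chromosome
with

```
minus.end − plus.start = overlap      (default 10, exact)
minus.start < plus.end                (genuine interval overlap)
```

Exactness (not ≥ 10) reflects the canonical Ping-Pong geometry of ten
complementary 5′ positions. Signature flags — 1U (first base U/T) and 10A
(adenine at base 10, 1-based from the 5′ end; false for < 10 nt) — are
annotations, not filters: pairs without the bias are reported with flags
false, and `--require-signature` switches to strict mode. On
genome-consistent sequences, base 1 of the sense read is the reverse
complement of base 10 of the antisense read, so sense-1U implies
antisense-10A; the synthetic fixture exploits exactly this to plant 10A
by forcing 1U.

## Cluster calling

Clusters are found by sliding a `window_length` (default 20 000 bp)
window per chromosome in `step` (1 000 bp) increments, counting hits by
their start position (membership by start keeps the density
integer-valued). A window with ≥ `min_density` (20) hits seeds a cluster.

**Extension.** The right edge then grows in `extension_step` (1 000 bp)
increments for as long as the *density of the whole extended window* —
hits per `window_length` of span, i.e. `count × window_length ≥
min_density × span` — stays at threshold. A count-only rule cannot
terminate (the count never drops as the window grows), so the density is
normalised per window-length of span; for the initial window the two
rules coincide. This is the one place where the procedure admits more
than one reading; the normalised-density rule is this package's choice
and is mirrored, independently and naively, by the test oracle.

**Trimming and closure.** The cluster is trimmed to
`[first contained hit start, last contained hit end)`; hits starting
before the trimmed end but after the extension edge are then absorbed and
the end recomputed until stable, so every hit inside a reported cluster
interval is counted. Scanning resumes at the first window position at or
beyond the cluster end, making clusters disjoint; ids are
`chrom.serial`, serial being the 1-based start rank per chromosome.

**Score.** `score = (n/L × 1000) × (min_density / window_kb)` — hit
density in hits/kb scaled by a parameter constant that is 1 under
defaults. It is strictly increasing in hit count and decreasing in
length. **Directionality**: bidirectional when the minority strand holds
≥ `bidir_min_fraction` (default 0.2 — the categories are standard, the
numeric cutoff is this package's choice) of hits, else mono with the
majority strand. Cluster GC% is computed from the genomic slice. The
descriptive upper end of the "~20–50" density range is not enforced as a
cap: windows above 50 hits still seed clusters, since a cap would discard
the densest hotspots.

## Synteny projection

A source cluster wholly inside a synteny block's source interval is
projected linearly (proportional offsets; axis reversed for inverted
blocks) into the target interval, with outward rounding (floor/ceil) so
the projection covers the exact image. Every target-genome cluster
overlapping the projection by ≥ 1 bp is reported as a conserved pair.

## Expression

Reads are assigned to catalogue piRNAs by exact sequence identity (U≡T,
case-insensitive) — catalogue entries are collapsed read sequences, so
mismatch tolerance would double-count. Unassigned reads are tallied,
giving the conservation law `assigned + unassigned = total`. `top_n`
returns the prefix of the total order (−count, id): descending count,
ties broken by id, zero counts excluded.

## Synthetic fixture

The generator emulates the toolkit's inputs at desk scale: a 550 kb
three-chromosome source genome and a 150 kb target genome at 40% GC
(with planted all-GC and all-AT segments), five planted clusters
(25–40 hits in 3–6 kb; mono-plus, bidirectional and mono-minus strand
mixes), 30 Ping-Pong pairs at exactly 10 nt plus 12 decoy pairs at each
of offsets 8/9/11/12, engineered context/repeat/pseudogene/blacklist
hits with truth labels, 16 multimapper piRNAs (multiplicity 1–4, stamped
into the genome so every alignment stays genome-consistent), a 625-read
multinomial expression sample with recorded draws, and three synteny
blocks carrying two planted conserved cluster pairs. Layout constants
keep every planted cluster ≥ ~35 kb from any other hit — under the
normalised-density extension a cluster of *n* hits can reach
`(n/min_density) × window_length` past its seed window, so clearance
beyond one window length is required for exact boundary recovery — and
keep background densities below threshold everywhere else.

What the fixture does *not* emulate: realistic transposon sequence
composition, sequencing error, read-length heterogeneity within a locus,
multi-locus gene families, and genome-scale hit counts (the real studies
involve 10⁵–10⁷ alignments). Passing tests therefore demonstrate
algorithmic correctness at the stated geometry, not biological recall on
real libraries.

All randomness flows from a single seeded `numpy` generator;
regeneration with one seed is byte-identical, which the determinism
tests assert file by file.

## Numerical and degenerate-input choices

- Intervals must be non-empty (`start < end`); empty hit lists yield
  empty outputs rather than errors except where a contract requires input
  (empty catalogue, empty sequence, zero-length cluster).
- Ties: `top_n` breaks by id; Ping-Pong pairs sort by
  (chrom, plus.start, minus.start, ids); repeat associations sort by name.
- Pattern search: `*` matches exactly one nucleotide (the tool's
  wildcard is positional, not Kleene); `[XY]` one position against a
  class; `N` in a record matches nothing (conservative); leftmost offset
  reported once per record.
- Problem sizes in the test-suite oracles (100 random chromosomes of
  ≤ 100 kb / ≤ 300 hits; 50 seeds × 200 hits × 10 gene models; 1000
  pattern cases) were chosen so exhaustive references stay trivially
  correct while covering boundary behaviour densely.

## Known limitations

- The cluster extension rule is one defensible reading of an ambiguous
  published procedure; alternatives (re-check only the trailing window,
  or the new segment) would call slightly different right edges on
  gradually decaying hotspots.
- No multi-mapper weighting: every hit counts once toward density
  (`--unique-only` restricts to unique mappers instead).
- Expression counts are raw totals; no RPM/CPM normalisation or
  cross-sample statistics.
- GTF attribute parsing covers `gene_id`/`transcript_id`/`gene_name`
  only.
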