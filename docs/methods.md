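# Methods

## The measurement chain

The package treats ncRF profiling as a chain of deterministic statistics on
read-to-precursor assignments. All coordinates are 0-based half-open and
all lengths are in nt.

**Read structure and trimming.** Raw reads are 36 nt: a 7-nt adaptor, then
an insert of up to 29 nt. Trimming removes the leading adaptor when it
matches with ≤ 1 mismatch (reads without a match are flagged untrimmed and
passed through), then removes trailing padding at the first recurrence of
the adaptor's 5-nt prefix. The recurrence search starts at position 15
because shorter inserts are discarded anyway; this keeps chance 5-mer hits
inside genuine inserts (probability ≈ 1% per read) from truncating them.
Padding shorter than 5 nt — i.e. on inserts of 25–27 nt — is undetectable
by construction and rides along to a 29-nt insert; the consequences are
quantified under *Limitations*.

**Assignment.** An insert is placed by exhaustively scanning every
admissible ungapped window of every precursor (sense strand only) and
keeping hits with the minimal mismatch count, capped at 2. Ties are broken
by class priority (default miRNA > tRNA > rRNA > snoRNA > snRNA > mtRNA >
ra-ncRNA > others alphabetically), then smallest start, then lexicographic
precursor id, so multimappers resolve deterministically. The scanner is
vectorized (one uint8 window matrix per query length, cached, plus
memoization of repeated inserts), which is ample for references of a few
hundred short precursors; an exhaustive position-by-position oracle in the
test suite pins its semantics on 1,000 random instances. Antisense ncRNAs
are a *class of the reference*, not a strand decision at alignment time:
small-RNA references are conventionally oriented, so reverse-complement
matching is deliberately absent. Inserts shorter than 15 nt (configurable)
are discarded and counted.

**Fragment calling.** Insert length partitions reads exactly: ≤ 27 nt →
ncRF; ≥ 29 nt → full-length precursor read; exactly 28 nt → neither (the
two definitions leave a one-nt gap, and excluding is the only reading
consistent with both; 28-nt reads are tallied separately as `n_gap28`).
Precursors with fewer than 5 total mapped reads (fragments + full-length,
the most literal reading of the inclusion rule) are dropped entirely. A
fragment is 5′ when `start ≤ t`, 3′ when `precursor_length − end ≤ t`
(5′ wins if both hold, which requires a precursor ≤ 27+t nt), internal
otherwise; the tolerance `t` defaults to 2 nt to absorb ragged cleavage
and is reported in output metadata.

**Positional bins.** Each precursor, regardless of length L, is divided
into 10 bins, bin b covering `[⌊bL/10⌋, ⌊(b+1)L/10⌋)`. A fragment is
counted once, in the bin containing its start — deterministic and aligned
with the 5′-bias measurement; a coverage-spreading alternative (each read
distributed over the bins it overlaps, proportionally) is available via
`method="coverage"`. Counts are normalized within each class; an empty
class yields an all-zero distribution flagged empty rather than an error.

**Enrichment.** Per precursor, `ratio = n_fragment / n_precursor`
(fragments ≤ 27 nt over full-length reads ≥ 29 nt); a zero denominator is
reported as missing with the row retained. Family aggregation (tRNA
isoacceptors such as GlyGCC, snoRNA family ids, carried in the annotation
table's `family` column) sums numerators and denominators over members
*before* dividing. Both the ratio and the raw paired counts appear in the
output, since figure-level summaries sometimes plot one, sometimes the
other.

**Prorating.** Counts of pool p are multiplied by
`total(reference_pool) / total(p)`; totals default to assigned reads, with
fragment-only totals available, because the phrase "prorating all ncRF
reads to a reference sample" is ambiguous between the two. The reference
pool's factor is exactly 1.

**Comparison layer.** Change flags compare a control (Ct) and an exposed
(SR) value per item: `appeared`/`disappeared` require a true zero on one
side; otherwise `up`/`down` at a relative change ≥ 10% (explicit in the
output, since qualitative summary tables carry no stated threshold), else
`=`. Target predictions keep scores strictly > 80 with case-insensitive
gene deduplication; pathway records keep BH-adjusted p strictly < 0.05.
The BH step-up is implemented directly
(`adj_(i) = min(1, min_{k≥i} m·p_(k)/k)` on the sorted vector, mapped back
to input order) and is cross-checked in the tests against both a literal
brute-force of the definition and statsmodels. miRDB- and DAVID-style
results are consumed as plain TSV exports; the web services are never
queried.

## The simulator and what it emulates

`synthref` generates the study conditions: an annotated multi-class
precursor reference and seeded read libraries with per-read ground truth.

- **Reference.** `n_precursors_per_class` (default 20) random sequences
  per class, lengths uniform in a class-specific range (e.g. miRNA
  60–90 nt, rRNA 100–160 nt), bases i.i.d. with per-class GC targets —
  realized GC therefore hits the target in expectation, verified by direct
  base counting in the tests. tRNA precursors carry isoacceptor family
  labels (GlyGCC, GluCTC, …), snoRNAs carry family ids.
- **Composition.** Default class weights miRNA 0.80, ra-ncRNA 0.11, tRNA
  0.04, rRNA 0.02, snoRNA 0.015, snRNA 0.015 — the ~80% miRNA / ~11%
  repeat-associated library structure typical of brain small-RNA data.
- **Reads.** Each read draws a class (group-adjusted weights), a precursor
  (uniform within class), then either the precursor's first 29 nt (class
  full-length probability) or a terminal fragment: length from a
  discretized normal truncated to [15, 27], 5′-anchored with probability
  `end_bias`, else ending at the 3′ terminus. An optional internal-fragment
  rate (default 0) exercises the internal bucket; fragments otherwise come
  only from termini, so ground truth aligns with the end-mapping statistic
  being measured. The raw read is adaptor + insert, 3′-padded with the
  adaptor repeated to exactly 36 nt; qualities are constant Q40 since no
  quality filtering is modelled.
- **Length modes.** Only boxplot-level summaries (modes near 22 nt) are
  available to anchor the per-class distributions, so defaults are chosen
  as realistic rather than claimed as truth: mode 21–22 nt with sd 1.2
  (miRNA, whose mature-length distribution is tight) to 2.0 (rRNA, snoRNA,
  ra-ncRNA). All are configurable.
- **Group effects.** A `(region, sex, treatment)` → effect map applies
  multiplicative shifts to class weights (renormalized) and end bias
  (clipped to [0,1]), integer shifts to length modes, and additive GC
  shifts; an unknown group falls back to baseline with a logged warning.
  Per-group RNG streams are derived as `(seed, crc32(region_sex_treatment))`
  so samples are independent yet reproducible.
- **Determinism.** A fixed seed gives byte-identical FASTQ and tables.

Default library size is 50,000 reads per sample (the study's 1–6 million,
scaled to desk size); verification suites use 10,000-read pools, at which
binomial noise on an 80% class is ≈ ±0.8% (2 s.e.) — comfortably inside
the ±2% recovery band the tests assert.

### What the simulator does *not* model

Sequencing error, quality variation, tRNA modification chemistry and
mapping artefacts it causes, isoform/locus redundancy beyond simple family
copies, genomic (chromosomal) origin, and adapter dimers. Passing recovery
tests therefore demonstrates the *statistics* are computed correctly on
reads with known origins — not that real-library artefacts are handled.

## Numerical choices and degenerate inputs

- Fractions are exact ratios of counts; class fractions sum to 1 to 1e-9.
- Quartiles use linear interpolation (numpy default).
- A class profile over zero assigned reads, a zero-depth pool in
  prorating, an empty reference, and p-values outside [0,1] are errors;
  an empty bin class, a zero enrichment denominator, and an
  internal-only class in end-fraction summaries are flagged, not raised.
- Tables are written with 6-decimal floats and fixed column order, so
  write→read round-trips are exact at that precision and reruns are
  byte-identical.

## Limitations

- **Undetectable short padding.** Fragments of 25–27 nt leave < 5 nt of
  padding, which the trimmer cannot recognize; such inserts reach the
  aligner at 29 nt. 5′-anchored ones can still be placed (the pad bases
  count as mismatches) and then land in the full-length bucket; 3′ ones
  usually fail to map. With the default narrow length models this affects
  ≈ 1–4% of fragments per class, which the recovery suite shows keeps class
  fractions within ±2%, end bias within ±0.05 and busy-precursor
  enrichment within ±15% of ground truth. Wider length distributions push
  more mass into this blind spot.
- The ≤2-mismatch scanner is exhaustive, not seeded; it is designed for
  references of at most a few thousand short precursors, not genomes.
- Multimapper resolution by class priority is a documented convention, not
  a biological claim; alternative priorities are configurable.
- The comparison layer flags qualitative change; it performs no inferential
  statistics (no replicate-level variance model), mirroring a
  pooled-repeats design.
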