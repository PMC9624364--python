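# ncrf — small-RNA classification and ncRNA-fragment profiling

`ncrf` is a Python package for profiling **non-coding RNA fragments
(ncRFs)** — tRFs, rRFs, snoRFs, snRFs and friends — in small RNA-seq
libraries. Stable fragments of tRNAs, rRNAs, snoRNAs and snRNAs are
regulated products of precursor processing, and comparing their abundance,
end-of-origin and positional profiles between experimental groups (e.g.
brain regions of control vs. scatter-irradiated animals, by sex) requires a
chain of small, well-defined statistics. This package implements that chain
as a tested library plus a thin CLI, together with a synthetic read
simulator that carries per-read ground truth so every stage can be verified
by parameter recovery.

## What it computes

Raw 36-nt reads are modelled as a 7-nt adaptor followed by a 29-nt ncRNA
insert. After adaptor trimming, each insert *s* is placed on an annotated
precursor reference by an ungapped, sense-strand, best-hit scan allowing at
most 2 mismatches (the classic `bowtie -v 2 --best` policy), with
deterministic tie-breaking (class priority, then position, then id). On top
of the assignments:

- **Class profiles** — per-class read fractions (of 1), pooled GC content,
  and insert-size distributions with quartile summaries; mapping rate
  `100·assigned/raw`.
- **ncRF calls** — a read is an ncRF iff its insert length ≤ 27 nt; reads
  ≥ 29 nt count as full-length precursor reads; 28-nt reads belong to
  neither set. Only precursors with ≥ 5 mapped reads are analysed. Each
  fragment is 5′, 3′ or internal depending on whether it starts/ends within
  a small tolerance (default 2 nt) of a precursor terminus.
- **Positional bins** — every precursor is split into 10 equal bins and
  fragment starts are counted per bin, normalized within each ncRNA class.
- **Enrichment** — per precursor (or per family, e.g. tRNA isoacceptor
  GlyGCC): `ratio = n_fragment(≤27 nt) / n_precursor(≥29 nt)`; a ratio of 1
  means one fragment per full-length read.
- **Prorating** — cross-pool counts rescaled by library-size ratio to a
  designated reference pool.
- **Comparison** — control-vs-exposed change flags (up/down/appeared/
  disappeared), target-prediction filtering (score strictly > 80),
  Benjamini–Hochberg correction with strict adjusted-p < 0.05 pathway
  filtering, and 2–4-set Venn decompositions.

## Worked example

```python
import ncrf
from ncrf.pipeline import classify_reads

params = ncrf.SimulationParams(seed=1, n_reads=10_000)
sequences, annotation = ncrf.make_reference(params)
reads, truth = ncrf.simulate_sample(params, sequences, annotation)

index = ncrf.PrecursorIndex(sequences, annotation)
assignments, stats = classify_reads(reads, index, params.adaptor)
print(f"mapping rate: {stats.mapping_rate_pct:.1f}%")

profile = ncrf.class_profile(assignments, pool_id="FC_SR_M")
print(profile.fractions.round(3))

lengths = {p: len(s) for p, s in sequences.items()}
fragset = ncrf.call_fragments(assignments, lengths, annotation)
print(ncrf.end_fraction_summary(fragset).per_class.round(3))
```

prints

```
mapping rate: 98.7%
class
miRNA       0.802
rRNA        0.020
ra-ncRNA    0.105
snRNA       0.017
snoRNA      0.017
tRNA        0.040
Name: proportion, dtype: float64
          frac_5prime  frac_3prime  n_end
class
miRNA           0.806        0.194   3847
rRNA            0.624        0.376    109
ra-ncRNA        0.473        0.527    579
snRNA           1.000        0.000    115
snoRNA          0.530        0.470    100
tRNA            1.000        0.000    359
```

The classifier recovers the simulator's composition (80% miRNA, 11%
repeat-associated, …) to a few tenths of a percent, and the per-class
5′-fraction column reproduces the configured cleavage biases (tRNA and
snRNA fragments purely 5′-derived, snoRNA/rRNA mixed). Family-level
enrichment then quantifies fragments per full-length read, e.g. for the
tRNA isoacceptors:

```python
enrich = ncrf.enrichment(fragset, by="family")
print(enrich[enrich["class"] == "tRNA"][
    ["family", "n_fragment", "n_precursor", "ratio"]].round(2).to_string(index=False))
```

```
family  n_fragment  n_precursor  ratio
GluCTC          67            8   8.38
GlyGCC          70            9   7.78
HisGTG          89            9   9.89
LysCTT          73            9   8.11
ValCAC          60            5  12.00
```

— high ratios, as expected for a class simulated with a low full-length
emission probability (tRFs dominating their precursors).

The same workflow is available from the shell:

```sh
ncrf simulate --config params.yaml --out sim/ --seed 1 --group FC_M_SR
ncrf classify --reads sim/FC_M_SR.fastq --ref sim/reference.fa \
              --annot sim/annotation.tsv --adaptor TGGAATT --out run/
ncrf fragments --assignments run/assignments.tsv --ref sim/reference.fa \
               --annot sim/annotation.tsv --out run/
ncrf compare --ct-profile ct/class_profile.tsv --sr-profile sr/class_profile.tsv \
             --region FC --sex M --out cmp/
```

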