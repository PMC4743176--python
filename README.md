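# tagcapture

Mechanistic models of tagmentation-based chromatin-accessibility assays,
plus the complete peak-set comparison toolkit used to benchmark them.

Chromatin accessibility is commonly mapped by letting a Tn5 transposase cut
and tag ("tagment") genomic DNA, which it does preferentially in
nucleosome-depleted regions. Two library chemistries turn those insertion
events into sequencing reads in very different ways:

- **THS-seq** (transposome hypersensitive sites sequencing) attaches a T7
  promoter to every cut end and amplifies linearly by in vitro
  transcription (~1,000-fold), so *every* insertion end with enough runoff
  template becomes a read, regardless of transposon orientation.
- **ATAC-seq** amplifies by PCR the fragment *between* two adjacent
  insertions. This costs a factor of two up front — the adaptors at the
  two ends are in the PCR-compatible (heteroadapter) configuration only
  half the time, because each transposon inserts in random orientation —
  and it imposes a fragment-size window (~200–800 bp), so two compatible
  insertions must land close together. Small accessible regions rarely
  contain such a pair and are lost.

`tagcapture` implements both capture models on top of a per-molecule Tn5
insertion simulator with a ground-truth accessible landscape, the standard
primary processing applied to real libraries (clonal read removal on the
(contig, 5′ position, strand) key, seed-reproducible down-sampling to
matched unique-alignment depth, coverage binning, a transparent Poisson
stand-in peak caller), and every comparison statistic used in accessibility
benchmarking:

- base-pair overlap between peak sets (coverage-style linear sweep) and
  ≥1-bp peak sharing,
- peak-size distributions and length-stratified overlap normalized by the
  global overlap percentage,
- "percentage more peaks" per 100-bp length bin, three-way Venn sharing,
  peak-to-TSS distance binning,
- FRiP-style capture efficiency (fraction of alignments in peaks), reads
  per 100 bp of peak with zero-count peaks removed, mean ± SEM per 100-bp
  peak-length bin, the larger-30 % / smaller-70 % alignment split, and
  unique transposition events per cell.

It is written for people developing or evaluating accessibility assays and
peak-comparison pipelines: real BED peak files (e.g. Dfilter or ENCODE
output) and SAM/TSV alignment records can be imported and analyzed with the
same functions the simulator feeds.

## Model sketch

Insertions on one chromosomal molecule follow an inhomogeneous Poisson
process with per-bp rate `r_closed` outside accessible regions and
`r_open · w` inside a region of weight `w` (defaults: `r_open = 2·10⁻³`,
`r_closed = r_open/100` per bp per molecule, i.e. ~500 bp mean cut spacing
in open chromatin). Each insertion carries an independent uniform
orientation. For cuts `p₁ < … < p_k` on a molecule:

- **THS**: each cut offers two runoff templates with lengths
  `p_i − p_{i−1}` (left) and `p_{i+1} − p_i` (right, molecule ends
  included); a template is captured iff its length is ≥ 400 bp (an upper
  bound can be configured), and emits `amp_factor` duplicate reads in one
  duplicate group.
- **ATAC**: each adjacent pair defines a candidate fragment of length
  `p_{i+1} − p_i`, amplifiable iff the flanking orientations are compatible
  (probability ½) and the length is in [200, 800] bp; each fragment emits
  two reads per geometric PCR copy.

A high-copy mitochondrial contig (copy factor × molecules per cell) can be
added to emulate mitochondrial background reads.

## Worked example

`examples/04_capture_bias.py` runs both assays on one 2 Mb synthetic
landscape (~1 % accessible, regions 100–3,000 bp, 500 cells) at matched
unique-alignment depth:

```
matched unique-alignment depth: 10,004
truth regions: 26 (12 of them <= 400 bp)

                                 THS      ATAC
        truth recall (all)     0.985     0.924
   truth recall (<=400 bp)     0.900     0.324
   fraction reads in peaks     0.251     0.940
length-trend rho (>1.3 kb)    -0.500     1.000

ATAC capture probability by region length (2,000 molecules each):
    100 bp: 0.001
    300 bp: 0.013
   1000 bp: 0.237
   2000 bp: 0.503
   3000 bp: 0.678
```

Reading the numbers: both assays recover most accessible base pairs
overall, but for regions ≤ 400 bp THS recovers 90 % of truth base pairs
where ATAC recovers 32 % — the orientation and spacing constraints of PCR
capture starve small regions of amplifiable fragments, as the capture
probability curve shows directly. The Spearman correlation of mean reads
per 100 bp against peak length (bins above 1.3 kb) is strongly positive for
ATAC (large-peak capture bias) and flat-to-negative for THS. The other
examples cover landscape simulation, the raw capture yield gap, and the
single-assay peak pipeline.

A thin CLI mirrors the pipeline for shell use:
`tagcapture simulate | capture | dedup | downsample | summarize | callpeaks
| compare | counts | ranksplit | binned` (see `tagcapture --help`).

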