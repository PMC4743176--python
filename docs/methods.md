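# Methods

## Simulation model

**Genome and landscape.** A genome is a set of contigs with an
accessible-chromatin landscape: non-overlapping intervals, each with a
rate-multiplier weight. Coordinates are 0-based half-open throughout (BED
convention); a cut site is a single bp position. The landscape generator
draws region lengths from a bounded log-uniform law on [100, 3,000] bp —
spanning the peak-length range the comparison statistics stratify over —
and places them uniformly at random, rejecting overlaps, bookended
adjacency and contig-edge truncation (so truth regions stay distinct
intervals after merging). The final draw is resized within the bounds so
the realised accessible fraction lands on the target; a configuration whose
realised fraction deviates more than 20 % (relative), or that cannot be
placed without overlap, raises a configuration error rather than clipping.

**Insertions.** Conditional on the landscape, insertions on each
chromosomal molecule are an inhomogeneous Poisson process: per-bp rate
`rate_closed` outside regions, `rate_open × weight` inside. Counts are
drawn per (molecule, constant-rate segment) and positions uniformly within
the segment, which is exactly equivalent to the process and vectorizes
well. Each event carries an independent fair-coin transposon orientation.

**Mitochondrial background.** The mitochondrial contig is modelled as a
separate short contig (16,569 bp) carried on
`round(molecules_per_cell × mito_copy_factor)` molecules per cell —
elevated copy number, not an elevated per-copy rate — so its per-bp event
rate is `mito_copy_factor`-fold that of equal-length nuclear closed
chromatin. It is opt-in (`SimConfig.mito_contig`), because the comparative
statistics are about nuclear accessibility and a contig whose effective
rate rivals open chromatin would otherwise dominate peak lists, much as
real pipelines exclude chrM before analysis.

**Defaults as study conditions.** One nuclear contig of 2 Mb,
`accessible_fraction = 0.01`, `rate_open = 2·10⁻³` insertions/bp/molecule,
`rate_closed = rate_open / 100`, 100 cells × 2 molecules (diploid). The
open rate corresponds to a mean cut spacing of ~500 bp in open chromatin,
the density implied by on the order of 10⁵ unique transposition events per
cell spread over the ~1 % of a mammalian genome that is accessible on two
chromosomal copies. The comparative benchmark uses 500 cells, the input
size at which the two chemistries are classically compared head-to-head.
The mitochondrial copy factor defaults to 100, a textbook mtDNA copy
number per cell.

**Randomness.** One global seed; every consumer derives its stream via
`SeedSequence(entropy=(seed, tag))` with a fixed integer tag per module
(landscape 1, insertions 2, ATAC PCR duplicates 3, down-sampling 4, THS
end-efficiency 5), so modules are individually reproducible and independent.

## Capture models

**THS.** Tagmentation cuts the molecule at every insertion, and a T7
promoter points outward from each cut, so each cut offers two runoff
templates ending at the neighbouring cut or the molecule end. A template is
captured iff its runoff length is at least `ths_min_template` (400 bp, the
lower edge of the observed in vitro transcription fragment range); the
upper bound is configurable but **defaults to none**. This is a deliberate
model choice: linear amplification reads out an insertion end regardless of
the distance to the adjacent insertion, and observed template sizes of
"400–2,000+" bp reflect downstream fragmentation of long runoffs, not their
loss. A hard 2,000 bp gate would reject precisely the isolated insertions
in small accessible regions (whose runoff crosses tens of kb of sparse
closed chromatin) and invert the small-region sensitivity the chemistry is
designed for. Orientation never gates THS capture — permuting all
orientations leaves the output bit-identical, which is tested exactly.
Each captured template emits `amp_factor` duplicate reads (nominally 1,000;
analyses that only touch unique alignments may run with a small factor
since duplicates collapse at clonal removal). A per-end capture efficiency
parameter exists for sensitivity analyses and defaults to 1 (every end
usable).

**ATAC.** Adjacent cuts on one molecule define candidate fragments;
molecule ends never form fragments (PCR needs an adaptor at both ends). A
fragment is amplifiable iff (a) the two flanking insertions are in the
heteroadapter configuration and (b) its length falls in
[`atac_min_frag`, `atac_max_frag`] = [200, 800] bp by default. The
heteroadapter test is computed from the stored orientations — equal
orientation ⇒ two different adaptor species on the fragment, per tandem
insertion geometry — so the amplifiable fraction is exactly ½ marginally,
while fragments sharing a cut are weakly anti-correlated. (A variant with
an independent coin per fragment would erase that correlation; the
orientation-driven rule was chosen because orientations are already part of
the event record and the marginal is identical.) Each amplifiable fragment
emits two reads (one per end, opposite strands) per PCR copy, with copies
drawn from a geometric law (mean `pcr_mean_copies`, default 5).

A known asymmetry: an ATAC fragment of 200–399 bp is amplifiable although
its two flank runoffs are below the THS 400 bp minimum, so the intuition
"every ATAC fragment end is also a captured THS flank" holds only when the
THS window contains the ATAC window; the test suite checks the containment
inequality under such a configuration.

## Primary processing

Clonal removal keeps the first record per (contig, 5′ position, strand) key
in sort order (single-end convention; deterministic). Down-sampling draws a
uniform subset without replacement of exactly `n` records, seed-reproducible,
and operates on post-deduplication records because depth matching is stated
in unique alignments. Unique alignments equal distinct capture duplicate
groups only as long as no two templates collide on a genomic key; at
realistic densities occasional cross-molecule collisions occur, so that
bookkeeping identity is asserted on a sparse simulation only. SAM I/O goes
through pysam (positions converted to 1-based at the boundary; duplicate
groups ride in a `DG` tag); a 5-column TSV dialect (contig, start, strand,
duplicate_group, cell) and fixedStep wiggle export are provided.

## Stand-in peak caller

A deliberately transparent caller, not a reimplementation of any published
one: reads are binned (100 bp default), the background rate is the
genome-wide mean bin count excluding the top 1 % of bins (so open chromatin
does not inflate it), each bin gets the Poisson upper-tail p-value
P(X ≥ count), Benjamini–Hochberg correction is applied across all bins, and
bins with q ≤ α (default 0.01) merge into peaks; peaks shorter than 100 bp
(the smallest analyzed length bin) are dropped; the score is the summed bin
count. Count-0 bins are never significant. Lowering α can only shrink the
called set (monotonicity is tested). All comparison operations equally
accept imported BED peaks, so externally called peaks analyze unchanged.

## Comparison statistics: conventions

- "1 base pair or more" sharing means non-empty half-open intersection;
  bookended intervals do not overlap.
- "Overlap of X with reference R" is the fraction of X's base pairs covered
  by R (coverage-style, directional); the intersection itself is symmetric
  and computed by a linear sweep validated against a per-base oracle.
- Length-bin labels are upper edges: a 250 bp peak is in bin "300".
- Length-stratified overlap is normalized as
  `100 × bin_overlap_pct / global_overlap_pct`, the ratio interpretation of
  normalizing by the global base-pair overlap value.
- Empty bins and zero-denominator "percentage more peaks" values are
  reported as absent/NaN, never as 0 or infinity.
- A read is assigned to a peak by its 5′ position (reads model insertion
  sites). Reads-per-100-bp normalization removes zero-count peaks first and
  defaults to `count / (length/100)`; a `literal` mode (`count / 100`) is
  retained because the flat division only equals a density for 100-bp
  peaks. SEM uses the n−1 standard deviation; singleton bins report 0.
- The "larger 30 %" split ranks peaks by length, descending, with a stable
  (contig, start) tie-break and a ceiling split; percentages are of all
  alignments, so the two classes sum to the fraction-in-peaks × 100.
- TSS distances are signed from the peak midpoint to the nearest same-contig
  TSS, strand-aware (positive = downstream); default bin edges
  ±5 kb / 50 kb / 500 kb.

## Benchmark problem sizes

The comparative evaluation (`benchmark.run_assay_comparison`) uses a 2 Mb
genome, 500 cells, matched depth ≈ 10⁴ unique alignments, and replicates
over three seeds when a trend statistic is aggregated; the ATAC capture
probability curve uses 2,000 independent molecules per region length.
These sizes give Monte-Carlo standard errors comfortably below the effect
sizes of interest while keeping a full run in seconds.

## What the generator does and does not emulate

Emulated: the open/closed insertion-rate contrast (~1 % accessible,
100-fold rate ratio), random per-insertion orientation, amplification
duplicates, high-copy mitochondrial background, and the depth matching /
deduplication pipeline of real analyses. Not emulated: sequence-level Tn5
preference (no quantitative model is available for the enzymes in
question), nucleosome positioning and semi-accessible flanking chromatin,
mappability and alignment error, chromatin-state correlation between
molecules of one cell, and the elevated accessibility of protein-poor
mitochondrial DNA (real ATAC's 30–50 % mito read burden is therefore not
reproduced — the synthetic mito fraction reflects copy number only).
Passing tests show the mechanistic consequences of the capture chemistries
on an idealised landscape, not quantitative agreement with any real
library; real-data magnitudes (e.g. ENCODE overlap percentages) require the
corresponding real datasets, which are outside the build/test loop.

## Known limitations

- The stand-in caller's peaks are unions of whole bins, so peak boundaries
  are quantized to the bin size; the last bin of a contig may extend past
  the contig end.
- THS length-trend estimates above 1.3 kb rest on few occupied bins per
  simulation (a 2 Mb genome carries only a handful of >1.3 kb regions);
  the benchmark therefore aggregates over replicate seeds, and the trend is
  "flat to slightly negative" rather than exactly zero — dense insertion
  spacing in long regions removes sub-400-bp templates, the same mechanism
  that keeps THS free of the ATAC large-peak preference.
- Down-sampling composition (`downsample(n₂) ∘ downsample(n₁)`) yields a
  valid uniform subset but not the same subset as a direct `downsample(n₂)`.
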