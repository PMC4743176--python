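"""THS vs ATAC capture bias at matched unique-alignment depth.

Reproduces the mechanistic comparison: on the same synthetic landscape, both
assays are down-sampled to the same unique-alignment depth and peak-called;
THS recovers small accessible regions that ATAC misses, and the ATAC
alignment density per 100 bp of peak rises with peak length (large-peak
capture bias) while the THS profile stays flat.  A separate Monte-Carlo
sweep shows the ATAC capture probability of a region growing with its
length.
"""

from tagcapture.benchmark import atac_capture_probability_curve, run_assay_comparison

comparison = run_assay_comparison(seed=1)
print(f"matched unique-alignment depth: {comparison.depth:,}")
print(f"truth regions: {comparison.n_regions} "
      f"({comparison.n_small_regions} of them <= 400 bp)\n")
print(f"{'':>26}{'THS':>10}{'ATAC':>10}")
rows = [
    ("truth recall (all)", "recall_overall"),
    ("truth recall (<=400 bp)", "recall_small"),
    ("fraction reads in peaks", "fraction_in_peaks"),
    ("length-trend rho (>1.3 kb)", "length_trend_rho"),
]
for label, attr in rows:
    values = getattr(comparison, attr)
    print(f"{label:>26}{values['THS']:>10.3f}{values['ATAC']:>10.3f}")

print("\nATAC capture probability by region length (2,000 molecules each):")
curve = atac_capture_probability_curve([100, 300, 1000, 2000, 3000], seed=5)
for _, row in curve.iterrows():
    print(f"  {int(row.region_length):5} bp: {row.capture_probability:.3f}")
print("\nThe probability rises with length: spacing- and orientation-"
      "constrained PCR\nrarely finds two compatible insertions inside a "
      "small region, which is why\nATAC loses small peaks and THS does not.")
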