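"""Peak-set comparison statistics.

Every statistic used to compare accessibility peak sets lives here:
base-pair overlap (coverage-style, computed by a linear sweep over sorted
intervals), >=1-bp peak sharing, peak-size distributions, length-stratified
overlap normalized by the global overlap, "percentage more peaks" per
length bin, three-way sharing (Venn classes of a counting set against two
others), and peak-to-TSS distance binning.

Conventions: all coordinates 0-based half-open; "one base pair or more"
means a non-empty half-open intersection, so bookended intervals do not
overlap.  "Overlap of X with reference R" is always the fraction of X's
base pairs covered by R.  A peak of length L belongs to the length bin
whose label is ``ceil(L / bin_width) * bin_width`` (upper edge, so a 250 bp
peak falls in bin "300").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tagcapture.peak_calling import PeakSet


@dataclass(frozen=True)
class OverlapSummary:
    bp_A: int
    bp_B: int
    bp_intersection: int
    frac_A_covered: float
    frac_B_covered: float
    peaks_A_shared: int
    peaks_B_shared: int


@dataclass
class LengthBinTable:
    """Per-length-bin statistics; ``rows`` columns depend on the producing
    operation but always include ``length_bin`` (upper-edge label, bp)."""

    bin_width: int
    rows: pd.DataFrame


@dataclass(frozen=True)
class ThreeWaySharing:
    """Classification of the counting set's peaks by which of the two other
    sets each shares >= 1 bp with; the four classes partition the set."""

    counting: str
    other_first: str
    other_second: str
    with_both: int
    with_first_only: int
    with_second_only: int
    with_neither: int

    @property
    def total(self) -> int:
        return (self.with_both + self.with_first_only
                + self.with_second_only + self.with_neither)


def per_peak_overlap(A: PeakSet, B: PeakSet) -> np.ndarray:
    """Base pairs of each A peak covered by B, in A's peak order.

    Uses a cumulative-coverage sweep over B's sorted, merged intervals: the
    covered bp below position x is a piecewise-linear function evaluated by
    binary search, and the overlap of [s, e) is cov(e) - cov(s).
    """
    out = np.zeros(len(A), dtype=np.int64)
    idx = 0
    for contig in sorted({p.contig for p in A}):
        a_peaks = [(i, p) for i, p in enumerate(A) if p.contig == contig]
        b_starts, b_ends = B.intervals_on(contig)
        if b_starts.size == 0:
            continue
        cum = np.concatenate(([0], np.cumsum(b_ends - b_starts)))

        def cov(x: np.ndarray) -> np.ndarray:
            j = np.searchsorted(b_starts, x, side="right") - 1
            j = np.clip(j, 0, b_starts.size - 1)
            partial = np.clip(x - b_starts[j], 0, b_ends[j] - b_starts[j])
            return np.where(x <= b_starts[0], 0, cum[j] + partial)

        starts = np.asarray([p.start for _, p in a_peaks])
        ends = np.asarray([p.end for _, p in a_peaks])
        ov = cov(ends) - cov(starts)
        for (i, _), o in zip(a_peaks, ov):
            out[i] = o
    return out


def basepair_overlap(A: PeakSet, B: PeakSet) -> OverlapSummary:
    """Coverage-style base-pair overlap between two merged peak sets.

    ``bp_intersection`` is symmetric; the covered fractions and shared-peak
    counts are directional.
    """
    ov_a = per_peak_overlap(A, B)
    ov_b = per_peak_overlap(B, A)
    inter = int(ov_a.sum())
    assert inter == int(ov_b.sum())
    bp_a, bp_b = A.total_bp, B.total_bp
    return OverlapSummary(
        bp_A=bp_a,
        bp_B=bp_b,
        bp_intersection=inter,
        frac_A_covered=inter / bp_a if bp_a else 0.0,
        frac_B_covered=inter / bp_b if bp_b else 0.0,
        peaks_A_shared=int((ov_a > 0).sum()),
        peaks_B_shared=int((ov_b > 0).sum()),
    )


def peak_sharing(A: PeakSet, B: PeakSet) -> tuple[int, int]:
    """Counts of peaks sharing >= 1 bp with the other set, per direction.
    A peak is counted once however many peaks of the other set it touches."""
    return (int((per_peak_overlap(A, B) > 0).sum()),
            int((per_peak_overlap(B, A) > 0).sum()))


def _length_bins(lengths: np.ndarray, bin_width: int) -> np.ndarray:
    return (np.ceil(lengths / bin_width) * bin_width).astype(np.int64)


def size_distribution(S: PeakSet, bin_width: int = 100) -> LengthBinTable:
    """Peak counts and base pairs per length bin (upper-edge labels)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(S) == 0:
        return LengthBinTable(bin_width, pd.DataFrame(
            columns=["length_bin", "peak_count", "bp_in_bin"]))
    lengths = np.asarray([p.length for p in S])
    bins = _length_bins(lengths, bin_width)
    df = (pd.DataFrame({"length_bin": bins, "length": lengths})
          .groupby("length_bin")
          .agg(peak_count=("length", "size"), bp_in_bin=("length", "sum"))
          .reset_index())
    return LengthBinTable(bin_width, df)


def length_stratified_overlap(S: PeakSet, reference: PeakSet, bin_width: int = 100,
                              global_overlap_pct: float | None = None) -> LengthBinTable:
    """Per-length-bin base-pair overlap of S with a reference set, plus the
    same overlap normalized by the global overlap percentage.

    overlap_pct(L) = 100 * (bp of S peaks in bin L covered by reference)
                         / (bp of S peaks in bin L);
    normalized_overlap_pct(L) = 100 * overlap_pct(L) / global_overlap_pct.
    When ``global_overlap_pct`` is not given it is computed from
    ``basepair_overlap(S, reference)``.  Only occupied bins are emitted, so
    an empty bin is absent rather than zero.
    """
    if global_overlap_pct is None:
        global_overlap_pct = 100.0 * basepair_overlap(S, reference).frac_A_covered
    if not (0.0 < global_overlap_pct <= 100.0):
        raise ValueError("global_overlap_pct must be in (0, 100]")
    lengths = np.asarray([p.length for p in S], dtype=np.int64)
    overlap = per_peak_overlap(S, reference)
    df = (pd.DataFrame({
            "length_bin": _length_bins(lengths, bin_width),
            "bp": lengths,
            "ov": overlap,
        })
        .groupby("length_bin")
        .agg(peak_count=("bp", "size"), bp_in_bin=("bp", "sum"),
             bp_overlap_with_reference=("ov", "sum"))
        .reset_index())
    df["overlap_pct"] = 100.0 * df["bp_overlap_with_reference"] / df["bp_in_bin"]
    df["normalized_overlap_pct"] = 100.0 * df["overlap_pct"] / global_overlap_pct
    return LengthBinTable(bin_width, df)


def pct_more_peaks(S: PeakSet, other: PeakSet, bin_width: int = 100) -> LengthBinTable:
    """Per length bin, the percentage more peaks in S than in the other set:
    100 * (count_S - count_other) / count_other, NaN where the other set has
    no peaks in the bin (undefined, not infinite)."""
    count_s = size_distribution(S, bin_width).rows.set_index("length_bin")["peak_count"]
    count_o = size_distribution(other, bin_width).rows.set_index("length_bin")["peak_count"]
    df = pd.DataFrame({"count_S": count_s, "count_other": count_o}).fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (df["count_S"] - df["count_other"]) / df["count_other"]
    df["pct_more_peaks"] = pct.replace([np.inf, -np.inf], np.nan)
    return LengthBinTable(bin_width, df.reset_index().rename(
        columns={"index": "length_bin"}))


def threeway_sharing(A: PeakSet, B: PeakSet, C: PeakSet,
                     counting: str = "A") -> ThreeWaySharing:
    """Classify each peak of the counting set by >=1-bp sharing with the
    other two sets (e.g. peaks found by A and B but not C)."""
    sets = {"A": A, "B": B, "C": C}
    if counting not in sets:
        raise ValueError("counting must be one of 'A', 'B', 'C'")
    count_set = sets.pop(counting)
    (name1, first), (name2, second) = sets.items()
    in_first = per_peak_overlap(count_set, first) > 0
    in_second = per_peak_overlap(count_set, second) > 0
    return ThreeWaySharing(
        counting=counting, other_first=name1, other_second=name2,
        with_both=int((in_first & in_second).sum()),
        with_first_only=int((in_first & ~in_second).sum()),
        with_second_only=int((~in_first & in_second).sum()),
        with_neither=int((~in_first & ~in_second).sum()),
    )


DEFAULT_TSS_EDGES = (-500_000, -50_000, -5_000, 0, 5_000, 50_000, 500_000)


def tss_distance_distribution(S: PeakSet, tss: list[tuple[str, int, str]],
                              bin_edges=DEFAULT_TSS_EDGES) -> pd.DataFrame:
    """Signed distance from each peak midpoint to its nearest TSS, binned.

    The distance is strand-aware: positive means the midpoint lies 3' of
    the TSS (downstream), negative upstream.  Nearest means smallest
    absolute distance among TSS on the peak's contig; peaks on contigs with
    no TSS are not assigned.  Returns a DataFrame of (bin_low, bin_high,
    count) with open outer bins at +-infinity.
    """
    if not tss:
        raise ValueError("TSS list must be non-empty")
    by_contig: dict[str, list[tuple[int, str]]] = {}
    for contig, position, strand in tss:
        by_contig.setdefault(contig, []).append((int(position), strand))
    distances = []
    for p in S:
        if p.contig not in by_contig:
            continue
        mid = (p.start + p.end) // 2
        best = None
        for position, strand in by_contig[p.contig]:
            d = mid - position if strand == "+" else position - mid
            if best is None or abs(d) < abs(best):
                best = d
        distances.append(best)
    edges = np.concatenate(([-np.inf], np.asarray(bin_edges, dtype=float), [np.inf]))
    counts, _ = np.histogram(np.asarray(distances, dtype=float), bins=edges)
    return pd.DataFrame({
        "bin_low": edges[:-1],
        "bin_high": edges[1:],
        "count": counts,
    })
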