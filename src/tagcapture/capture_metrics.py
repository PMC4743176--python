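"""Capture-efficiency and capture-bias statistics.

Counts alignments in peaks (the FRiP-style capture-efficiency fraction),
normalizes per-peak counts to reads per 100 bp with zero-count peaks
removed, summarizes them as mean +- SEM per 100-bp peak-length bin, splits
alignments between the larger 30 % and smaller 70 % of peaks, and converts
unique-alignment totals into transposition events per cell (each unique
read represents one transposition event on one chromosomal molecule).

A read is assigned to a peak by its 5' position — reads model insertion
sites, so a read is in a peak iff its cut site lies inside the half-open
peak interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from tagcapture.alignment_processing import AlignmentRecord, LibrarySummary
from tagcapture.peak_calling import PeakSet


@dataclass
class PeakCountTable:
    """Per-peak alignment counts plus library-level totals.

    ``rows`` columns: contig, start, end, length, alignment_count and — after
    normalization — reads_per_100bp.  ``normalization`` records which mode
    produced the normalized column (None before normalization).
    """

    rows: pd.DataFrame
    alignments_in_peaks: int
    alignments_total: int
    normalization: str | None = None

    @property
    def fraction_in_peaks(self) -> float:
        if self.alignments_total == 0:
            return 0.0
        return self.alignments_in_peaks / self.alignments_total


@dataclass
class BinnedSEMTable:
    """Mean +- SEM of reads_per_100bp per peak-length bin (upper-edge
    labels); every emitted row has at least one peak."""

    bin_width: int
    rows: pd.DataFrame  # columns: length_bin, n_peaks, mean_reads_per_100bp, sem


@dataclass(frozen=True)
class RankSplitResult:
    pct_alignments_in_larger_30pct: float
    pct_alignments_in_smaller_70pct: float
    split_index: int


@dataclass(frozen=True)
class TranspositionEventEstimate:
    unique_alignments: int
    n_cells: int
    events_per_cell: float


def count_alignments_in_peaks(records: Sequence[AlignmentRecord],
                              S: PeakSet) -> PeakCountTable:
    """Count, for every peak, the alignments whose 5' position falls in
    [start, end).  Peaks are disjoint after merging, so each record lands in
    at most one peak."""
    counts = np.zeros(len(S), dtype=np.int64)
    peak_idx_by_contig: dict[str, np.ndarray] = {}
    for contig in S.contigs:
        peak_idx_by_contig[contig] = np.asarray(
            [i for i, p in enumerate(S) if p.contig == contig])
    by_contig: dict[str, list[int]] = {}
    for r in records:
        by_contig.setdefault(r.contig, []).append(r.position)
    in_peaks = 0
    for contig, positions in by_contig.items():
        starts, ends = S.intervals_on(contig)
        if starts.size == 0:
            continue
        pos = np.asarray(positions, dtype=np.int64)
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        j_in = j[inside]
        np.add.at(counts, peak_idx_by_contig[contig][j_in], 1)
        in_peaks += int(inside.sum())
    rows = pd.DataFrame({
        "contig": [p.contig for p in S],
        "start": [p.start for p in S],
        "end": [p.end for p in S],
        "length": [p.length for p in S],
        "alignment_count": counts,
    })
    return PeakCountTable(rows=rows, alignments_in_peaks=in_peaks,
                          alignments_total=len(records))


def normalize_reads_per_100bp(table: PeakCountTable,
                              mode: str = "per_length") -> PeakCountTable:
    """Add the reads_per_100bp column, removing zero-count peaks first.

    ``per_length``: count / (peak_length / 100) — reads per 100 bp of peak.
    ``literal``: count / 100 regardless of peak length.
    Both modes exist because a flat division by 100 only equals a per-100-bp
    density for peaks of exactly 100 bp; ``per_length`` is the default.
    """
    if mode not in ("per_length", "literal"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    rows = table.rows[table.rows["alignment_count"] > 0].copy()
    if mode == "per_length":
        rows["reads_per_100bp"] = rows["alignment_count"] / (rows["length"] / 100.0)
    else:
        rows["reads_per_100bp"] = rows["alignment_count"] / 100.0
    return PeakCountTable(rows=rows.reset_index(drop=True),
                          alignments_in_peaks=table.alignments_in_peaks,
                          alignments_total=table.alignments_total,
                          normalization=mode)


def binned_mean_sem(table: PeakCountTable, bin_width: int = 100) -> BinnedSEMTable:
    """Mean +- SEM of the normalized counts per peak-length bin.

    SEM is the sample (n-1) standard deviation over sqrt(n); a single-member
    bin reports SEM 0 so summaries remain total.
    """
    if "reads_per_100bp" not in table.rows.columns:
        raise ValueError("normalize_reads_per_100bp must be applied first")
    rows = table.rows
    bins = (np.ceil(rows["length"] / bin_width) * bin_width).astype(np.int64)
    grouped = (rows.assign(length_bin=bins)
               .groupby("length_bin")["reads_per_100bp"]
               .agg(n_peaks="size", mean_reads_per_100bp="mean",
                    sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0)
               .reset_index())
    return BinnedSEMTable(bin_width, grouped)


def rank_split(records: Sequence[AlignmentRecord], S: PeakSet,
               table: PeakCountTable | None = None,
               split_fraction: float = 0.30) -> RankSplitResult:
    """Percentage of all alignments in the larger 30 % vs smaller 70 % of
    peaks.

    Peaks are ranked by length descending with a stable (contig, start)
    tie-break; the top ``ceil(split_fraction * |S|)`` form the larger class.
    Percentages are of all alignments, in and out of peaks, so the two
    numbers sum to the capture-efficiency fraction times 100.
    """
    if len(S) == 0:
        raise ValueError("peak set must be non-empty")
    if table is None:
        table = count_alignments_in_peaks(records, S)
    rows = table.rows.sort_values(["length", "contig", "start"],
                                  ascending=[False, True, True],
                                  kind="stable").reset_index(drop=True)
    split = math.ceil(split_fraction * len(rows))
    total = table.alignments_total
    larger = int(rows["alignment_count"].iloc[:split].sum())
    smaller = int(rows["alignment_count"].iloc[split:].sum())
    return RankSplitResult(
        pct_alignments_in_larger_30pct=100.0 * larger / total if total else 0.0,
        pct_alignments_in_smaller_70pct=100.0 * smaller / total if total else 0.0,
        split_index=split,
    )


def events_per_cell(summary: LibrarySummary, n_cells: int) -> TranspositionEventEstimate:
    """Unique transposition events per cell: each unique read represents one
    transposition event, so this is unique alignments over cell count."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return TranspositionEventEstimate(
        unique_alignments=summary.unique_alignments,
        n_cells=n_cells,
        events_per_cell=summary.unique_alignments / n_cells,
    )
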