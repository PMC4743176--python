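"""Peak sets and a transparent stand-in peak caller.

Externally called peaks (e.g. Dfilter or ENCODE narrowPeak-style BED) are
imported unchanged through :func:`read_peaks`; every downstream comparison
operates on :class:`PeakSet` regardless of origin.  The built-in caller is a
deliberately simple bin-based Poisson test so that the pipeline is fully
self-contained on synthetic data: it makes no attempt to reproduce any
particular published caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from tagcapture.alignment_processing import CoverageTrack


@dataclass(frozen=True)
class Peak:
    """A half-open genomic interval called significant."""

    contig: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid peak [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class PeakSet:
    """A named set of peaks, sorted by (contig, start) and merged on
    construction: overlapping or bookended input intervals become one peak
    whose score is the sum of its parts."""

    def __init__(self, peaks, name: str = ""):
        self.name = name
        self.peaks: list[Peak] = self._merge(sorted(
            peaks, key=lambda p: (p.contig, p.start, p.end)))
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig in {p.contig for p in self.peaks}:
            sub = [p for p in self.peaks if p.contig == contig]
            self._index[contig] = (
                np.asarray([p.start for p in sub], dtype=np.int64),
                np.asarray([p.end for p in sub], dtype=np.int64),
            )

    @staticmethod
    def _merge(sorted_peaks: list[Peak]) -> list[Peak]:
        merged: list[Peak] = []
        for p in sorted_peaks:
            if merged and merged[-1].contig == p.contig and p.start <= merged[-1].end:
                last = merged.pop()
                merged.append(Peak(p.contig, last.start, max(last.end, p.end),
                                   last.score + p.score))
            else:
                merged.append(p)
        return merged

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return [(p.contig, p.start, p.end) for p in self.peaks] == \
               [(p.contig, p.start, p.end) for p in other.peaks]

    @property
    def total_bp(self) -> int:
        return sum(p.length for p in self.peaks)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._index)

    def intervals_on(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one contig (empty if absent)."""
        if contig in self._index:
            return self._index[contig]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty


def read_peaks(path, name: str | None = None) -> PeakSet:
    """Load a BED file (>= 3 columns) into a sorted, merged PeakSet.

    A malformed line raises ValueError naming the 1-based line number.
    Column 5 is used as the score when present.
    """
    peaks = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{line_no}: start must be < end")
            score = 0.0
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = 0.0
            peaks.append(Peak(fields[0], start, end, score))
    return PeakSet(peaks, name=name or str(path))


def write_peaks(peak_set: PeakSet, path) -> None:
    """Write a PeakSet as 5-column BED (name column carries the set name)."""
    with open(path, "w") as fh:
        for p in peak_set:
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{peak_set.name or '.'}\t"
                     f"{p.score:g}\n")


def estimate_background(tracks, trim_top: float = 0.01) -> float:
    """Genome-wide mean bin count excluding the top ``trim_top`` fraction of
    bins, so open-chromatin bins do not inflate the background estimate."""
    counts = np.concatenate([t.counts for t in tracks]) if tracks else np.empty(0)
    if counts.size == 0:
        return 0.0
    cutoff = np.quantile(counts, 1.0 - trim_top)
    trimmed = counts[counts <= cutoff]
    return float(trimmed.mean()) if trimmed.size else float(counts.mean())


def call_peaks_standin(tracks: list[CoverageTrack], background_rate: float | None = None,
                       alpha: float = 0.01, min_width: int = 100,
                       name: str = "standin") -> PeakSet:
    """Bin-based Poisson enrichment caller.

    A bin is significant when its count clears the Poisson(background)
    upper tail at level ``alpha`` after Benjamini-Hochberg correction across
    all bins of all tracks; adjacent significant bins merge into one peak;
    peaks shorter than ``min_width`` bp are dropped.  Peak score is the
    summed bin count.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not tracks:
        return PeakSet([], name=name)
    if background_rate is None:
        background_rate = estimate_background(tracks)
    all_counts = np.concatenate([t.counts for t in tracks])
    if all_counts.sum() == 0:
        return PeakSet([], name=name)
    # P(X >= count) under Poisson(background); count 0 is never significant
    pvals = stats.poisson.sf(all_counts - 1, background_rate)
    pvals[all_counts == 0] = 1.0
    qvals = stats.false_discovery_control(pvals, method="bh")
    significant = qvals <= alpha

    peaks = []
    offset = 0
    for track in tracks:
        sig = significant[offset:offset + track.counts.size]
        offset += track.counts.size
        edges = np.flatnonzero(np.diff(np.concatenate(([0], sig.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            start = int(lo) * track.bin_size
            end = int(hi) * track.bin_size
            if end - start < min_width:
                continue
            peaks.append(Peak(track.contig, start, end,
                              float(track.counts[lo:hi].sum())))
    return PeakSet(peaks, name=name)
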