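"""Primary processing of alignment records.

Implements the steps applied to every library before any comparison:
clonal (duplicate) read removal on the (contig, 5' position, strand) key,
random down-sampling to a fixed unique-alignment depth so that libraries
are compared at matched depth, library summaries (clonal rate,
mitochondrial fraction) and fixed-bin coverage tracks.

Internal coordinates are 0-based half-open; SAM positions are converted
from 1-based at the reader/writer boundary (handled by pysam).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from tagcapture.synthetic_data import GenomeModel, stream_rng, STREAM_DOWNSAMPLE


@dataclass(frozen=True)
class AlignmentRecord:
    """A mapped single-end read: contig, 0-based 5' position, strand, and an
    optional duplicate-group label carried over from the capture model."""

    contig: str
    position: int
    strand: str  # '+' | '-'
    duplicate_group: int | None = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.strand)


@dataclass(frozen=True)
class LibrarySummary:
    total_reads: int
    unique_alignments: int
    clonal_rate: float
    mito_fraction: float


@dataclass
class CoverageTrack:
    """Per-contig read-start counts in fixed bins of ``bin_size`` bp."""

    contig: str
    bin_size: int
    counts: np.ndarray

    def total(self) -> int:
        return int(self.counts.sum())


def _check_sorted(records: Sequence[AlignmentRecord]) -> None:
    for a, b in zip(records, records[1:]):
        if a.key > b.key:
            raise ValueError("records must be sorted by (contig, position, strand)")


def sort_records(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    return sorted(records, key=lambda r: r.key)


def remove_clonal(records: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse clonal reads: keep exactly one record per distinct
    (contig, position, strand) key — the first in sort order.  Idempotent.
    """
    _check_sorted(records)
    out: list[AlignmentRecord] = []
    last_key = None
    for record in records:
        if record.key != last_key:
            out.append(record)
            last_key = record.key
    return out


def downsample(records: Sequence[AlignmentRecord], n: int, seed: int) -> list[AlignmentRecord]:
    """Uniformly random, seed-reproducible subset of exactly ``n`` records,
    drawn without replacement and re-sorted.

    Depth matching in comparative analyses always down-samples to the
    smallest library; asking for more records than exist is an error.
    """
    if n > len(records):
        raise ValueError(f"cannot down-sample {len(records)} records to {n}")
    rng = stream_rng(seed, STREAM_DOWNSAMPLE)
    idx = rng.choice(len(records), size=n, replace=False)
    return sort_records([records[i] for i in idx])


def summarize_library(records: Sequence[AlignmentRecord],
                      model: GenomeModel) -> LibrarySummary:
    """Totals, clonal rate and mitochondrial read fraction of a library."""
    total = len(records)
    if total == 0:
        return LibrarySummary(0, 0, 0.0, 0.0)
    unique = len({r.key for r in records})
    mito = 0
    if model.mito_contig is not None:
        mito = sum(1 for r in records if r.contig == model.mito_contig)
    return LibrarySummary(
        total_reads=total,
        unique_alignments=unique,
        clonal_rate=1.0 - unique / total,
        mito_fraction=mito / total,
    )


def bin_coverage(records: Sequence[AlignmentRecord], bin_size: int,
                 model: GenomeModel) -> list[CoverageTrack]:
    """Count read starts in fixed bins; every contig of the model gets a
    track and per-contig counts are conserved."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    tracks = []
    by_contig: dict[str, list[int]] = {name: [] for name, _ in model.contigs}
    for r in records:
        by_contig[r.contig].append(r.position)
    for name, length in model.contigs:
        n_bins = -(-length // bin_size)
        counts = np.zeros(n_bins, dtype=np.int64)
        positions = np.asarray(by_contig[name], dtype=np.int64)
        if positions.size:
            np.add.at(counts, positions // bin_size, 1)
        tracks.append(CoverageTrack(name, bin_size, counts))
    return tracks


# --- I/O boundary -----------------------------------------------------------

def write_sam(records: Sequence[AlignmentRecord], model: GenomeModel, path,
              read_length: int = 50) -> None:
    """Write minimal single-end SAM: flag carries the strand, CIGAR is
    ``<read_length>M``, the duplicate group rides in the ``DG`` tag."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in model.contigs],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, r in enumerate(records):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"read{i}"
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_name = r.contig
            seg.reference_start = r.position
            seg.mapping_quality = 60
            seg.cigarstring = f"{read_length}M"
            if r.duplicate_group is not None:
                seg.set_tag("DG", int(r.duplicate_group))
            out.write(seg)


def read_sam(path) -> list[AlignmentRecord]:
    """Read single-end SAM back to alignment records (unmapped reads are
    skipped); the ``DG`` tag restores the duplicate group when present."""
    records = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            group = seg.get_tag("DG") if seg.has_tag("DG") else None
            records.append(AlignmentRecord(
                contig=seg.reference_name,
                position=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                duplicate_group=group,
            ))
    return records


def write_tsv(reads: Sequence, path) -> None:
    """Write the 5-column dialect: contig, start, strand, duplicate_group,
    cell.  Accepts captured reads or alignment records (cell written as -1
    when absent)."""
    with open(path, "w") as fh:
        for r in reads:
            group = getattr(r, "duplicate_group", None)
            cell = getattr(r, "source_cell", -1)
            fh.write(f"{r.contig}\t{r.position}\t{r.strand}\t"
                     f"{-1 if group is None else group}\t{cell}\n")


def read_tsv(path) -> list[AlignmentRecord]:
    """Read the 5-column dialect into alignment records."""
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{line_no}: expected 5 columns")
            group = int(fields[3])
            records.append(AlignmentRecord(fields[0], int(fields[1]), fields[2],
                                           None if group < 0 else group))
    return records


def write_wig(tracks: Sequence[CoverageTrack], path) -> None:
    """Export coverage as fixedStep wiggle for genome-browser inspection."""
    with open(path, "w") as fh:
        for track in tracks:
            fh.write(f"fixedStep chrom={track.contig} start=1 "
                     f"step={track.bin_size} span={track.bin_size}\n")
            fh.write("\n".join(str(int(c)) for c in track.counts))
            fh.write("\n")
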