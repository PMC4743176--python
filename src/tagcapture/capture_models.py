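"""Capture of insertion events as sequencing reads under two assay models.

THS model (transposome hypersensitive sites sequencing): tagmentation cuts
the molecule at every insertion; a T7 promoter is attached to every cut end,
so each cut offers two runoff templates (one per flank, transcribing away
from the cut until the neighbouring cut or the molecule end).  A template is
captured when its runoff length falls in a window (nominally 400-2,000 bp,
collapsing in vitro transcription and second-round tagmentation into a
single length filter), and linear amplification emits a fixed number of
duplicate copies per template.  Transposon orientation never gates capture.

ATAC model: the fragment between two adjacent insertions on a molecule is
PCR-amplifiable only when (a) its two flanking adaptors form the
heteroadapter configuration — with independent random orientations this
happens for half of the fragments — and (b) the fragment length falls in the
PCR/size-selection window (nominally 200-800 bp).  Molecule ends never form
fragments.  PCR duplicates follow a geometric law.

The orientation bookkeeping follows tandem Tn5 chemistry: each insertion
deposits one adaptor species on its left flank and the other on its right,
so the fragment between two insertions carries two different adaptors
exactly when the two transposons inserted in the *same* orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tagcapture.alignment_processing import AlignmentRecord
from tagcapture.synthetic_data import GenomeModel, InsertionEvent, stream_rng, STREAM_PCR

_THS_EFFICIENCY_STREAM = 5


@dataclass(frozen=True)
class CaptureParams:
    """Assay-level capture parameters.

    amp_factor
        Number of linear-amplification copies per captured THS template
        (nominally ~1,000-fold in vitro transcription).  Duplicates collapse
        to one record at clonal removal, so analyses that only use unique
        alignments may run with a small value.
    ths_min_template, ths_max_template
        Runoff-length capture window for THS templates, bp.  The default
        upper bound is ``None`` (no gate): linear amplification captures an
        insertion end regardless of the distance to the adjacent insertion,
        and templates observed at 400-2,000+ bp reflect a ~400 bp lower
        bound with long runoffs fragmented downstream rather than lost.
    atac_min_frag, atac_max_frag
        Amplifiable fragment-length window for ATAC, bp; ``None`` disables
        the corresponding bound.
    ths_end_efficiency
        Per-end probability that a THS flank yields a usable template
        (default 1: every insertion end usable).
    pcr_mean_copies
        Mean of the geometric PCR duplicate law for ATAC fragments.
    """

    assay: str  # 'THS' | 'ATAC'
    amp_factor: int = 1000
    ths_min_template: int = 400
    ths_max_template: int | None = None
    atac_min_frag: int | None = 200
    atac_max_frag: int | None = 800
    read_length: int = 50
    ths_end_efficiency: float = 1.0
    pcr_mean_copies: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ("THS", "ATAC"):
            raise ValueError("assay must be 'THS' or 'ATAC'")
        if self.amp_factor < 1:
            raise ValueError("amp_factor must be >= 1")
        ths_hi = self.ths_max_template if self.ths_max_template is not None else np.inf
        if self.ths_min_template >= ths_hi:
            raise ValueError("THS template window must have min < max")
        lo = self.atac_min_frag if self.atac_min_frag is not None else 0
        hi = self.atac_max_frag if self.atac_max_frag is not None else np.inf
        if lo >= hi:
            raise ValueError("ATAC fragment window must have min < max")
        if not (0.0 <= self.ths_end_efficiency <= 1.0):
            raise ValueError("ths_end_efficiency must be in [0, 1]")
        if self.pcr_mean_copies < 1:
            raise ValueError("pcr_mean_copies must be >= 1")


@dataclass(frozen=True)
class CapturedRead:
    """A sequenced read; all amplification copies of one molecular end share
    one ``duplicate_group`` and hence one (contig, position, strand) key."""

    contig: str
    position: int
    strand: str  # '+' | '-'
    duplicate_group: int
    source_cell: int


def is_heteroadapter(orientation_a: str, orientation_b: str) -> bool:
    """Whether the fragment flanked by two insertions carries two different
    adaptor species (the PCR-amplifiable configuration).

    Under tandem insertion geometry this is the equal-orientation case, which
    has probability 1/2 for independent random orientations.
    """
    return orientation_a == orientation_b


def _event_arrays(events: Sequence[InsertionEvent]):
    """Decompose events into parallel arrays plus contiguous-run boundaries.

    A run is one (cell, molecule, contig) group; events must already be
    sorted by (cell, molecule, contig, position).
    """
    n = len(events)
    cells = np.fromiter((e.cell_id for e in events), dtype=np.int64, count=n)
    mols = np.fromiter((e.molecule_id for e in events), dtype=np.int64, count=n)
    pos = np.fromiter((e.position for e in events), dtype=np.int64, count=n)
    contigs = [e.contig for e in events]
    forward = np.fromiter((e.orientation == "forward" for e in events),
                          dtype=bool, count=n)
    same_run = np.zeros(n, dtype=bool)
    if n > 1:
        same_run[1:] = ((cells[1:] == cells[:-1]) & (mols[1:] == mols[:-1])
                        & np.fromiter((contigs[i] == contigs[i - 1] for i in range(1, n)),
                                      dtype=bool, count=n - 1))
    if n and not np.all(np.diff(pos)[same_run[1:]] >= 0):
        raise ValueError("events must be sorted by (cell, molecule, contig, position)")
    return cells, pos, contigs, forward, same_run


def ths_capture(events: Sequence[InsertionEvent], params: CaptureParams,
                model: GenomeModel) -> list[CapturedRead]:
    """Capture reads under the THS model.

    Every insertion cut offers two runoff templates; a template is captured
    iff its runoff length (distance to the neighbouring cut on the same
    molecule, or to the molecule end) lies in the THS window.  Each captured
    template emits ``amp_factor`` reads sharing one duplicate group.  The
    orientation field of the events never affects the result.
    """
    if params.assay != "THS":
        raise ValueError("ths_capture requires params.assay == 'THS'")
    if not events:
        return []
    lengths = model.contig_lengths
    cells, pos, contigs, _forward, same_run = _event_arrays(events)
    n = len(events)
    contig_len = np.fromiter((lengths[c] for c in contigs), dtype=np.int64, count=n)

    prev_gap = np.empty(n, dtype=np.int64)
    prev_gap[0] = pos[0]
    prev_gap[1:] = np.where(same_run[1:], pos[1:] - pos[:-1], pos[1:])
    next_gap = np.empty(n, dtype=np.int64)
    next_gap[:-1] = np.where(same_run[1:], pos[1:] - pos[:-1],
                             contig_len[:-1] - pos[:-1])
    next_gap[-1] = contig_len[-1] - pos[-1]

    lo = params.ths_min_template
    hi = params.ths_max_template
    left_ok = (prev_gap >= lo) if hi is None else (prev_gap >= lo) & (prev_gap <= hi)
    right_ok = (next_gap >= lo) if hi is None else (next_gap >= lo) & (next_gap <= hi)
    if params.ths_end_efficiency < 1.0:
        rng = stream_rng(params.seed, _THS_EFFICIENCY_STREAM)
        left_ok &= rng.random(n) < params.ths_end_efficiency
        right_ok &= rng.random(n) < params.ths_end_efficiency

    reads: list[CapturedRead] = []
    group = 0
    for strand, mask in (("-", left_ok), ("+", right_ok)):
        for i in np.flatnonzero(mask):
            i = int(i)
            reads.extend(CapturedRead(contigs[i], int(pos[i]), strand, group,
                                      int(cells[i]))
                         for _ in range(params.amp_factor))
            group += 1
    return reads


def atac_capture(events: Sequence[InsertionEvent], params: CaptureParams,
                 model: GenomeModel) -> list[CapturedRead]:
    """Capture reads under the ATAC model.

    Each pair of adjacent insertions on one molecule defines a candidate
    fragment, amplifiable iff the heteroadapter configuration holds (an
    orientation coincidence of probability 1/2) and the fragment length is
    in the size window.  Each amplifiable fragment emits two reads per PCR
    copy, one per end on opposite strands; each end forms one duplicate
    group.
    """
    if params.assay != "ATAC":
        raise ValueError("atac_capture requires params.assay == 'ATAC'")
    if not events:
        return []
    cells, pos, contigs, forward, same_run = _event_arrays(events)
    n = len(events)
    # candidate fragments: event i-1 .. event i within one run
    cand = np.flatnonzero(same_run[1:]) + 1
    if cand.size == 0:
        return []
    frag_len = pos[cand] - pos[cand - 1]
    hetero = forward[cand] == forward[cand - 1]
    ok = hetero
    if params.atac_min_frag is not None:
        ok = ok & (frag_len >= params.atac_min_frag)
    if params.atac_max_frag is not None:
        ok = ok & (frag_len <= params.atac_max_frag)
    keep = cand[ok]
    if keep.size == 0:
        return []
    rng = stream_rng(params.seed, STREAM_PCR)
    copies = rng.geometric(1.0 / params.pcr_mean_copies, size=keep.size)

    reads: list[CapturedRead] = []
    group = 0
    for j, i in enumerate(keep.tolist()):
        c = int(copies[j])
        left, right = int(pos[i - 1]), int(pos[i])
        cell = int(cells[i])
        reads.extend(CapturedRead(contigs[i], left, "+", group, cell)
                     for _ in range(c))
        reads.extend(CapturedRead(contigs[i], right, "-", group + 1, cell)
                     for _ in range(c))
        group += 2
    return reads


def candidate_fragments(events: Sequence[InsertionEvent]) -> np.ndarray:
    """Lengths of all adjacent-insertion fragments (no filters applied)."""
    if not events:
        return np.empty(0, dtype=np.int64)
    _, pos, _, _, same_run = _event_arrays(events)
    cand = np.flatnonzero(same_run[1:]) + 1
    return pos[cand] - pos[cand - 1]


def reads_to_alignments(reads: Sequence[CapturedRead]) -> list[AlignmentRecord]:
    """Losslessly convert captured reads to alignment records (perfect
    mapping assumed), sorted by (contig, position, strand)."""
    records = [AlignmentRecord(r.contig, r.position, r.strand, r.duplicate_group)
               for r in reads]
    records.sort(key=lambda r: (r.contig, r.position, r.strand))
    return records
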