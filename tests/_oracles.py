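"""Brute-force reference implementations used to check the fast paths.

Everything here works by exhaustive per-base or per-record enumeration and
is only meant for tiny instances (total span <= ~10 kb).
"""

from __future__ import annotations

import numpy as np

from tagcapture.peak_calling import Peak, PeakSet


def base_set(S: PeakSet) -> dict[str, set[int]]:
    """Every covered (contig, base) as explicit sets."""
    out: dict[str, set[int]] = {}
    for p in S:
        out.setdefault(p.contig, set()).update(range(p.start, p.end))
    return out


def bp_intersection_oracle(A: PeakSet, B: PeakSet) -> int:
    a, b = base_set(A), base_set(B)
    return sum(len(a[c] & b[c]) for c in a if c in b)


def per_peak_overlap_oracle(A: PeakSet, B: PeakSet) -> np.ndarray:
    b = base_set(B)
    return np.asarray([
        len(set(range(p.start, p.end)) & b.get(p.contig, set())) for p in A
    ])


def counts_in_peaks_oracle(records, S: PeakSet) -> list[int]:
    return [
        sum(1 for r in records
            if r.contig == p.contig and p.start <= r.position < p.end)
        for p in S
    ]


def threeway_oracle(count_set: PeakSet, first: PeakSet, second: PeakSet):
    """(with_both, with_first_only, with_second_only, with_neither)."""
    f, s = base_set(first), base_set(second)
    both = f_only = s_only = neither = 0
    for p in count_set:
        span = set(range(p.start, p.end))
        in_f = bool(span & f.get(p.contig, set()))
        in_s = bool(span & s.get(p.contig, set()))
        if in_f and in_s:
            both += 1
        elif in_f:
            f_only += 1
        elif in_s:
            s_only += 1
        else:
            neither += 1
    return both, f_only, s_only, neither


def nearest_tss_oracle(S: PeakSet, tss) -> list[int]:
    """Signed midpoint-to-nearest-TSS distances by exhaustive pairwise scan."""
    out = []
    for p in S:
        mid = (p.start + p.end) // 2
        best = None
        for contig, position, strand in tss:
            if contig != p.contig:
                continue
            d = mid - position if strand == "+" else position - mid
            if best is None or abs(d) < abs(best):
                best = d
        if best is not None:
            out.append(best)
    return out


def random_peakset(rng: np.random.Generator, name: str, span: int = 10_000,
                   max_peaks: int = 12, contigs=("chrA", "chrB")) -> PeakSet:
    """A random small peak set with total span <= ``span`` per contig."""
    peaks = []
    for contig in contigs:
        for _ in range(int(rng.integers(0, max_peaks + 1))):
            start = int(rng.integers(0, span - 2))
            end = int(rng.integers(start + 1, min(start + 1 + 800, span)))
            peaks.append(Peak(contig, start, end))
    return PeakSet(peaks, name=name)
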