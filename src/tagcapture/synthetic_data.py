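"""Synthetic genome landscapes and per-molecule Tn5 insertion simulation.

The simulator emulates the statistical structure that tagmentation-based
accessibility assays act on: a genome of which roughly 1 % is accessible,
Poisson transposition with an elevated rate inside open regions, a random
transposon orientation at every insertion, and an optional high-copy
mitochondrial contig that contributes background insertions in proportion
to its per-cell molecule count.

Coordinates are 0-based half-open throughout (BED convention); a cut site
is a single base-pair position.

Randomness: one global seed; every stochastic draw derives from it through
``numpy.random.SeedSequence(entropy=(seed, tag))`` where each consumer has a
fixed integer tag (landscape placement = 1, insertion simulation = 2, ATAC
PCR duplicates = 3, down-sampling = 4).  Modules can therefore be exercised
in isolation with reproducible streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

# fixed stream tags for the seed-splitting scheme
STREAM_LANDSCAPE = 1
STREAM_INSERTIONS = 2
STREAM_PCR = 3
STREAM_DOWNSAMPLE = 4


def stream_rng(seed: int, tag: int) -> np.random.Generator:
    """Return the generator for one named substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), int(tag))))


@dataclass(frozen=True)
class AccessibleRegion:
    """A nucleosome-depleted interval with an insertion-rate multiplier.

    ``weight`` scales the open-chromatin insertion rate for this region
    relative to other open regions (1.0 = the configured ``rate_open``).
    """

    contig: str
    start: int
    end: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")
        if self.weight <= 0:
            raise ValueError("region weight must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InsertionEvent:
    """One transposition on one chromosomal molecule of one cell.

    ``orientation`` is the direction of the transposon after insertion
    ('forward' or 'reverse'); it is marginally uniform because the Tn5
    transposome inserts its adaptors in random orientation.
    """

    cell_id: int
    molecule_id: int
    contig: str
    position: int
    orientation: str  # 'forward' | 'reverse'


@dataclass
class GenomeModel:
    """Ground-truth genome: contigs, accessible landscape, mito designation."""

    contigs: list[tuple[str, int]]
    accessible_regions: list[AccessibleRegion]
    mito_contig: str | None = None
    mito_copy_factor: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lengths = dict(self.contigs)
        if len(lengths) != len(self.contigs):
            raise ValueError("duplicate contig names")
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name} has non-positive length")
        if self.mito_contig is not None and self.mito_contig not in lengths:
            raise ValueError(f"mito contig {self.mito_contig!r} not in contigs")
        if self.mito_copy_factor <= 0:
            raise ValueError("mito_copy_factor must be positive")
        last: dict[str, int] = {}
        for region in self.accessible_regions:
            if region.contig not in lengths:
                raise ValueError(f"region on unknown contig {region.contig!r}")
            if region.end > lengths[region.contig]:
                raise ValueError("region extends past contig end")
            if region.start < last.get(region.contig, -1):
                raise ValueError("regions must be sorted and non-overlapping")
            last[region.contig] = region.end

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    @property
    def nuclear_contigs(self) -> list[tuple[str, int]]:
        return [(n, l) for n, l in self.contigs if n != self.mito_contig]

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.contigs)

    @property
    def accessible_bp(self) -> int:
        return sum(r.length for r in self.accessible_regions)

    def regions_on(self, contig: str) -> list[AccessibleRegion]:
        return [r for r in self.accessible_regions if r.contig == contig]


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Rates are insertions per base pair per chromosomal molecule.  The
    default landscape is a 2 Mb nuclear contig with ~1 % accessible
    chromatin in regions of 100-3,000 bp, plus a 16.6 kb mitochondrial
    contig present at ``mito_copy_factor`` copies per nuclear molecule.
    ``rate_open`` corresponds to a mean cut spacing of ~500 bp inside open
    chromatin, ``rate_closed`` is 100-fold lower.
    """

    seed: int = 0
    contigs: tuple[tuple[str, int], ...] = (("chr1", 2_000_000),)
    accessible_fraction: float = 0.01
    region_length_law: tuple[str, tuple[float, float]] = ("log_uniform", (100.0, 3000.0))
    rate_open: float = 2.0e-3
    rate_closed: float = 2.0e-5
    n_cells: int = 100
    molecules_per_cell: int = 2
    mito_contig: str | None = None
    mito_length: int = 16_569
    mito_copy_factor: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.accessible_fraction <= 1.0):
            raise ValueError("accessible_fraction must be in [0, 1]")
        if self.rate_open < 0 or self.rate_closed < 0:
            raise ValueError("rates must be non-negative")
        if self.rate_closed > self.rate_open:
            raise ValueError("rate_closed must not exceed rate_open")
        if self.n_cells < 1 or self.molecules_per_cell < 1:
            raise ValueError("n_cells and molecules_per_cell must be >= 1")
        law, params = self.region_length_law
        if law != "log_uniform":
            raise ValueError(f"unknown region length law {law!r}")
        lo, hi = params
        if not (0 < lo <= hi):
            raise ValueError("region length bounds must satisfy 0 < lo <= hi")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a config from a YAML key/value file (keys = field names)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contigs" in raw:
            raw["contigs"] = tuple((str(n), int(l)) for n, l in raw["contigs"])
        if "region_length_law" in raw:
            law, params = raw["region_length_law"]
            raw["region_length_law"] = (str(law), (float(params[0]), float(params[1])))
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "contigs": [list(c) for c in self.contigs],
            "accessible_fraction": self.accessible_fraction,
            "region_length_law": [self.region_length_law[0], list(self.region_length_law[1])],
            "rate_open": self.rate_open,
            "rate_closed": self.rate_closed,
            "n_cells": self.n_cells,
            "molecules_per_cell": self.molecules_per_cell,
            "mito_contig": self.mito_contig,
            "mito_length": self.mito_length,
            "mito_copy_factor": self.mito_copy_factor,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class ConfigurationError(ValueError):
    """Raised when a requested landscape cannot be realised."""


def _draw_region_lengths(rng: np.random.Generator, target_bp: float,
                         lo: float, hi: float) -> list[int]:
    """Draw log-uniform lengths until their sum approximates target_bp.

    The final draw is resized (within the [lo, hi] bounds) so the total
    lands on the target up to one minimum region length.
    """
    lengths: list[int] = []
    total = 0
    while total < target_bp:
        length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        length = max(int(lo), min(int(hi), length))
        lengths.append(length)
        total += length
    if lengths:
        last = lengths.pop()
        base = sum(lengths)
        options = [base, base + last,
                   base + int(min(hi, max(lo, target_bp - base)))]
        best = min(options, key=lambda t: abs(t - target_bp))
        if best > base:
            lengths.append(best - base)
    return lengths


def generate_landscape(config: SimConfig) -> GenomeModel:
    """Place an accessible-chromatin landscape on the configured genome.

    Region lengths are drawn from the configured bounded log-uniform law and
    placed uniformly at random on the nuclear contigs, rejecting overlaps,
    bookended adjacency and contig-edge truncation.  The realised accessible
    fraction is required to fall within 20 % (relative) of the request.
    Deterministic given ``config.seed``.
    """
    rng = stream_rng(config.seed, STREAM_LANDSCAPE)
    contigs = [(str(n), int(l)) for n, l in config.contigs]
    nuclear_bp = sum(l for _, l in contigs)
    target = config.accessible_fraction * nuclear_bp

    regions: list[AccessibleRegion] = []
    if target > 0:
        lo, hi = config.region_length_law[1]
        if target < lo / 2:
            raise ConfigurationError(
                f"accessible fraction {config.accessible_fraction} asks for "
                f"{target:.0f} bp, below the minimum region length {lo:.0f}")
        lengths = _draw_region_lengths(rng, target, lo, hi)
        if sum(lengths) > 0.5 * nuclear_bp:
            raise ConfigurationError(
                "requested accessible fraction too high to place without overlap")
        names = [n for n, _ in contigs]
        sizes = np.array([l for _, l in contigs], dtype=float)
        probs = sizes / sizes.sum()
        placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
        for length in sorted(lengths, reverse=True):  # place large regions first
            for _ in range(10_000):
                ci = int(rng.choice(len(names), p=probs))
                contig_len = int(sizes[ci])
                if contig_len < length + 2:
                    continue
                start = int(rng.integers(1, contig_len - length))  # avoid contig edges
                end = start + length
                # reject overlap or bookending with anything already placed
                ok = all(end < s or start > e for s, e in placed[names[ci]])
                if ok:
                    placed[names[ci]].append((start, end))
                    break
            else:
                raise ConfigurationError(
                    "could not place accessible regions without overlap")
        for name in names:
            for start, end in sorted(placed[name]):
                regions.append(AccessibleRegion(name, start, end))
        realised = sum(r.length for r in regions)
        if target > 0 and abs(realised - target) > 0.2 * target:
            raise ConfigurationError(
                f"realised accessible bp {realised} deviates more than 20 % "
                f"from the target {target:.0f}")

    mito = None
    if config.mito_contig is not None:
        mito = config.mito_contig
        contigs.append((mito, int(config.mito_length)))
    # order regions by contig appearance then start
    order = {n: i for i, (n, _) in enumerate(contigs)}
    regions.sort(key=lambda r: (order[r.contig], r.start))
    return GenomeModel(contigs=contigs, accessible_regions=regions,
                       mito_contig=mito, mito_copy_factor=config.mito_copy_factor)


def _segments_for_contig(model: GenomeModel, config: SimConfig,
                         contig: str, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (starts, rates) piecewise-constant segmentation of one contig.

    Segment boundaries are region starts/ends; the returned arrays give the
    start of each segment (last segment ends at the contig end) and its
    per-bp insertion rate.
    """
    bounds = [0]
    rates = []
    cursor = 0
    for region in model.regions_on(contig):
        if region.start > cursor:
            rates.append(config.rate_closed)
            bounds.append(region.start)
        rates.append(config.rate_open * region.weight)
        bounds.append(region.end)
        cursor = region.end
    rates.append(config.rate_closed)
    bounds.append(length)
    starts = np.asarray(bounds[:-1], dtype=np.int64)
    ends = np.asarray(bounds[1:], dtype=np.int64)
    keep = ends > starts
    return np.stack([starts[keep], ends[keep]]), np.asarray(rates)[keep]


def _simulate_block(rng: np.random.Generator, seg: np.ndarray, rates: np.ndarray,
                    n_molecules: int) -> tuple[np.ndarray, np.ndarray]:
    """Poisson counts then uniform positions for every (molecule, segment).

    Returns (molecule_index, position) arrays, unsorted.
    """
    starts, ends = seg
    lam = rates * (ends - starts)
    counts = rng.poisson(lam, size=(n_molecules, lam.size))
    n_total = int(counts.sum())
    if n_total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    flat = counts.ravel()
    seg_idx = np.repeat(np.tile(np.arange(lam.size), n_molecules), flat)
    mol_idx = np.repeat(np.repeat(np.arange(n_molecules), lam.size), flat)
    span = (ends - starts)[seg_idx]
    pos = starts[seg_idx] + np.floor(rng.random(n_total) * span).astype(np.int64)
    return mol_idx, pos


def simulate_insertions(model: GenomeModel, config: SimConfig) -> list[InsertionEvent]:
    """Simulate per-molecule Tn5 insertions over the whole genome.

    Within each chromosomal molecule, insertion counts on any interval follow
    a Poisson law with per-bp rate ``rate_closed`` outside accessible regions
    and ``rate_open * weight`` inside them.  The transposon orientation of
    each event is an independent fair draw.  The mitochondrial contig, if
    declared, is carried on ``round(molecules_per_cell * mito_copy_factor)``
    additional molecules per cell (elevated copy number, not elevated
    per-copy rate).  Events are returned sorted by
    (cell, molecule, contig, position).
    """
    model.validate()
    rng = stream_rng(config.seed, STREAM_INSERTIONS)
    lengths = model.contig_lengths
    contig_order = {name: i for i, (name, _) in enumerate(model.contigs)}

    rows: list[tuple[int, int, int, int, int]] = []  # cell, mol, contig_idx, pos, orient
    n_nuclear_mols = config.n_cells * config.molecules_per_cell
    for name, length in model.nuclear_contigs:
        seg, rates = _segments_for_contig(model, config, name, length)
        mol, pos = _simulate_block(rng, seg, rates, n_nuclear_mols)
        orient = rng.integers(0, 2, size=pos.size)
        cell = mol // config.molecules_per_cell
        mol_in_cell = mol % config.molecules_per_cell
        ci = contig_order[name]
        rows.extend(zip(cell.tolist(), mol_in_cell.tolist(),
                        [ci] * pos.size, pos.tolist(), orient.tolist()))

    if model.mito_contig is not None:
        mito_len = lengths[model.mito_contig]
        mito_per_cell = max(1, int(round(config.molecules_per_cell * model.mito_copy_factor)))
        n_mito_mols = config.n_cells * mito_per_cell
        seg = np.stack([np.array([0]), np.array([mito_len])])
        rates = np.array([config.rate_closed])
        mol, pos = _simulate_block(rng, seg, rates, n_mito_mols)
        orient = rng.integers(0, 2, size=pos.size)
        cell = mol // mito_per_cell
        # mito molecule ids live above the nuclear ids within each cell
        mol_in_cell = config.molecules_per_cell + (mol % mito_per_cell)
        ci = contig_order[model.mito_contig]
        rows.extend(zip(cell.tolist(), mol_in_cell.tolist(),
                        [ci] * pos.size, pos.tolist(), orient.tolist()))

    rows.sort()
    names = [name for name, _ in model.contigs]
    return [
        InsertionEvent(cell_id=c, molecule_id=m, contig=names[ci], position=p,
                       orientation="forward" if o == 0 else "reverse")
        for c, m, ci, p, o in rows
    ]


def export_truth(model: GenomeModel, path) -> None:
    """Write the accessible regions as a BED file (0-based, half-open)."""
    with open(path, "w") as fh:
        for region in model.accessible_regions:
            fh.write(f"{region.contig}\t{region.start}\t{region.end}\n")
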