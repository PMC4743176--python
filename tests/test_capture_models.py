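"""THS/ATAC capture mechanics against enumeration and binomial oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tagcapture as tc
from tagcapture.capture_models import candidate_fragments, is_heteroadapter
from tagcapture.synthetic_data import GenomeModel, InsertionEvent


def molecule(positions, orientations=None, contig="chr1", cell=0, mol=0):
    if orientations is None:
        orientations = ["forward"] * len(positions)
    return [InsertionEvent(cell, mol, contig, p, o)
            for p, o in zip(sorted(positions), orientations)]


def flank_lengths(positions, contig_len):
    """All 2k runoff templates of one molecule, by exhaustive enumeration."""
    pos = sorted(positions)
    out = []
    for i, p in enumerate(pos):
        out.append(p - (pos[i - 1] if i > 0 else 0))          # left flank
        out.append((pos[i + 1] if i + 1 < len(pos) else contig_len) - p)  # right
    return out


GENOME = GenomeModel(contigs=[("chr1", 1_000_000)], accessible_regions=[])


class TestTHSCapture:
    def test_no_insertions_no_reads(self):
        params = tc.CaptureParams(assay="THS")
        assert tc.ths_capture([], params, GENOME) == []

    def test_three_insertions_enumeration(self):
        """3 insertions 500 bp apart: captured templates equal the in-window
        flanks among all 6, enumerated exhaustively."""
        positions = [10_000, 10_500, 11_000]
        params = tc.CaptureParams(assay="THS", amp_factor=1,
                                  ths_min_template=400, ths_max_template=2000)
        reads = tc.ths_capture(molecule(positions), params, GENOME)
        expected = sum(400 <= f <= 2000 for f in flank_lengths(positions, 1_000_000))
        assert expected == 4
        assert len({r.duplicate_group for r in reads}) == expected

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 999_999), min_size=1, max_size=15, unique=True),
           st.integers(50, 1000), st.integers(1, 5000))
    def test_enumeration_oracle_random_molecules(self, positions, lo, extra):
        hi = lo + extra
        params = tc.CaptureParams(assay="THS", amp_factor=1,
                                  ths_min_template=lo, ths_max_template=hi)
        reads = tc.ths_capture(molecule(positions), params, GENOME)
        expected = sum(lo <= f <= hi for f in flank_lengths(positions, 1_000_000))
        assert len({r.duplicate_group for r in reads}) == expected
        assert len(reads) == expected  # amp_factor 1

    def test_amp_factor_copies_one_group(self):
        """One captured template amplified 1,000-fold: 1,000 reads, 1 group."""
        params = tc.CaptureParams(assay="THS", amp_factor=1000,
                                  ths_min_template=400, ths_max_template=2000)
        reads = tc.ths_capture(molecule([450]), params, GENOME)
        assert len(reads) == 1000
        assert len({r.duplicate_group for r in reads}) == 1
        assert len({(r.contig, r.position, r.strand) for r in reads}) == 1

    def test_orientation_never_gates_capture(self, tiny_events, tiny_model):
        """Flipping every orientation leaves THS output exactly invariant."""
        params = tc.CaptureParams(assay="THS", amp_factor=1)
        flipped = [InsertionEvent(e.cell_id, e.molecule_id, e.contig, e.position,
                                  "reverse" if e.orientation == "forward" else "forward")
                   for e in tiny_events]
        assert tc.ths_capture(tiny_events, params, tiny_model) == \
               tc.ths_capture(flipped, params, tiny_model)

    def test_unbounded_window_captures_every_long_runoff(self):
        """With no upper template bound, an isolated insertion's two long
        runoffs are both captured (every insertion end usable)."""
        params = tc.CaptureParams(assay="THS", amp_factor=1, ths_min_template=400)
        reads = tc.ths_capture(molecule([500_000]), params, GENOME)
        assert len(reads) == 2
        assert {r.strand for r in reads} == {"+", "-"}

    def test_assay_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tc.ths_capture([], tc.CaptureParams(assay="ATAC"), GENOME)


class TestATACCapture:
    def test_single_insertion_no_fragment(self):
        params = tc.CaptureParams(assay="ATAC")
        assert tc.atac_capture(molecule([5_000]), params, GENOME) == []

    def test_amplifiable_fraction_is_half(self):
        """>= 100,000 adjacent pairs with random orientations and the size
        filter disabled: amplifiable fraction 0.5 within 3 binomial SE."""
        rng = np.random.default_rng(42)
        n = 100_001
        positions = np.sort(rng.choice(50_000_000, size=n, replace=False))
        orients = ["forward" if b else "reverse" for b in rng.integers(0, 2, n)]
        events = [InsertionEvent(0, 0, "chr1", int(p), o)
                  for p, o in zip(positions, orients)]
        model = GenomeModel(contigs=[("chr1", 50_000_000)], accessible_regions=[])
        params = tc.CaptureParams(assay="ATAC", atac_min_frag=None,
                                  atac_max_frag=None, pcr_mean_copies=1.0)
        reads = tc.atac_capture(events, params, model)
        fragments = len({r.duplicate_group for r in reads}) / 2
        pairs = n - 1
        se = 0.5 / math.sqrt(pairs)
        assert abs(fragments / pairs - 0.5) <= 3 * se

    def test_spacing_filter_rejects_distant_pair(self):
        """Heteroadapter pair 1,000 bp apart with a 200-800 window: nothing."""
        params = tc.CaptureParams(assay="ATAC", atac_min_frag=200, atac_max_frag=800)
        events = molecule([10_000, 11_000], ["forward", "forward"])
        assert is_heteroadapter("forward", "forward")
        assert tc.atac_capture(events, params, GENOME) == []

    def test_homoadapter_pair_rejected_regardless_of_length(self):
        params = tc.CaptureParams(assay="ATAC", atac_min_frag=None, atac_max_frag=None)
        events = molecule([10_000, 10_500], ["forward", "reverse"])
        assert tc.atac_capture(events, params, GENOME) == []

    def test_fragment_emits_two_ends_opposite_strands(self):
        params = tc.CaptureParams(assay="ATAC", atac_min_frag=200,
                                  atac_max_frag=800, pcr_mean_copies=1.0)
        reads = tc.atac_capture(molecule([10_000, 10_500]), params, GENOME)
        assert {(r.position, r.strand) for r in reads} == \
               {(10_000, "+"), (10_500, "-")}
        assert len({r.duplicate_group for r in reads}) == 2

    def test_molecule_ends_never_form_fragments(self):
        # two insertions on different molecules: no adjacent pair
        events = molecule([10_000], mol=0) + molecule([10_500], mol=1)
        events.sort(key=lambda e: (e.cell_id, e.molecule_id, e.contig, e.position))
        params = tc.CaptureParams(assay="ATAC", atac_min_frag=None, atac_max_frag=None)
        assert tc.atac_capture(events, params, GENOME) == []

    def test_ths_templates_cover_atac_fragment_ends(self, tiny_events, tiny_model):
        """When the THS window contains the ATAC window, every amplifiable
        fragment's two ends are also captured THS flanks, so distinct THS
        groups >= 2x distinct ATAC fragments."""
        ths = tc.ths_capture(
            tiny_events,
            tc.CaptureParams(assay="THS", amp_factor=1, ths_min_template=200),
            tiny_model)
        atac = tc.atac_capture(
            tiny_events,
            tc.CaptureParams(assay="ATAC", atac_min_frag=200, atac_max_frag=800,
                             pcr_mean_copies=1.0),
            tiny_model)
        ths_groups = len({r.duplicate_group for r in ths})
        atac_fragments = len({r.duplicate_group for r in atac}) / 2
        assert ths_groups >= 2 * atac_fragments

    def test_candidate_fragments_match_adjacent_gaps(self):
        events = molecule([100, 350, 900, 2_000])
        assert candidate_fragments(events).tolist() == [250, 550, 1100]


class TestReadsToAlignments:
    def test_empty(self):
        assert tc.reads_to_alignments([]) == []

    def test_conservation_and_order(self, tiny_events, tiny_model):
        reads = tc.ths_capture(tiny_events, tc.CaptureParams(assay="THS", amp_factor=2),
                               tiny_model)
        records = tc.reads_to_alignments(reads)
        assert len(records) == len(reads)
        keys = [r.key for r in records]
        assert keys == sorted(keys)

    def test_sam_roundtrip_identity(self, tiny_events, tiny_model, tmp_path):
        from tagcapture.alignment_processing import read_sam, write_sam
        reads = tc.ths_capture(tiny_events, tc.CaptureParams(assay="THS", amp_factor=1),
                               tiny_model)
        records = tc.reads_to_alignments(reads)
        path = tmp_path / "reads.sam"
        write_sam(records, tiny_model, path)
        assert read_sam(path) == records
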