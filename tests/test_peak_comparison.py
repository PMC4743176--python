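"""Peak-set comparison statistics against per-base brute-force oracles."""

import numpy as np
import pytest

import tagcapture as tc
from tagcapture.peak_calling import Peak, PeakSet
from tagcapture.peak_comparison import per_peak_overlap

from _oracles import (
    bp_intersection_oracle,
    nearest_tss_oracle,
    per_peak_overlap_oracle,
    random_peakset,
    threeway_oracle,
)


def peakset(*intervals, name="S"):
    return PeakSet([Peak(*iv) for iv in intervals], name=name)


class TestBasepairOverlap:
    def test_identity(self):
        A = peakset(("chr1", 0, 100), ("chr1", 200, 500))
        summary = tc.basepair_overlap(A, A)
        assert summary.frac_A_covered == 1.0
        assert summary.bp_intersection == A.total_bp

    def test_disjoint(self):
        A = peakset(("chr1", 0, 100))
        B = peakset(("chr1", 200, 300))
        assert tc.basepair_overlap(A, B).bp_intersection == 0

    def test_partial_overlap_arithmetic(self):
        A = peakset(("chr1", 0, 100))
        B = peakset(("chr1", 50, 150))
        summary = tc.basepair_overlap(A, B)
        assert summary.bp_intersection == 50
        assert summary.bp_intersection == bp_intersection_oracle(A, B)
        assert summary.frac_A_covered == pytest.approx(0.5)

    def test_symmetry_random(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            A = random_peakset(rng, "A")
            B = random_peakset(rng, "B")
            ab = tc.basepair_overlap(A, B).bp_intersection
            ba = tc.basepair_overlap(B, A).bp_intersection
            assert ab == ba == bp_intersection_oracle(A, B)

    def test_adding_peak_never_decreases_overlap(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            A = random_peakset(rng, "A")
            B = random_peakset(rng, "B")
            extra = random_peakset(rng, "x", max_peaks=1)
            bigger = PeakSet(list(B) + list(extra), name="B+")
            assert tc.basepair_overlap(A, bigger).bp_intersection >= \
                   tc.basepair_overlap(A, B).bp_intersection
            assert tc.peak_sharing(A, bigger)[0] >= tc.peak_sharing(A, B)[0]


class TestPeakSharing:
    def test_single_bp_counts_as_shared(self):
        A = peakset(("chr1", 0, 100))
        B = peakset(("chr1", 99, 200))
        assert tc.peak_sharing(A, B) == (1, 1)

    def test_bookended_not_shared(self):
        A = peakset(("chr1", 0, 100))
        B = peakset(("chr1", 100, 200))
        assert tc.peak_sharing(A, B) == (0, 0)

    def test_identical_sets_all_shared(self):
        A = peakset(("chr1", 0, 100), ("chr2", 0, 50))
        assert tc.peak_sharing(A, A) == (2, 2)

    def test_counted_once_despite_multiple_touches(self):
        A = peakset(("chr1", 0, 1000))
        B = peakset(("chr1", 10, 20), ("chr1", 500, 600))
        assert tc.peak_sharing(A, B) == (1, 2)


class TestSizeDistribution:
    def test_forced_binning(self):
        S = peakset(("chr1", 0, 100), ("chr1", 200, 450), ("chr2", 0, 250),
                    ("chr2", 1000, 4000))
        rows = tc.size_distribution(S, 100).rows
        assert dict(zip(rows.length_bin, rows.peak_count)) == {100: 1, 300: 2, 3000: 1}

    def test_empty_set(self):
        assert len(tc.size_distribution(peakset(), 100).rows) == 0

    def test_counts_conserved_random(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            S = random_peakset(rng, "S")
            rows = tc.size_distribution(S, 100).rows
            assert rows.peak_count.sum() == len(S)
            assert rows.bp_in_bin.sum() == S.total_bp


class TestLengthStratifiedOverlap:
    def test_identity_is_100_everywhere(self):
        S = peakset(("chr1", 0, 150), ("chr1", 300, 1000))
        table = tc.length_stratified_overlap(S, S, 100).rows
        assert (table.overlap_pct == 100.0).all()
        assert (table.normalized_overlap_pct == 100.0).all()

    def test_normalization_arithmetic(self):
        # bin overlap 30 % with global 60 % -> normalized 50 %
        S = peakset(("chr1", 0, 100))
        ref = peakset(("chr1", 0, 30))
        table = tc.length_stratified_overlap(S, ref, 100, global_overlap_pct=60.0).rows
        assert table.overlap_pct.iloc[0] == pytest.approx(30.0)
        assert table.normalized_overlap_pct.iloc[0] == pytest.approx(50.0)

    def test_per_bin_totals_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            S = random_peakset(rng, "S")
            ref = random_peakset(rng, "ref")
            if len(S) == 0 or S.total_bp == 0:
                continue
            ov = per_peak_overlap(S, ref)
            if ov.sum() == 0:
                continue
            table = tc.length_stratified_overlap(S, ref, 100).rows
            expected = per_peak_overlap_oracle(S, ref)
            lengths = np.array([p.length for p in S])
            bins = np.ceil(lengths / 100).astype(int) * 100
            for _, row in table.iterrows():
                mask = bins == row.length_bin
                assert row.bp_overlap_with_reference == expected[mask].sum()
            # conservation: per-bin overlap sums to the global intersection
            assert table.bp_overlap_with_reference.sum() == \
                   tc.basepair_overlap(S, ref).bp_intersection

    def test_empty_bins_absent_not_zero(self):
        S = peakset(("chr1", 0, 100), ("chr1", 200, 3200))
        table = tc.length_stratified_overlap(S, S, 100).rows
        assert set(table.length_bin) == {100, 3000}


class TestPctMorePeaks:
    def test_sixty_percent_more(self):
        S = peakset(*[("chr1", i * 200, i * 200 + 50) for i in range(160)])
        other = peakset(*[("chr2", i * 200, i * 200 + 50) for i in range(100)])
        rows = tc.pct_more_peaks(S, other, 100).rows
        assert rows.pct_more_peaks.iloc[0] == pytest.approx(60.0)

    def test_equal_counts_zero(self):
        S = peakset(("chr1", 0, 80))
        other = peakset(("chr2", 0, 80))
        assert tc.pct_more_peaks(S, other, 100).rows.pct_more_peaks.iloc[0] == 0.0

    def test_zero_denominator_undefined(self):
        S = peakset(("chr1", 0, 80))
        other = peakset(("chr2", 0, 500))
        rows = tc.pct_more_peaks(S, other, 100).rows.set_index("length_bin")
        assert np.isnan(rows.loc[100, "pct_more_peaks"])


class TestThreewaySharing:
    def test_all_identical(self):
        A = peakset(("chr1", 0, 100), ("chr1", 200, 300))
        result = tc.threeway_sharing(A, A, A, counting="A")
        assert result.with_both == 2 and result.total == 2

    def test_third_set_disjoint(self):
        A = peakset(("chr1", 0, 100))
        C = peakset(("chr2", 0, 100))
        result = tc.threeway_sharing(A, A, C, counting="A")
        assert (result.with_first_only, result.with_both) == (1, 0)

    def test_classes_partition_counting_set_random(self):
        rng = np.random.default_rng(18)
        for _ in range(15):
            A, B, C = (random_peakset(rng, n) for n in "ABC")
            result = tc.threeway_sharing(A, B, C, counting="A")
            assert result.total == len(A)
            assert (result.with_both, result.with_first_only,
                    result.with_second_only, result.with_neither) == \
                   threeway_oracle(A, B, C)


class TestTssDistance:
    TSS = [("chr1", 1_000, "+"), ("chr1", 50_000, "-"), ("chr2", 500, "+")]

    def test_midpoint_at_tss_distance_zero(self):
        S = peakset(("chr1", 950, 1050))  # midpoint exactly 1000
        table = tc.tss_distance_distribution(S, self.TSS)
        row = table[(table.bin_low == 0)]
        assert row["count"].iloc[0] == 1

    def test_downstream_of_plus_strand_positive(self):
        S = peakset(("chr1", 1_450, 1_550))  # midpoint 1500, +500 of TSS@1000
        assert nearest_tss_oracle(S, self.TSS) == [500]

    def test_upstream_respects_strand(self):
        # midpoint 50_500 is 500 bp right of a minus-strand TSS: upstream
        S = peakset(("chr1", 50_450, 50_550))
        assert nearest_tss_oracle(S, self.TSS) == [-500]

    def test_binned_counts_match_pairwise_oracle(self):
        rng = np.random.default_rng(19)
        tss = [("chrA", int(p), str(s)) for p, s in
               zip(rng.integers(0, 10_000, 8), rng.choice(["+", "-"], 8))]
        for _ in range(10):
            S = random_peakset(rng, "S", contigs=("chrA",))
            if len(S) == 0:
                continue
            table = tc.tss_distance_distribution(S, tss, bin_edges=(-1000, -100, 0, 100, 1000))
            expected = np.histogram(
                nearest_tss_oracle(S, tss),
                bins=[-np.inf, -1000, -100, 0, 100, 1000, np.inf])[0]
            assert table["count"].tolist() == expected.tolist()

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            tc.tss_distance_distribution(peakset(("chr1", 0, 10)), [])
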