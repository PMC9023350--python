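"""Junction counting, the processing ratio and direction inference."""

import math

import numpy as np
import pytest

from cotxmir.annotation import derive_cleavage_map
from cotxmir.coverage import CoverageTrack
from cotxmir.processing import (
    ProcessingRatioRecord,
    compare_conditions,
    count_ends_at,
    count_spanning,
    infer_direction,
    processing_ratio,
    score_matrix,
)
from cotxmir.simulate import SimConfig, expected_counts, simulate_netseq

from conftest import brute_force_counts, make_locus

TOY = [(90, 100), (80, 100), (95, 120)]


class TestCounting:
    def test_ends_at_counts_three_prime_base(self):
        assert count_ends_at(TOY, 100) == 2

    def test_empty_read_set(self):
        assert count_ends_at([], 100) == 0
        assert count_spanning([], 100) == 0

    def test_spanning_requires_both_adjacent_bases(self):
        assert count_spanning(TOY, 100) == 1  # only [95, 120)

    def test_minimal_spanning_read(self):
        assert count_spanning([(99, 101)], 100) == 1

    def test_exclusion_removes_junction_ending_reads_from_denominator(self):
        reads = [(95, 120), (90, 121)]  # second ends at junction 121
        assert count_spanning(reads, 100, exclude_ends_at=(121,)) == 1

    def test_matches_brute_force_on_random_reads(self):
        rng = np.random.default_rng(11)
        ts = rng.integers(0, 400, 1000)
        te = ts + rng.integers(20, 80, 1000)
        for j in (50, 150, 250, 380):
            bf_end, bf_span = brute_force_counts(ts, te, j)
            assert count_ends_at((ts, te), j) == bf_end
            assert count_spanning((ts, te), j) == bf_span


class TestProcessingRatio:
    def _cm(self, direction="BTL"):
        return derive_cleavage_map(make_locus(direction, hp_off=100, loop=29))

    def test_co_preference(self):
        reads = [(50, 100)] * 2 + [(80, 130)]
        rec = processing_ratio(reads, self._cm(), min_reads=1)
        assert (rec.n_end_at_a, rec.n_span_a) == (2, 1)
        assert rec.ratio == pytest.approx(2.0)
        assert rec.preference == "co"

    def test_equal_band(self):
        reads = [(50, 100), (80, 130)]
        rec = processing_ratio(reads, self._cm(), min_reads=1)
        assert rec.ratio == pytest.approx(1.0)
        assert rec.preference == "equal"

    def test_min_reads_gives_undetermined(self):
        reads = [(50, 100), (80, 130)]
        rec = processing_ratio(reads, self._cm(), min_reads=10)
        assert rec.preference == "undetermined"
        assert math.isnan(rec.ratio)

    def test_no_spanning_reads_is_infinite_co(self):
        reads = [(50, 100)] * 12
        rec = processing_ratio(reads, self._cm(), min_reads=10)
        assert math.isinf(rec.ratio)
        assert rec.preference == "co"

    def test_invariant_under_read_duplication(self):
        rng = np.random.default_rng(4)
        ts = rng.integers(0, 200, 500)
        te = ts + rng.integers(20, 80, 500)
        reads = list(zip(ts.tolist(), te.tolist()))
        one = processing_ratio(reads, self._cm(), min_reads=1)
        two = processing_ratio(reads + reads, self._cm(), min_reads=1)
        assert two.n_end_at_a == 2 * one.n_end_at_a
        assert two.n_span_a == 2 * one.n_span_a
        if math.isfinite(one.ratio):
            assert two.ratio == pytest.approx(one.ratio)

    def test_ltype_denominator_excludes_intermediates(self):
        cm = self._cm("LTB")  # junctions at 121 (site a) and 100
        spanning = [(80, 160)]
        intermediate = [(80, 171)]  # ends at mature_3p_end junction
        rec = processing_ratio(spanning + intermediate, cm, min_reads=1)
        assert rec.n_span_a == 1

    def test_expected_ratio_increases_with_p_co(self):
        locus = make_locus("BTL")
        cm = derive_cleavage_map(locus)
        ratios = [
            expected_counts(locus, cm, SimConfig(p_co=p)).ratio
            for p in np.linspace(0.05, 0.95, 10)
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))


class TestCompareConditions:
    @pytest.mark.parametrize(
        "ctrl,treat,expected",
        [(1.0, 1.6, "up"), (1.0, 1.4, "unchanged"), (2.0, 0.9, "down")],
    )
    def test_half_threshold(self, ctrl, treat, expected):
        rc = [ProcessingRatioRecord("x", 100, 10, 10, ctrl, "equal")]
        rt = [ProcessingRatioRecord("x", 100, 10, 10, treat, "equal")]
        (delta,) = compare_conditions(rc, rt)
        assert delta.changed == expected

    def test_undefined_ratio_reported_not_classified(self):
        rc = [ProcessingRatioRecord("x", 100, 0, 0, math.nan, "undetermined")]
        rt = [ProcessingRatioRecord("x", 100, 10, 5, 2.0, "co")]
        (delta,) = compare_conditions(rc, rt)
        assert delta.changed == "undetermined"


class TestScoreMatrix:
    def test_constant_and_zero_tracks(self):
        locus = make_locus("BTL")
        const = CoverageTrack("whole", "+")
        for t in range(0, locus.transcript_length):
            const.add(locus.chrom, locus.t2g(t), 7)
        zero = CoverageTrack("whole", "+")
        scores = score_matrix({"c": const, "z": zero}, [(locus, (100, 200))])
        assert scores.loc[locus.locus_id, "c"] == pytest.approx(7.0)
        assert scores.loc[locus.locus_id, "z"] == 0.0

    def test_random_track_matches_brute_force(self):
        rng = np.random.default_rng(8)
        locus = make_locus("BTL")
        track = CoverageTrack("whole", "+")
        for pos in rng.integers(locus.tss, locus.tss + 500, 2000):
            track.add("chr1", int(pos))
        window = (30, 400)
        brute = np.mean([track.get("chr1", locus.t2g(t)) for t in range(*window)])
        scores = score_matrix({"t": track}, [(locus, window)])
        assert scores.loc[locus.locus_id, "t"] == pytest.approx(brute)


class TestInferDirection:
    def _values(self, locus, peaks):
        arr = np.zeros(locus.transcript_length)
        for pos, height in peaks.items():
            arr[pos] = height
        return arr

    def test_basal_peak_with_retention_is_btl(self):
        locus = make_locus("BTL")
        m5s, _ = locus.mir5p_t
        _, m3e = locus.mir3p_t
        call = infer_direction(self._values(locus, {m5s - 1: 40, m3e - 1: 12}), locus)
        assert call.direction == "BTL"
        assert call.retention

    def test_loop_sequence_is_ltbs(self):
        locus = make_locus("LTBs", loop=120)
        _, m5e = locus.mir5p_t
        peaks = {m5e - 1: 30, m5e - 1 + 21: 25, m5e - 1 + 42: 20}
        call = infer_direction(self._values(locus, peaks), locus)
        assert call.direction == "LTBs"

    def test_sub_basal_peak_is_btls(self):
        locus = make_locus("BTLs")
        m5s, _ = locus.mir5p_t
        call = infer_direction(self._values(locus, {m5s - 1 - 21: 30}), locus)
        assert call.direction == "BTLs"

    def test_conflicting_evidence_is_undefined(self):
        locus = make_locus("BTL", loop=120)
        m5s, m5e = locus.mir5p_t
        peaks = {m5e - 1: 30, m5s - 1 - 21: 30}
        call = infer_direction(self._values(locus, peaks), locus)
        assert call.direction == "UNDEFINED"
        assert call.evidence["loop"]["peak"] and call.evidence["sequential_basal"]

    def test_flat_signal_is_undefined(self):
        locus = make_locus("BTL")
        call = infer_direction(np.ones(locus.transcript_length), locus)
        assert call.direction == "UNDEFINED"

    @pytest.mark.parametrize("direction", ["BTL", "LTB", "BTLs", "LTBs"])
    def test_simulated_recovery_per_direction(self, direction):
        rng = np.random.default_rng(17)
        hits = 0
        n_loci = 15
        for i in range(n_loci):
            locus = make_locus(direction, locus_id=f"s{i}", loop=int(rng.integers(80, 140)),
                               hp_off=int(rng.integers(150, 350)))
            cm = derive_cleavage_map(locus)
            reads, _ = simulate_netseq(locus, cm, SimConfig(n_molecules=3000, p_co=0.5), rng=rng)
            call = infer_direction(reads.three_prime_values(), locus)
            hits += call.direction == direction
        assert hits >= n_loci - 1

    @pytest.mark.parametrize("direction", ["BTL", "LTB"])
    def test_no_false_sequential_calls_noiseless(self, direction):
        rng = np.random.default_rng(23)
        for i in range(10):
            locus = make_locus(direction, locus_id=f"n{i}", loop=int(rng.integers(80, 140)))
            cm = derive_cleavage_map(locus)
            cfg = SimConfig(n_molecules=3000, p_co=0.5, background_rate=0.0)
            reads, _ = simulate_netseq(locus, cm, cfg, rng=rng)
            call = infer_direction(reads.three_prime_values(), locus)
            assert call.direction == direction
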