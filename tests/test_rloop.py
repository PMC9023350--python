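"""R-loop window profiling, archetype classification and group comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from cotxmir.annotation import derive_cleavage_map, scaling_windows
from cotxmir.coverage import CoverageTrack
from cotxmir.processing import ProcessingRatioRecord
from cotxmir.rloop import (
    RCLASSES,
    classify_rloop,
    locus_report,
    ratio_by_class,
    strand_split_drip,
    track_background,
    window_means,
)
from cotxmir.simulate import SimConfig, simulate_drip, simulate_netseq

from conftest import make_locus


def constant_track(locus, value, lo=-400, hi=None):
    track = CoverageTrack("whole", "+")
    hi = hi if hi is not None else locus.transcript_length + 400
    for t in range(lo, hi):
        track.add(locus.chrom, locus.t2g(t), value)
    return track


class TestStrandSplit:
    def test_forward_signal_is_sense_for_plus_locus(self):
        plus = make_locus("BTL", "+")
        fwd, rev = CoverageTrack("whole", "+"), CoverageTrack("whole", "-")
        fwd.add("chr1", plus.tss + 5, 3.0)
        sense, antisense = strand_split_drip(fwd, rev, plus)
        assert sense is fwd and antisense is rev

    def test_flipping_locus_strand_swaps_labels(self):
        minus = make_locus("BTL", "-", tss=5000)
        fwd, rev = CoverageTrack("whole", "+"), CoverageTrack("whole", "-")
        sense, antisense = strand_split_drip(fwd, rev, minus)
        assert sense is rev and antisense is fwd


class TestWindowMeans:
    def test_signal_equal_to_background_gives_means_of_one(self):
        locus = make_locus("BTL")
        const = constant_track(locus, 3.0)
        rec = window_means(const, const, locus, background=(3.0, 3.0))
        assert all(v == pytest.approx(1.0) for v in rec.means.values())

    def test_zero_signal_gives_zero_means(self):
        locus = make_locus("BTL")
        zero = CoverageTrack("whole", "+")
        rec = window_means(zero, zero, locus, background=(1.0, 1.0))
        assert all(v == 0.0 for v in rec.means.values())

    def test_means_match_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(9)
        locus = make_locus("BTL")
        sense = CoverageTrack("whole", "+")
        anti = CoverageTrack("whole", "-")
        for t in rng.integers(-300, locus.transcript_length + 300, 4000):
            sense.add(locus.chrom, locus.t2g(int(t)), 1.0)
        for t in rng.integers(-300, locus.transcript_length + 300, 4000):
            anti.add(locus.chrom, locus.t2g(int(t)), 1.0)
        sw = scaling_windows(locus)
        rec = window_means(sense, anti, locus, sw, background=(2.0, 4.0))
        a, b = sw.tss_window
        brute = np.mean([sense.get(locus.chrom, locus.t2g(t)) for t in range(a, b)]) / 2.0
        assert rec.means[("tss", "sense")] == pytest.approx(brute)
        _, m3e = sw.hairpin_window
        T = locus.transcript_length
        brute_tail = np.mean([anti.get(locus.chrom, locus.t2g(t)) for t in range(m3e, T)]) / 4.0
        assert rec.means[("tail", "antisense")] == pytest.approx(brute_tail)


class TestClassify:
    def _record(self, locus, fwd, rev, bg=(1.0, 1.0)):
        sense, antisense = strand_split_drip(fwd, rev, locus)
        return window_means(sense, antisense, locus, background=bg)

    def test_all_zero_record_is_alpha(self):
        locus = make_locus("BTL")
        zero = CoverageTrack("whole", "+")
        rec = window_means(zero, zero, locus, background=(1.0, 1.0))
        assert classify_rloop(rec) == "alpha"

    def test_antisense_tss_bump_is_beta(self):
        locus = make_locus("BTL")
        anti = CoverageTrack("whole", "-")
        for t in range(0, locus.mir5p_t[0]):
            anti.add(locus.chrom, locus.t2g(t), 5.0)
        rec = window_means(CoverageTrack("whole", "+"), anti, locus, background=(1.0, 1.0))
        assert classify_rloop(rec) == "beta"

    def test_sense_plateau_over_locus_is_delta(self):
        locus = make_locus("BTL")
        sense = constant_track(locus, 5.0, lo=0, hi=locus.transcript_length)
        rec = window_means(sense, CoverageTrack("whole", "-"), locus, background=(1.0, 1.0))
        assert classify_rloop(rec) == "delta"

    def test_scale_invariance_is_exact(self):
        locus = make_locus("LTB")
        for rclass in RCLASSES:
            fwd, rev = simulate_drip(locus, rclass, snr=5.0, seed=31)
            base = self._record(locus, fwd, rev, bg=(track_background(fwd), track_background(rev)))
            c = 7.3
            fwd2, rev2 = fwd.copy(), rev.copy()
            for tr in (fwd2, rev2):
                for chrom in tr.data:
                    for pos in tr.data[chrom]:
                        tr.data[chrom][pos] *= c
            scaled = self._record(
                locus, fwd2, rev2, bg=(c * track_background(fwd), c * track_background(rev))
            )
            assert classify_rloop(base) == classify_rloop(scaled)
            for key in base.means:
                assert scaled.means[key] == pytest.approx(base.means[key], abs=1e-12)

    @pytest.mark.parametrize("rclass", RCLASSES)
    def test_noiseless_archetypes_classify_exactly(self, rclass):
        locus = make_locus("BTL")
        fwd, rev = simulate_drip(locus, rclass, snr=None, seed=0)
        rec = self._record(locus, fwd, rev, bg=(track_background(fwd), track_background(rev)))
        assert classify_rloop(rec) == rclass

    def test_every_record_gets_exactly_one_class(self):
        rng = np.random.default_rng(41)
        locus = make_locus("BTL")
        for i in range(25):
            rclass = RCLASSES[i % 5]
            fwd, rev = simulate_drip(locus, rclass, snr=2.0, seed=100 + i)
            rec = self._record(locus, fwd, rev, bg=(track_background(fwd), track_background(rev)))
            assert classify_rloop(rec) in RCLASSES
        _ = rng


class TestRatioByClass:
    def _records(self, classes):
        recs = []
        for i, rclass in enumerate(classes):
            r = __import__("cotxmir.rloop", fromlist=["RloopProfileRecord"]).RloopProfileRecord(
                locus_id=f"l{i}", means={}, body_profile={}, centroid={}, background=(1, 1)
            )
            r.rclass = rclass
            recs.append(r)
        return recs

    def _ratios(self, values):
        return [
            ProcessingRatioRecord(f"l{i}", 100, 10, 10, v, "equal") for i, v in enumerate(values)
        ]

    def test_single_element_group_gives_undefined_p(self):
        recs = self._records(["alpha", "beta", "beta", "beta"])
        ratios = self._ratios([1.0, 2.0, 2.1, 1.9])
        summary, tests = ratio_by_class(recs, ratios)
        row = tests[(tests.group_a == "alpha") & (tests.group_b == "beta+gamma")].iloc[0]
        assert math.isnan(row.p_value)
        assert summary.loc["alpha", "n_used"] == 1

    def test_known_shift_is_detected_with_high_power(self):
        """Welch t-test power at n=30/group, d=1 exceeds the closed-form
        normal-approximation bound (~0.97)."""
        rng = np.random.default_rng(5)
        n, d, reps = 30, 1.0, 300
        hits = 0
        for _ in range(reps):
            a = np.exp(rng.normal(0.0, 1.0, n))
            b = np.exp(rng.normal(d, 1.0, n))
            recs = self._records(["alpha"] * n + ["beta"] * n)
            ratios = self._ratios(np.concatenate([a, b]))
            _, tests = ratio_by_class(recs, ratios)
            p = tests[(tests.group_a == "alpha") & (tests.group_b == "beta+gamma")].p_value.iloc[0]
            hits += p < 0.05
        # closed-form power oracle: P(|Z| > z_{0.975} - d*sqrt(n/2))
        power = 1 - stats.norm.cdf(stats.norm.ppf(0.975) - d * math.sqrt(n / 2))
        assert hits / reps > 0.9
        assert hits / reps == pytest.approx(power, abs=0.06)


class TestLocusReport:
    def test_report_coordinates_match_junction_bed(self, tmp_path):
        from cotxmir.annotation import write_junction_bed

        locus = make_locus("LTB")
        cm = derive_cleavage_map(locus)
        reads, _ = simulate_netseq(locus, cm, SimConfig(seed=3, n_molecules=2000))
        from cotxmir.coverage import end_coverage

        net = end_coverage(reads.to_read_intervals(), "three_prime", locus.strand, max_len=500)
        fwd, rev = simulate_drip(locus, "beta", snr=5.0, seed=2)
        report = locus_report(locus, cm, net, fwd, rev)
        write_junction_bed([(locus, cm)], tmp_path / "j.bed")
        bed = {int(l.split("\t")[1]) for l in open(tmp_path / "j.bed")}
        report_j = set(report.loc[report.cut_index >= 0, "g_pos"].astype(int))
        assert report_j == bed

    def test_empty_tracks_give_empty_report(self):
        locus = make_locus("BTL")
        cm = derive_cleavage_map(locus)
        empty = CoverageTrack("three_prime", "+")
        report = locus_report(locus, cm, empty, CoverageTrack("whole", "+"), CoverageTrack("whole", "-"))
        assert len(report) == 0
        assert not report.attrs["co_processing_evidence"]

    def test_polycistron_flags_co_processing_only_at_5prime_hairpin(self):
        """A beta R-loop at the 5' hairpin with high p_co there and low p_co
        at the 3' hairpin: only the 5' member shows site-a evidence."""
        member1 = make_locus("BTL", locus_id="pc1", hp_off=220)
        member2 = make_locus("BTL", locus_id="pc2", hp_off=1200, tail=200)
        cm1, cm2 = derive_cleavage_map(member1), derive_cleavage_map(member2)
        rng = np.random.default_rng(6)
        r1, _ = simulate_netseq(member1, cm1, SimConfig(n_molecules=4000, p_co=0.9), rng=rng)
        r2, _ = simulate_netseq(member2, cm2, SimConfig(n_molecules=4000, p_co=0.0), rng=rng)
        from cotxmir.coverage import end_coverage

        net = end_coverage(
            r1.to_read_intervals() + r2.to_read_intervals(), "three_prime", "+", max_len=500
        )
        fwd, rev = simulate_drip(member1, "beta", snr=5.0, seed=9)
        rep1 = locus_report(member1, cm1, net, fwd, rev)
        rep2 = locus_report(member2, cm2, net, fwd, rev)
        assert rep1.attrs["co_processing_evidence"]
        assert not rep2.attrs["co_processing_evidence"]


def test_plot_helpers_return_figures(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    from cotxmir.plotting import plot_locus_report, plot_profile

    locus = make_locus("BTL")
    cm = derive_cleavage_map(locus)
    reads, _ = simulate_netseq(locus, cm, SimConfig(seed=1, n_molecules=500))
    from cotxmir.coverage import end_coverage

    net = end_coverage(reads.to_read_intervals(), "three_prime", "+", max_len=500)
    fwd, rev = simulate_drip(locus, "beta", snr=5.0, seed=1)
    report = locus_report(locus, cm, net, fwd, rev)
    fig = plot_locus_report(report)
    fig.savefig(tmp_path / "report.svg")
    import pandas as pd

    profiles = {"BTL": (np.arange(10.0), 3), "LTB": (None, 0)}
    fig2 = plot_profile(profiles, n_flank=2, title="demo")
    fig2.savefig(tmp_path / "profile.svg")
    assert (tmp_path / "report.svg").stat().st_size > 0
    assert (tmp_path / "profile.svg").stat().st_size > 0
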