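import math

import numpy as np
import pytest

from pausepier.core import Interval, SampleMeta, SignalTrack
from pausepier.netseq import (
    DwellRecord,
    Peak,
    PeakCluster,
    call_peaks,
    classify_seb1_dependent,
    dwell_compare,
    dwell_time,
    find_clusters,
    fragment_cluster_ratio,
)

from conftest import make_track


def region(start, end, strand="+", chrom="chrI"):
    return Interval(chrom, start, end, strand)


class TestCallPeaks:
    def test_single_high_position_called(self):
        v = np.ones(100)
        v[40] = 200
        peaks = call_peaks(make_track(v), region(0, 100))
        assert [p.pos for p in peaks] == [40]
        assert peaks[0].reads == 200

    def test_all_zero_region_yields_empty_list(self):
        assert call_peaks(make_track(np.zeros(50)), region(0, 50)) == []

    def test_min_reads_gate_beats_z(self):
        v = np.ones(100)
        v[40] = 9  # huge Z but below the 10-read support threshold
        assert call_peaks(make_track(v), region(0, 100)) == []

    def test_z_is_computed_over_nonzero_positions_only(self):
        # sparse region: zeros must not enter the Z sample
        v = np.zeros(1000)
        nz = np.arange(0, 1000, 10)
        v[nz] = 1.0
        v[500] = 64
        peaks = call_peaks(make_track(v), region(0, 1000))
        assert [p.pos for p in peaks] == [500]

    def test_uniform_scaling_leaves_z_criterion_unchanged(self, rng):
        v = rng.poisson(1.0, 500).astype(float) + 1
        v[100] = 50
        t1, t2 = make_track(v), make_track(v * 4)
        p1 = call_peaks(t1, region(0, 500))
        p2 = call_peaks(t2, region(0, 500))
        # log2 scaling shifts all values equally; robust Z is shift-invariant
        assert [p.pos for p in p1] == [p.pos for p in p2]
        for a, b in zip(p1, p2):
            assert a.z == pytest.approx(b.z, rel=1e-9)


def brute_force_clusters(positions, region_start, width, step, region_end):
    """Oracle: enumerate every window explicitly, union-find over peaks."""
    parent = {p: p for p in positions}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    j = 0
    while region_start + j * step < region_end:
        lo = region_start + j * step
        hi = lo + width
        inside = [p for p in positions if lo <= p < hi]
        for a, b in zip(inside, inside[1:]):
            union(a, b)
        j += 1
    groups = {}
    for p in positions:
        groups.setdefault(find(p), []).append(p)
    return sorted(sorted(g) for g in groups.values())


class TestFindClusters:
    def make(self, positions, reads, size=200):
        v = np.zeros(size)
        for p, r in zip(positions, reads):
            v[p] = r
        track = make_track(v)
        peaks = [Peak("chrI", "+", p, float(r), 5.0) for p, r in zip(positions, reads)]
        return track, peaks

    def test_two_peaks_joined_by_shared_window(self):
        track, peaks = self.make([12, 58], [30, 20])
        clusters = find_clusters(peaks, track, region(0, 200))
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.iv.start, c.iv.end) == (12, 59)
        assert c.reads_total == 50
        assert c.density == pytest.approx(50 * 1000 / 47)

    def test_two_peaks_no_shared_grid_window(self):
        track, peaks = self.make([9, 57], [30, 20])
        clusters = find_clusters(peaks, track, region(0, 200))
        assert len(clusters) == 2
        assert all(len(c.peaks) == 1 for c in clusters)

    def test_single_peak_density(self):
        track, peaks = self.make([77], [12])
        (c,) = find_clusters(peaks, track, region(0, 200))
        assert (c.iv.start, c.iv.end) == (77, 78)
        assert c.density == pytest.approx(12 * 1000)

    def test_reads_total_counts_non_peak_positions(self):
        track, peaks = self.make([12, 58], [30, 20])
        track.values("chrI", "+")[30] = 7  # non-peak read starts inside the span
        (c,) = find_clusters(peaks, track, region(0, 200))
        assert c.reads_total == 57

    def test_width_below_step_errors(self):
        track, peaks = self.make([10], [15])
        with pytest.raises(ValueError):
            find_clusters(peaks, track, region(0, 200), width=5, step=10)

    def test_empty_peaks(self):
        track, _ = self.make([], [])
        assert find_clusters([], track, region(0, 200)) == []

    def test_matches_brute_force_window_oracle(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 12))
            start = int(rng.integers(0, 30))
            positions = sorted(
                int(p) for p in rng.choice(np.arange(start, start + 300), n, replace=False)
            )
            track, peaks = self.make(positions, [15] * len(positions), size=400)
            reg = region(start, 400)
            got = [
                [p.pos for p in c.peaks]
                for c in find_clusters(peaks, track, reg)
            ]
            expected = brute_force_clusters(positions, start, 50, 10, 400)
            assert sorted(got) == expected

    def test_cluster_reads_bounded_by_region_reads(self, rng):
        v = rng.poisson(0.5, 500).astype(float)
        v[[50, 60, 200]] += 20
        track = make_track(v)
        reg = region(0, 500)
        peaks = call_peaks(track, reg, min_reads=10)
        clusters = find_clusters(peaks, track, reg)
        for c in clusters:
            assert all(c.iv.start <= p.pos < c.iv.end for p in c.peaks)
        assert sum(c.reads_total for c in clusters) <= v.sum()


class TestDwellTime:
    def test_peak_over_unit_flanks(self):
        v = np.ones(200)
        v[100] = 20
        assert dwell_time(make_track(v), Peak("chrI", "+", 100, 20, 5.0)) == 20.0

    def test_uniform_track_dwell_is_one(self, uniform_track):
        assert dwell_time(uniform_track, Peak("chrI", "+", 1000, 3, 5.0)) == pytest.approx(1.0)

    def test_zero_flanks_give_infinity(self):
        v = np.zeros(200)
        v[100] = 50
        assert math.isinf(dwell_time(make_track(v), Peak("chrI", "+", 100, 50, 5.0)))

    def test_flank_truncated_at_chromosome_start(self):
        v = np.ones(200)
        v[2] = 10
        # only positions 0,1,3..52 exist in the window
        assert dwell_time(make_track(v), Peak("chrI", "+", 2, 10, 5.0)) == pytest.approx(10.0)


def tracks_for_classify(wt_vals, mut_vals, pos=50, size=100, filler=1000.0):
    """Replicate track pairs with equal totals so RPM preserves raw ratios."""
    out_wt, out_mut = [], []
    for vals, out in ((wt_vals, out_wt), (mut_vals, out_mut)):
        for rep, x in enumerate(vals, start=1):
            v = np.zeros(size)
            v[pos] = x
            v[0] = filler - x  # equalize library size
            t = make_track(v)
            t.sample = SampleMeta(f"s{rep}", replicate=rep)
            out.append(t)
    return out_wt, out_mut


class TestClassifySeb1Dependent:
    def peak(self, pos=50, reads=40.0):
        return Peak("chrI", "+", pos, reads, 5.0)

    def test_fourfold_drop_in_both_replicates_is_dependent(self):
        wt, mut = tracks_for_classify([40, 38], [10, 9])
        labeled = classify_seb1_dependent(
            [[self.peak()], [self.peak()]], wt, mut
        )
        assert labeled == [(self.peak(), True)]

    def test_subthreshold_pair_is_independent(self):
        wt, mut = tracks_for_classify([40, 38], [25, 10])
        labeled = classify_seb1_dependent([[self.peak()], [self.peak()]], wt, mut)
        assert labeled == [(self.peak(), False)]

    def test_zero_mutant_signal_counts_as_infinite_fold(self):
        wt, mut = tracks_for_classify([40, 38], [0, 0])
        labeled = classify_seb1_dependent([[self.peak()], [self.peak()]], wt, mut)
        assert labeled == [(self.peak(), True)]

    def test_unreplicated_peak_is_independent(self):
        wt, mut = tracks_for_classify([40, 38], [5, 5])
        labeled = classify_seb1_dependent(
            [[self.peak()], []], wt, mut
        )
        assert labeled == [(self.peak(), False)]

    def test_fewer_than_two_replicates_errors(self):
        wt, mut = tracks_for_classify([40], [10])
        with pytest.raises(ValueError):
            classify_seb1_dependent([[self.peak()]], wt, mut)


def cluster_at(pos, density, strand="+", chrom="chrI"):
    span = Interval(chrom, pos, pos + 10, strand)
    reads = density * span.length / 1000.0
    return PeakCluster(
        iv=span,
        peaks=[Peak(chrom, strand, pos, reads, 5.0)],
        reads_total=reads,
        density=density,
    )


class TestFragmentClusterRatio:
    FRAGS = [Interval("chrI", 0, 100, name="FragA"), Interval("chrI", 100, 200, name="FragB")]

    def sample(self, genotype, rep):
        return SampleMeta(f"{genotype}_r{rep}", genotype=genotype, replicate=rep)

    def test_identical_cluster_sets_give_unit_ratio(self):
        clusters = [cluster_at(20, 100.0), cluster_at(150, 50.0)]
        by_sample = {
            self.sample(g, r): clusters for g in ("wt", "mut") for r in (1, 2)
        }
        df = fragment_cluster_ratio(by_sample, self.FRAGS, "wt", "mut")
        present = df[df["flag"] == ""]
        assert np.allclose(present["ratio"], 1.0)

    def test_numerator_only_fragment_flagged_infinite(self):
        wt_clusters = [cluster_at(20, 100.0), cluster_at(150, 50.0)]
        mut_clusters = [cluster_at(150, 50.0)]
        by_sample = {}
        for r in (1, 2):
            by_sample[self.sample("wt", r)] = wt_clusters
            by_sample[self.sample("mut", r)] = mut_clusters
        df = fragment_cluster_ratio(by_sample, self.FRAGS, "wt", "mut")
        row = df[(df["fragment"] == "FragA") & (df["strand"] == "+")].iloc[0]
        assert row["flag"] == "inf"

    def test_no_peaks_in_numerator_flagged_np(self):
        wt_clusters = [cluster_at(150, 50.0)]
        mut_clusters = [cluster_at(20, 100.0), cluster_at(150, 50.0)]
        by_sample = {}
        for r in (1, 2):
            by_sample[self.sample("wt", r)] = wt_clusters
            by_sample[self.sample("mut", r)] = mut_clusters
        df = fragment_cluster_ratio(by_sample, self.FRAGS, "wt", "mut")
        row = df[(df["fragment"] == "FragA") & (df["strand"] == "+")].iloc[0]
        assert row["flag"] == "n.p."

    def test_planted_threefold_enrichment_recovered(self):
        # FragA density 3x higher in wt; FragB equal → after per-sample
        # normalization the FragA ratio is 3 / (normalization shift)
        def sets(factor):
            return [cluster_at(20, 100.0 * factor), cluster_at(150, 50.0)]

        by_sample = {}
        for r in (1, 2):
            by_sample[self.sample("wt", r)] = sets(3.0)
            by_sample[self.sample("mut", r)] = sets(1.0)
        df = fragment_cluster_ratio(by_sample, self.FRAGS, "wt", "mut")
        a = df[(df["fragment"] == "FragA") & (df["strand"] == "+")].iloc[0]
        b = df[(df["fragment"] == "FragB") & (df["strand"] == "+")].iloc[0]
        # normalized scores: wt FragA 300/350, mut 100/150
        assert a["ratio"] == pytest.approx((300 / 350) / (100 / 150))
        assert a["ratio"] > 1 > b["ratio"]
        assert a["ratio_lo"] <= a["ratio"] <= a["ratio_hi"]


class TestDwellCompare:
    def rec(self, dwell):
        return DwellRecord(peak=Peak("chrI", "+", 1, 10, 5.0), dwell=dwell)

    def test_identical_distributions(self):
        res = dwell_compare([self.rec(x) for x in (1, 2, 3)], [self.rec(x) for x in (1, 2, 3)])
        assert res.ks_statistic == 0
        assert res.ks_pvalue > 0.99

    def test_singletons_give_extreme_statistic(self):
        res = dwell_compare([self.rec(1.0)], [self.rec(5.0)])
        assert res.ks_statistic in (0.0, 1.0)

    def test_infinite_dwells_excluded(self):
        res = dwell_compare(
            [self.rec(1.0), self.rec(math.inf)], [self.rec(2.0)]
        )
        assert res.median_dependent == 1.0

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            dwell_compare([], [self.rec(1.0)])
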