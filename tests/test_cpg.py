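import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpgdesert.cpg import (
    CpGSiteList,
    density_histogram,
    detect_clusters,
    detect_islands,
    find_cpg_sites,
    interval_cpg_density,
    sliding_density_profile,
)
from cpgdesert.intervals import GenomicInterval, SequenceRecord, reverse_complement

from conftest import random_sequence
from oracles import cluster_runs, island_oracle, scan_cpg_positions, window_densities

dna = st.text(alphabet="ACGTN", min_size=2, max_size=300)


class TestFindSites:
    @pytest.mark.parametrize(
        "seq, expected",
        [("CGCG", [0, 2]), ("GC", []), ("ACGT", [1]), ("CCGG", [1]), ("N" * 10, [])],
    )
    def test_examples(self, seq, expected):
        assert find_cpg_sites(SequenceRecord("s", seq)).positions.tolist() == expected

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(50):
            seq = random_sequence(rng, int(rng.integers(2, 2000)))
            rec = SequenceRecord("s", seq)
            assert find_cpg_sites(rec).positions.tolist() == scan_cpg_positions(seq)

    @settings(derandomize=True, max_examples=200)
    @given(seq=dna)
    def test_strand_symmetric_count(self, seq):
        fwd = find_cpg_sites(SequenceRecord("s", seq))
        rev = find_cpg_sites(SequenceRecord("s", reverse_complement(seq)))
        assert len(fwd) == len(rev)


class TestIntervalDensity:
    def test_four_sites_in_100bp(self):
        sites = CpGSiteList("s", np.array([10, 30, 50, 70]))
        iv = GenomicInterval("s", 0, 100)
        assert interval_cpg_density(sites, iv, 100) == 4.0

    def test_cgcg_whole_sequence(self):
        rec = SequenceRecord("s", "CGCG")
        sites = find_cpg_sites(rec)
        assert interval_cpg_density(sites, GenomicInterval("s", 0, 4), 4) == 50.0

    def test_no_sites(self):
        sites = CpGSiteList("s", np.array([], dtype=np.int64))
        assert interval_cpg_density(sites, GenomicInterval("s", 0, 200), 200) == 0.0

    def test_fully_masked_errors(self):
        sites = CpGSiteList("s", np.array([], dtype=np.int64))
        with pytest.raises(ValueError, match="masked"):
            interval_cpg_density(sites, GenomicInterval("s", 0, 200), 0)

    def test_concatenation_is_length_weighted_mean(self, rng):
        """Density over [a,c) equals the weighted mean over [a,b) and [b,c)."""
        seq = random_sequence(rng, 1000)
        sites = find_cpg_sites(SequenceRecord("s", seq))
        a, b, c = 100, 480, 900
        d1 = interval_cpg_density(sites, GenomicInterval("s", a, b), b - a)
        d2 = interval_cpg_density(sites, GenomicInterval("s", b, c), c - b)
        d = interval_cpg_density(sites, GenomicInterval("s", a, c), c - a)
        # a CpG straddling the cut (C at b-1) belongs to the left part either way
        assert d == pytest.approx((d1 * (b - a) + d2 * (c - b)) / (c - a))


class TestSlidingProfile:
    def test_all_a_is_zero(self):
        rec = SequenceRecord("s", "A" * 300)
        prof = sliding_density_profile(find_cpg_sites(rec), 300)
        assert np.all(prof.densities == 0.0) and len(prof.densities) == 5

    def test_cg_repeat_window_100(self):
        rec = SequenceRecord("s", "CG" * 50)
        prof = sliding_density_profile(find_cpg_sites(rec), 100, window=100, step=100)
        assert prof.densities.tolist() == [50.0]

    def test_short_sequence_warns_empty(self, caplog):
        rec = SequenceRecord("s", "ACGT")
        with caplog.at_level("WARNING"):
            prof = sliding_density_profile(find_cpg_sites(rec), 4, window=100)
        assert len(prof.densities) == 0
        assert any("empty density profile" in m for m in caplog.messages)

    def test_matches_window_counting_oracle(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(100, 1500)))
            sites = find_cpg_sites(SequenceRecord("s", seq))
            for window, step in [(100, 50), (200, 37), (50, 50)]:
                prof = sliding_density_profile(sites, len(seq), window, step)
                assert prof.densities.tolist() == window_densities(seq, window, step)


class TestIslands:
    def test_cg_repeat_is_one_island(self):
        rec = SequenceRecord("s", "CG" * 100)
        (isl,) = detect_islands(rec)
        assert (isl.interval.start, isl.interval.end) == (0, 200)
        assert isl.gc_fraction == 1.0
        assert isl.obs_exp == pytest.approx(2.0)

    def test_all_a_has_none(self):
        assert detect_islands(SequenceRecord("s", "A" * 1000)) == []

    def test_matches_exhaustive_oracle(self, rng):
        n_checked = 0
        for _ in range(30):
            # GC-rich composition so islands actually occur
            seq = random_sequence(rng, int(rng.integers(200, 1500)), p=(0.2, 0.3, 0.3, 0.2))
            rec = SequenceRecord("s", seq)
            got = [
                (i.interval.start, i.interval.end, i.gc_fraction, i.obs_exp)
                for i in detect_islands(rec)
            ]
            expected = island_oracle(seq)
            assert [(s, e) for s, e, *_ in got] == [(s, e) for s, e, *_ in expected]
            for g, x in zip(got, expected):
                assert g[2] == pytest.approx(x[2]) and g[3] == pytest.approx(x[3])
            n_checked += len(expected)
        assert n_checked > 0  # the comparison actually exercised islands

    def test_islands_disjoint_and_revalidated(self, rng):
        for _ in range(10):
            seq = random_sequence(rng, 2000, p=(0.22, 0.28, 0.28, 0.22))
            islands = detect_islands(SequenceRecord("s", seq))
            for a, b in zip(islands[:-1], islands[1:]):
                assert a.interval.end <= b.interval.start
            for isl in islands:
                sub = seq[isl.interval.start : isl.interval.end]
                n_c, n_g = sub.count("C"), sub.count("G")
                assert isl.interval.length() >= 200
                assert (n_c + n_g) / len(sub) >= 0.50
                assert sub.count("CG") * len(sub) / (n_c * n_g) >= 0.60


class TestClusters:
    def test_three_sites_within_gap(self):
        sites = CpGSiteList("s", np.array([10, 25, 40]))
        (cl,) = detect_clusters(sites, GenomicInterval("s", 0, 500))
        assert cl.n_sites == 3
        assert (cl.interval.start, cl.interval.end) == (10, 42)

    def test_run_of_two_is_not_a_cluster(self):
        sites = CpGSiteList("s", np.array([10, 25, 200]))
        assert detect_clusters(sites, GenomicInterval("s", 0, 500)) == []

    def test_island_exclusion(self):
        from cpgdesert.cpg import CpGIsland

        sites = CpGSiteList("s", np.array([10, 25, 40]))
        isl = CpGIsland(GenomicInterval("s", 0, 100), 0.6, 1.0)
        assert detect_clusters(sites, GenomicInterval("s", 0, 500), exclude=[isl]) == []

    def test_matches_run_enumeration_oracle(self, rng):
        for _ in range(50):
            pos = np.unique(rng.choice(1000, size=int(rng.integers(0, 60)), replace=False))
            pos = pos[np.diff(np.concatenate([[-5], pos])) >= 2]  # valid CpG spacing
            sites = CpGSiteList("s", pos.astype(np.int64))
            iv = GenomicInterval("s", 100, 900)
            got = detect_clusters(sites, iv)
            expected = cluster_runs(pos.tolist(), 100, 900)
            assert [(c.interval.start, c.interval.end - 2, c.n_sites) for c in got] == [
                (r[0], r[-1], len(r)) for r in expected
            ]

    def test_clusters_are_maximal(self, rng):
        pos = np.sort(rng.choice(2000, size=80, replace=False)).astype(np.int64)
        pos = pos[np.diff(np.concatenate([[-5], pos])) >= 2]
        sites = CpGSiteList("s", pos)
        iv = GenomicInterval("s", 0, 2000)
        for cl in detect_clusters(sites, iv):
            in_run = pos[(pos >= cl.interval.start) & (pos <= cl.interval.end - 2)]
            before = pos[pos < in_run[0]]
            after = pos[pos > in_run[-1]]
            if len(before):
                assert in_run[0] - before[-1] > 30
            if len(after):
                assert after[0] - in_run[-1] > 30


class TestHistogram:
    def test_example_bins(self):
        h = density_histogram([0.5, 1.2, 1.8])
        assert h.counts.tolist() == [1, 2]

    def test_empty(self):
        h = density_histogram([])
        assert h.total() == 0 and len(h.counts) == 0

    def test_matches_direct_binning(self, rng):
        draws = rng.uniform(0, 13, size=10_000)
        h = density_histogram(draws, bin_width=1.0)
        direct = np.bincount(np.floor(draws).astype(int))
        assert h.counts.tolist() == direct.tolist()
        assert h.total() == 10_000

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            density_histogram([-0.1])
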