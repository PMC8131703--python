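import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from rtcomp.genome import BinnedTrack, GenomeSpec
from rtcomp import repliseq as rs
from rtcomp import synthgen as sg

from conftest import make_track


class TestRpmNormalize:
    def test_equal_counts_split_evenly(self):
        t = rs.rpm_normalize(make_track([2.0, 2.0], mask=np.zeros(2, bool)))
        np.testing.assert_allclose(t.valid_values, [5e5, 5e5])

    def test_proportionality(self):
        t = rs.rpm_normalize(make_track([1.0, 3.0], mask=np.zeros(2, bool)))
        np.testing.assert_allclose(t.valid_values, [2.5e5, 7.5e5])

    @given(st.lists(st.integers(0, 10**6), min_size=10, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_output_sums_to_one_million(self, counts):
        arr = np.asarray(counts, dtype=float)
        if arr.sum() <= 0:
            return
        t = rs.rpm_normalize(make_track(arr, mask=np.zeros(len(arr), bool)))
        assert t.valid_values.sum() == pytest.approx(1e6, rel=1e-6)

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            rs.rpm_normalize(make_track(np.zeros(12)))


class TestExcludeBins:
    def test_unknown_chromosome_lenient_vs_strict(self):
        t = make_track(np.ones(12))
        out = rs.exclude_bins(t, ["chrX", "chrY"], strict=False)
        np.testing.assert_array_equal(out.mask, t.mask)
        with pytest.raises(ValueError, match="chrX"):
            rs.exclude_bins(t, ["chrX"], strict=True)

    def test_min_count_zero_masks_nothing(self):
        t = make_track(np.arange(12.0))
        out = rs.exclude_bins(t, min_count=0)
        np.testing.assert_array_equal(out.mask, t.mask)

    def test_coverage_threshold_masks_exact_bins(self):
        counts = [5.0, 0.0, 3.0, 1.0, 9.0, 2.0]
        t = make_track(counts, mask=np.zeros(6, bool))
        out = rs.exclude_bins(t, min_count=2)
        newly = out.mask & ~t.mask
        assert newly.sum() == 2  # the 0 and the 1

    def test_whole_chromosome_masked(self):
        g = GenomeSpec((("chr1", 10), ("chrX", 10)), 1000)
        t = BinnedTrack(g, np.ones(20))
        out = rs.exclude_bins(t, ["chrX"])
        assert out.mask[10:].all() and not out.mask[:10].any()


class TestComputeRTProfile:
    def test_equal_fractions_score_zero(self):
        e = make_track(np.full(12, 50.0))
        l = make_track(np.full(12, 50.0))
        np.testing.assert_allclose(rs.compute_rt_profile(e, l).values, 0.0)

    def test_fourfold_ratio_scores_two(self):
        e = make_track(np.full(12, 400.0))
        l = make_track(np.full(12, 100.0))
        rt = rs.compute_rt_profile(e, l, pseudocount=1e-9)
        np.testing.assert_allclose(rt.values, 2.0, atol=1e-6)

    def test_empty_bins_score_zero_via_pseudocount(self):
        e = make_track(np.zeros(12))
        l = make_track(np.zeros(12))
        np.testing.assert_allclose(rs.compute_rt_profile(e, l).values, 0.0)

    def test_rejects_mismatched_genomes(self):
        e = make_track(np.ones(12), bin_size=50_000)
        l = make_track(np.ones(12), bin_size=25_000)
        with pytest.raises(ValueError):
            rs.compute_rt_profile(e, l)

    def test_mask_propagates_from_either_fraction(self):
        m = np.zeros(12, bool)
        m[3] = True
        e = make_track(np.ones(12), mask=m)
        l = make_track(np.ones(12))
        assert rs.compute_rt_profile(e, l).mask[3]

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_rpm_then_ratio_invariant_to_library_scale(self, scale):
        """Multiplying one raw fraction by a constant leaves RT unchanged."""
        rng = np.random.default_rng(0)
        e_raw = rng.integers(10, 1000, 40).astype(float)
        l_raw = rng.integers(10, 1000, 40).astype(float)
        base = rs.compute_rt_profile(
            rs.rpm_normalize(make_track(e_raw)), rs.rpm_normalize(make_track(l_raw))
        )
        scaled = rs.compute_rt_profile(
            rs.rpm_normalize(make_track(e_raw * scale)),
            rs.rpm_normalize(make_track(l_raw)),
        )
        np.testing.assert_allclose(base.values, scaled.values, atol=1e-9)


class TestEstimatorConsistency:
    def test_per_domain_rt_recovered_at_high_depth(self):
        """Recovered per-domain RT within 0.1 of planted at depth 1e7, after
        removing the genome-wide offset the depth ratio imprints."""
        g = GenomeSpec(tuple((f"c{i}", 400) for i in range(10)), 250_000)
        seg = sg.segment_genome(g, 8.0, seed=3).refine(5)  # domains >= 10 fine bins
        rt_true = seg.rt_track()  # noiseless planted values
        reps = []
        for r in range(3):  # profiles are replicate means, as in the pipeline
            e, l = sg.simulate_repliseq_counts(rt_true, 10_000_000, seed=3 + r)
            reps.append(rs.compute_rt_profile(rs.rpm_normalize(e), rs.rpm_normalize(l)))
        prof = rs.mean_profile(reps)
        offset = np.median(prof.values - rt_true.values)
        off = 0
        worst = 0.0
        for name in seg.genome.names:
            for d in seg.domains[name]:
                rec = prof.values[off + d.start : off + d.end].mean() - offset
                planted = rt_true.values[off + d.start : off + d.end].mean()
                worst = max(worst, abs(rec - planted))
            off += seg.genome.chrom_length(name)
        assert worst < 0.1


class TestDistributionAndBimodality:
    def test_density_integrates_to_one(self, rt_track):
        edges, dens = rs.rt_distribution(rt_track, 40)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)

    def test_constant_values_occupy_single_bin(self):
        t = make_track(np.full(12, 1.3))
        edges, dens = rs.rt_distribution(t, 10)
        assert (dens > 0).sum() == 1

    def test_planted_mixture_shows_two_modes(self):
        g = GenomeSpec(tuple((f"c{i}", 1000) for i in range(4)), 50_000)
        seg = sg.segment_genome(g, 40.0, seed=1)
        t = sg.make_rt_track(seg, 0.2, seed=1)
        edges, dens = rs.rt_distribution(t, 40)
        centres = (edges[:-1] + edges[1:]) / 2
        lo = dens[np.abs(centres) < 0.5].max()
        left = dens[centres < -0.5].max()
        right = dens[centres > 0.5].max()
        assert left > lo and right > lo  # two maxima with a dip near zero

    def test_bimodal_vs_unimodal_verdicts(self):
        g = GenomeSpec(tuple((f"c{i}", 1000) for i in range(4)), 50_000)
        flagged_bi, flagged_uni = 0, 0
        for seed in range(5):
            seg = sg.segment_genome(g, 40.0, seed=seed)
            t = sg.make_rt_track(seg, 0.2, seed=seed)
            if rs.bimodality(t)[1]:
                flagged_bi += 1
            rng = np.random.default_rng(seed)
            u = BinnedTrack(g, rng.normal(0.0, 0.8, g.n_bins))
            if not rs.bimodality(u)[1]:
                flagged_uni += 1
        assert flagged_bi == 5 and flagged_uni == 5

    def test_degenerate_variance_returns_zero_false(self):
        t = make_track(np.zeros(200))
        assert rs.bimodality(t) == (0.0, False)


class TestCorrelateAndCluster:
    def test_self_and_negation(self, rt_track):
        corr = rs.correlate_profiles([rt_track, rt_track.with_values(-rt_track.values)])
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_independent_tracks_nearly_uncorrelated(self):
        g = GenomeSpec(tuple((f"c{i}", 400) for i in range(10)), 50_000)
        rng = np.random.default_rng(12)
        a = BinnedTrack(g, rng.normal(size=g.n_bins))
        b = BinnedTrack(g, rng.normal(size=g.n_bins))
        assert abs(rs.correlate_profiles([a, b])[0, 1]) < 0.06

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        g = GenomeSpec((("chr1", 100),), 50_000)
        t1 = BinnedTrack(g, rng.normal(size=100))
        t2 = BinnedTrack(g, rng.normal(size=100))
        base = rs.correlate_profiles([t1, t2])
        scaled = rs.correlate_profiles([t1.with_values(a * t1.values + b), t2])
        np.testing.assert_allclose(base, scaled, atol=1e-9)

    def test_two_replica_groups_separate_exactly(self):
        """WT-like vs flattened-RT replicas: the 2-cluster cut is perfect."""
        g = GenomeSpec(tuple((f"c{i}", 400) for i in range(4)), 50_000)
        seg = sg.segment_genome(g, 40.0, seed=2)
        tracks, truth = [], []
        for shrink, grp in ((0.0, 0), (0.95, 1)):
            rt_true = sg.make_rt_track(seg.with_rt_scaled(1 - shrink), 0.2, seed=grp)
            for r in range(3):
                e, l = sg.simulate_repliseq_counts(rt_true, 2_000_000, seed=10 * grp + r)
                tracks.append(
                    rs.compute_rt_profile(rs.rpm_normalize(e), rs.rpm_normalize(l))
                )
                truth.append(grp)
        corr = rs.correlate_profiles(tracks)
        res = rs.cluster_profiles(corr, [f"s{i}" for i in range(6)])
        assert adjusted_rand_score(truth, res.flat2) == 1.0

    def test_identical_tracks_merge_at_zero_height(self, rt_track):
        corr = rs.correlate_profiles([rt_track, rt_track, rt_track])
        res = rs.cluster_profiles(corr, ["a", "b", "c"])
        assert np.allclose(res.linkage[:, 2], 0.0, atol=1e-12)

    def test_two_tracks_single_merge_at_one_minus_r(self):
        corr = np.array([[1.0, 0.25], [0.25, 1.0]])
        res = rs.cluster_profiles(corr, ["a", "b"])
        assert res.linkage.shape[0] == 1
        assert res.linkage[0, 2] == pytest.approx(0.75)

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError):
            rs.cluster_profiles(np.array([[1.0, 0.2], [0.4, 1.0]]), ["a", "b"])

    def test_newick_roundtrip_has_all_leaves(self, rt_track):
        corr = rs.correlate_profiles([rt_track, rt_track, rt_track])
        nwk = rs.cluster_profiles(corr, ["x", "y", "z"]).to_newick()
        assert nwk.endswith(";") and all(n in nwk for n in "xyz")


class TestClassifyRTChanges:
    def test_identical_profiles_are_all_stable(self, rt_track):
        table = rs.classify_rt_changes(rt_track, rt_track)
        assert table.fractions()["stable"] == pytest.approx(1.0)

    def test_sign_flip_is_a_switch(self):
        a = make_track(np.full(12, 1.0))
        b = make_track(np.full(12, -1.0))
        table = rs.classify_rt_changes(a, b, 0.5, 0.25)
        assert (table.category == "EtoL").all()
        table_rev = rs.classify_rt_changes(b, a, 0.5, 0.25)
        assert (table_rev.category == "LtoE").all()

    def test_toward_and_away_from_zero(self):
        a = make_track([1.0, 0.2])
        b = make_track([0.4, 1.0])
        table = rs.classify_rt_changes(a, b, 0.5, 0.25)
        assert table.category[0] == "toward_zero"
        assert table.category[1] == "away_from_zero"

    def test_planted_switch_fraction_recovered(self):
        """Flipping the sign of 10% of high-|RT| bins yields ~10% switches."""
        g = GenomeSpec(tuple((f"c{i}", 1000) for i in range(4)), 50_000)
        rng = np.random.default_rng(5)
        vals = np.where(rng.random(g.n_bins) < 0.5, 1.0, -1.0) * rng.uniform(
            1.0, 2.0, g.n_bins
        )
        a = BinnedTrack(g, vals)
        flip = rng.random(g.n_bins) < 0.10
        b = BinnedTrack(g, np.where(flip, -vals, vals))
        table = rs.classify_rt_changes(a, b, 0.5, 0.25)
        assert table.switch_fraction() == pytest.approx(0.10, abs=0.01)

    def test_masked_bins_stay_masked(self):
        m = np.zeros(12, bool)
        m[2] = True
        a = make_track(np.ones(12), mask=m)
        b = make_track(np.ones(12))
        assert rs.classify_rt_changes(a, b).category[2] == "masked"

    def test_rejects_threshold_order(self, rt_track):
        with pytest.raises(ValueError):
            rs.classify_rt_changes(rt_track, rt_track, 0.2, 0.5)
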