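import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rtcomp.genome import BinnedTrack, GenomeSpec
from rtcomp import hic_core as hc
from rtcomp import synthgen as sg
from rtcomp import saddle as sd

from conftest import make_track


def brute_force_saddle(mats, labels, q, min_dist, max_dist=None):
    """Independent double-loop saddle aggregation (test oracle)."""
    sums = np.zeros((q, q))
    counts = np.zeros((q, q))
    for m in mats:
        lab = labels.chrom_labels(m.chrom)
        data = m.masked_data()
        for i in range(m.n_bins):
            for j in range(i + 1, m.n_bins):
                d = (j - i) * m.bin_size
                if d < min_dist or (max_dist is not None and d > max_dist):
                    continue
                v = data[i, j]
                if not np.isfinite(v) or lab[i] == 0 or lab[j] == 0:
                    continue
                p_, q_ = lab[i] - 1, lab[j] - 1
                sums[p_, q_] += v
                counts[p_, q_] += 1
    sums = sums + sums.T
    counts = counts + counts.T
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan), counts


class TestDigitizeTrack:
    def test_four_values_two_groups(self):
        g = GenomeSpec((("chr1", 40),), 50_000)
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 10)
        labels = sd.digitize_track(BinnedTrack(g, vals), 2, 0.0)
        first4 = labels.labels[:4]
        np.testing.assert_array_equal(first4, [1, 1, 2, 2])

    def test_group_sizes_differ_by_at_most_one(self, rt_track):
        labels = sd.digitize_track(rt_track, 7, 0.0)
        sizes = np.bincount(labels.labels)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_trimming_masks_extremes(self, rt_track):
        labels = sd.digitize_track(rt_track, 5, 0.1)
        n = rt_track.n_valid()
        n_trim = int(np.floor(0.1 * n))
        assert (labels.labels == 0).sum() == 2 * n_trim
        order = np.argsort(rt_track.values)
        assert np.all(labels.labels[order[:n_trim]] == 0)
        assert np.all(labels.labels[order[-n_trim:]] == 0)

    @given(st.integers(2, 8))
    @settings(max_examples=10, deadline=None)
    def test_monotone_transform_leaves_labels_unchanged(self, q):
        g = GenomeSpec((("chr1", 200),), 50_000)
        rng = np.random.default_rng(1)
        t = BinnedTrack(g, rng.normal(size=200))
        cubed = t.with_values(t.values**3)  # strictly monotone
        a = sd.digitize_track(t, q, 0.02)
        b = sd.digitize_track(cubed, q, 0.02)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_rejects_too_few_bins(self):
        t = make_track(np.arange(15.0))
        with pytest.raises(ValueError):
            sd.digitize_track(t, 2, 0.0)


class TestSaddleMatrix:
    def test_flat_oe_gives_flat_saddle(self, seg):
        oe = sg.structured_oe(seg, 0.0)
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        s = sd.saddle_matrix(oe, labels)
        assert np.nanmax(np.abs(s.saddle - 1.0)) < 1e-12
        assert s.strength == pytest.approx(1.0)

    def test_closed_form_strength(self, seg):
        """Noiseless delta=0.25 block model: strength exp(1) within 1e-6."""
        oe = sg.structured_oe(seg, 0.25)
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        s = sd.saddle_matrix(oe, labels)
        assert s.strength == pytest.approx(np.exp(1.0), abs=1e-6)

    def test_reversed_labels_flip_saddle_antidiagonally(self, seg):
        oe = sg.structured_oe(seg, 0.4)
        labels = sd.digitize_track(seg.rt_track(), 8, 0.0)
        rev = sd.QuantileLabels(
            labels.genome,
            np.where(labels.labels > 0, 9 - labels.labels, 0),
            8,
            labels.track_name,
        )
        s = sd.saddle_matrix(oe, labels)
        sr = sd.saddle_matrix(oe, rev)
        np.testing.assert_allclose(sr.saddle, s.saddle[::-1, ::-1], atol=1e-12)

    def test_agrees_with_brute_force(self, seg):
        """Vectorised aggregation equals an independent double loop exactly."""
        g = GenomeSpec((("chr1", 50), ("chr2", 40)), 250_000)
        seg2 = sg.segment_genome(g, 6.0, seed=7)
        mats = sg.simulate_hic(seg2, sg.GenotypeSpec("g", 0.2, seed=7), 1.0, 0.3)
        bal = [hc.balance(m) for m in mats]
        oes = [hc.observed_over_expected(m, min_pairs=1) for m in bal]
        labels = sd.digitize_track(seg2.rt_track(), 4, 0.0)
        s = sd.saddle_matrix(oes, labels, min_dist=2 * 250_000)
        bf_saddle, bf_counts = brute_force_saddle(oes, labels, 4, 2 * 250_000)
        np.testing.assert_allclose(s.saddle, bf_saddle, rtol=1e-12)
        np.testing.assert_array_equal(s.pair_counts, bf_counts)

    def test_empty_cells_are_missing_not_zero(self, seg):
        oe = sg.structured_oe(seg, 0.3)
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        s = sd.saddle_matrix(oe, labels, min_dist=1e12)  # beyond chromosomes
        assert np.isnan(s.saddle).all()
        assert np.all(s.pair_counts == 0)


class TestCompartmentStrength:
    def test_flat_saddle_scores_one(self):
        s = sd.SaddleResult("t", 10, np.ones((10, 10)), np.full((10, 10), 5.0), 1.0)
        assert sd.compartment_strength(s) == pytest.approx(1.0)

    def test_mixing_strictly_decreases_strength(self, seg):
        """Analytic mixing oracle: strength falls along lambda 0 -> 0.4 -> 0.8."""
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        got = []
        for lam in (0.0, 0.4, 0.8):
            oe = sg.structured_oe(seg, 0.5, lambda_mix=lam)
            got.append(sd.saddle_matrix(oe, labels).strength)
            e_d, e_m = np.exp(0.5), np.exp(-0.5)
            aa = (1 - lam) * e_d + lam
            ab = (1 - lam) * e_m + lam
            assert got[-1] == pytest.approx(aa**2 / ab**2, abs=1e-9)
        assert got[0] > got[1] > got[2]

    def test_strength_invariant_to_quantile_count(self, seg):
        """Q in {5, 10, 20} changes strength < 10% on the noiseless model."""
        oe = sg.structured_oe(seg, 0.25)
        vals = [
            sd.saddle_matrix(oe, sd.digitize_track(seg.rt_track(), q, 0.0)).strength
            for q in (5, 10, 20)
        ]
        assert (max(vals) - min(vals)) / min(vals) < 0.10

    def test_ranking_consistency_across_tracks(self):
        """RT-, RIF1- and E1-conditioned strengths agree within 15% on
        WT-like data with ample coverage."""
        from rtcomp.compartments import compartment_eigenvector

        g = GenomeSpec(tuple((f"c{i}", 300) for i in range(3)), 250_000)
        seg = sg.segment_genome(g, 8.0, seed=5)
        raw = sg.simulate_hic(
            seg, sg.GenotypeSpec("g", 0.0, coverage=1000, seed=5), 1.0, 0.3
        )
        oes = [hc.observed_over_expected(hc.balance(m)) for m in raw]
        rt = sg.make_rt_track(seg, 0.2, seed=5)
        rif1 = sg.simulate_rif1_track(rt, 0.5, seed=5)
        e1 = compartment_eigenvector(oes, rt).e1
        strengths = {}
        for name, track in (("rt", rt), ("rif1_inv", rif1.with_values(-rif1.values)),
                            ("e1", e1)):
            labels = sd.digitize_track(track, 20, 0.02)
            strengths[name] = sd.saddle_matrix(oes, labels).strength
        vals = np.array(list(strengths.values()))
        assert vals.max() / vals.min() < 1.15, strengths

    def test_rejects_empty_corner(self):
        s = sd.SaddleResult("t", 10, np.full((10, 10), np.nan), np.zeros((10, 10)), 1.0)
        with pytest.raises(ValueError):
            sd.compartment_strength(s)


class TestStrengthByDistance:
    def test_distance_independent_model_has_equal_strength_per_band(self, seg):
        oe = sg.structured_oe(seg, 0.3)
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        bands = [(1e6, 5e6), (5e6, 15e6), (15e6, 40e6)]
        curve = sd.strength_by_distance(oe, labels, bands)
        assert np.nanmax(curve.strength) - np.nanmin(curve.strength) < 1e-6

    def test_band_beyond_chromosome_is_missing(self, seg):
        oe = sg.structured_oe(seg, 0.3)
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        curve = sd.strength_by_distance(oe, labels, [(1e6, 5e6), (1e12, 2e12)])
        assert np.isfinite(curve.strength[0])
        assert np.isnan(curve.strength[1])

    def test_rejects_overlapping_bands(self, seg):
        oe = sg.structured_oe(seg, 0.3)
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        with pytest.raises(ValueError):
            sd.strength_by_distance(oe, labels, [(1e6, 5e6), (4e6, 8e6)])

    def test_dose_weakening_in_every_band(self, seg):
        """lambda=0.8 strength below lambda=0 in each well-populated band."""
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        bands = [(1e6, 5e6), (5e6, 15e6)]
        strong = sd.strength_by_distance(sg.structured_oe(seg, 0.5, 0.0), labels, bands)
        weak = sd.strength_by_distance(sg.structured_oe(seg, 0.5, 0.8), labels, bands)
        assert np.all(weak.strength < strong.strength)


class TestDifferentialSaddle:
    def test_self_difference_is_zero(self, seg):
        oe = sg.structured_oe(seg, 0.3)
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        s = sd.saddle_matrix(oe, labels)
        np.testing.assert_allclose(sd.differential_saddle(s, s), 0.0, atol=1e-12)

    def test_swap_negates(self, seg):
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        s1 = sd.saddle_matrix(sg.structured_oe(seg, 0.3, 0.0), labels)
        s2 = sd.saddle_matrix(sg.structured_oe(seg, 0.3, 0.6), labels)
        d12 = sd.differential_saddle(s1, s2)
        d21 = sd.differential_saddle(s2, s1)
        np.testing.assert_allclose(d12, -d21, atol=1e-12)

    def test_weakened_vs_reference_gains_in_cross_corners(self, seg):
        """KO-like vs WT-like on an RT ranking: positive log-ratio in the
        opposite-quantile corners, negative in same-quantile corners."""
        labels = sd.digitize_track(seg.rt_track(), 10, 0.0)
        wt = sd.saddle_matrix(sg.structured_oe(seg, 0.4, 0.0), labels)
        ko = sd.saddle_matrix(sg.structured_oe(seg, 0.4, 0.8), labels)
        diff = sd.differential_saddle(ko, wt)
        assert diff[0, 9] > 0 and diff[9, 0] > 0
        assert diff[0, 0] < 0 and diff[9, 9] < 0

    def test_rejects_quantile_mismatch(self, seg):
        l10 = sd.digitize_track(seg.rt_track(), 10, 0.0)
        l5 = sd.digitize_track(seg.rt_track(), 5, 0.0)
        s10 = sd.saddle_matrix(sg.structured_oe(seg, 0.3), l10)
        s5 = sd.saddle_matrix(sg.structured_oe(seg, 0.3), l5)
        with pytest.raises(ValueError):
            sd.differential_saddle(s10, s5)


class TestNullCalibration:
    def test_random_track_gives_flat_saddle(self):
        """Conditioning on a structure-free track: cells ~ 1, strength ~ 1."""
        g = GenomeSpec((("chr1", 300),), 250_000)
        seg = sg.segment_genome(g, 8.0, seed=9)
        raw = sg.simulate_hic(
            seg, sg.GenotypeSpec("g", 0.0, coverage=500, seed=9), 1.0, 0.4
        )
        oes = [hc.observed_over_expected(hc.balance(m)) for m in raw]
        rng = np.random.default_rng(9)
        null_track = BinnedTrack(g, rng.normal(size=g.n_bins))
        labels = sd.digitize_track(null_track, 5, 0.0)
        s = sd.saddle_matrix(oes, labels)
        assert np.nanmax(np.abs(s.saddle - 1.0)) < 0.1
        assert 0.9 < s.strength < 1.1
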