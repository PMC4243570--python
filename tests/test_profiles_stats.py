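"""Kaiser-Bessel gridding, peaks, and stratification statistics."""

import numpy as np
import pytest
import scipy.stats as sstats
from hypothesis import given, settings, strategies as st

from arbordepth.profiles_stats import (
    BIN_WIDTH_UM,
    DepthProfile,
    brown_forsythe,
    crest_factor,
    default_bin_centers,
    depth_profile,
    find_peaks,
    sigma_ci,
    signed_rank_right_p,
    snr,
    truncate_profile,
)


def _profile(mass, start=-20.0):
    mass = np.asarray(mass, dtype=float)
    centers = start + BIN_WIDTH_UM * np.arange(len(mass))
    return DepthProfile(centers, mass)


class TestGridding:
    def test_single_point_conserves_mass_and_peaks_at_itself(self):
        p = depth_profile(np.array([0.0]), np.array([1.0]))
        assert p.total() == pytest.approx(1.0, abs=1e-9)
        assert p.centers[np.argmax(p.mass)] == 0.0

    def test_total_mass_equals_total_weight(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(-15, 20, size=500)
        w = rng.uniform(0.5, 2.0, size=500)
        p = depth_profile(d, w)
        assert p.total() == pytest.approx(w.sum(), rel=1e-6)

    def test_close_to_nearest_bin_histogram(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(-18, 23, size=10_000)
        p = depth_profile(d)
        centers = default_bin_centers()
        # independent oracle: plain nearest-bin counting
        nearest = np.zeros_like(centers)
        idx = np.clip(np.round((d - centers[0]) / BIN_WIDTH_UM).astype(int),
                      0, len(centers) - 1)
        np.add.at(nearest, idx, 1.0)
        l1 = np.abs(p.mass - nearest).sum()
        assert l1 < 0.05 * len(d)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.floats(-19.0, 24.0), st.floats(0.01, 5.0)),
                    min_size=1, max_size=40))
    def test_mass_conservation_for_arbitrary_samples(self, samples):
        d = np.array([s[0] for s in samples])
        w = np.array([s[1] for s in samples])
        p = depth_profile(d, w)
        assert p.total() == pytest.approx(w.sum(), rel=1e-9)
        assert np.all(p.mass >= 0)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            depth_profile(np.array([]))
        with pytest.raises(ValueError):
            depth_profile(np.array([1.0]), np.array([0.0]))

    def test_normalization_is_idempotent(self):
        p = depth_profile(np.array([1.0, 2.0, 3.0]))
        n1 = p.normalize()
        n2 = n1.normalize()
        assert np.linalg.norm(n1.mass) == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(n1.mass, n2.mass)


class TestFindPeaks:
    def test_bistratified_phantom_modes(self):
        # bimodal profile with modes at 0.3 and 12.3 μm (grid origin shifted
        # so those depths are representable bin centers)
        centers = -19.7 + BIN_WIDTH_UM * np.arange(91)
        mass = (np.exp(-((centers - 0.3) ** 2) / 0.5)
                + 0.8 * np.exp(-((centers - 12.3) ** 2) / 0.5))
        r = find_peaks(DepthProfile(centers, mass), bistratified=True)
        assert r.peak1 == pytest.approx(0.3)
        assert r.peak2 == pytest.approx(12.3)

    def test_unimodal_second_peak_respects_exclusion(self):
        centers = default_bin_centers()
        mass = np.exp(-((centers - 5.5) ** 2) / 8.0)
        r = find_peaks(DepthProfile(centers, mass), bistratified=True)
        assert r.peak1 == 5.5
        assert abs(r.peak2 - r.peak1) >= 6.0
        far = np.abs(centers - 5.5) >= 6.0
        assert mass[centers == r.peak2][0] == mass[far].max()

    def test_tie_breaks_toward_smaller_depth(self):
        mass = np.zeros(91)
        mass[30] = mass[60] = 1.0
        p = _profile(mass)
        assert find_peaks(p).peak1 == p.centers[30]

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        mass = rng.random(91)
        p = _profile(mass)
        shifted = DepthProfile(p.centers + 2.0, mass)
        r0, r1 = find_peaks(p, True), find_peaks(shifted, True)
        assert r1.peak1 == pytest.approx(r0.peak1 + 2.0)
        assert r1.peak2 == pytest.approx(r0.peak2 + 2.0)

    def test_truncation_drops_ganglion_side_bins(self):
        mass = np.ones(91)
        t = truncate_profile(_profile(mass), -6.0)
        assert t.centers.min() == -6.0
        assert len(t.mass) == 63


class TestCrestFactor:
    def test_constant_profile_is_one(self):
        assert crest_factor(_profile(np.full(40, 3.3))) == pytest.approx(1.0)

    def test_single_spike_among_100_bins(self):
        mass = np.zeros(100)
        mass[17] = 7.0
        assert crest_factor(_profile(mass)) == pytest.approx(10.0)

    def test_scale_invariance_and_mean_variant(self):
        rng = np.random.default_rng(6)
        p = _profile(rng.random(50))
        scaled = _profile(p.mass * 37.0)
        assert crest_factor(scaled) == pytest.approx(crest_factor(p))
        assert crest_factor(p, "mean") >= crest_factor(p)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            crest_factor(_profile(np.zeros(10)))


class TestSnr:
    def test_two_orthogonal_unit_profiles(self):
        a = np.zeros(10)
        b = np.zeros(10)
        a[0] = b[1] = 1.0
        # signal = (a+b)/2 has norm sqrt(2)/2, each noise has the same norm
        assert snr([a, b]) == pytest.approx(1.0)

    def test_snr_grows_as_noise_shrinks(self):
        sig = np.ones(8) / np.sqrt(8)
        orth = np.zeros(8)
        orth[0], orth[1] = 1 / np.sqrt(2), -1 / np.sqrt(2)
        values = []
        for eps in (0.3, 0.1, 0.03):
            values.append(snr([sig + eps * orth, sig - eps * orth]))
        assert values[0] < values[1] < values[2]

    def test_identical_profiles_rejected(self):
        a = np.ones(5)
        with pytest.raises(ValueError):
            snr([a, a.copy()])


class TestSigmaCI:
    def test_zero_sd_collapses(self):
        ci = sigma_ci(0.0, 8)
        assert ci.lo == 0.0 and ci.hi == 0.0

    def test_known_value_n15(self):
        # s = 0.23, n = 15 against an independent chi-square evaluation
        ci = sigma_ci(0.23, 15)
        lo = np.sqrt(14 * 0.23**2 / sstats.chi2.ppf(0.975, 14))
        hi = np.sqrt(14 * 0.23**2 / sstats.chi2.ppf(0.025, 14))
        assert ci.lo == pytest.approx(lo, abs=1e-12)
        assert ci.hi == pytest.approx(hi, abs=1e-12)
        assert ci.lo == pytest.approx(0.168, abs=0.002)
        assert ci.hi == pytest.approx(0.363, abs=0.002)
        assert ci.lo <= ci.s <= ci.hi

    def test_interval_shrinks_with_sample_size(self):
        wide = sigma_ci(0.4, 10)
        narrow = sigma_ci(0.4, 100)
        assert (narrow.hi - narrow.lo) < (wide.hi - wide.lo)

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError):
            sigma_ci(0.3, 1)


class TestBrownForsythe:
    def test_identical_deviation_sets_give_f_zero(self):
        f, p = brown_forsythe([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_anova(self):
        g1, g2 = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]
        d1 = np.abs(np.array(g1) - np.median(g1))
        d2 = np.abs(np.array(g2) - np.median(g2))
        grand = np.concatenate([d1, d2]).mean()
        ssb = 4 * ((d1.mean() - grand) ** 2 + (d2.mean() - grand) ** 2)
        ssw = ((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()
        f_hand = (ssb / 1) / (ssw / 6)
        f, p = brown_forsythe(g1, g2)
        assert f == pytest.approx(f_hand, rel=1e-12)
        assert p == pytest.approx(sstats.f.sf(f_hand, 1, 6), rel=1e-12)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            brown_forsythe([1.0, 1.0], [2.0, 2.0])


class TestSignedRank:
    def test_three_pairs_rank_sum_two(self):
        # |d| ranks 1..3; the positive difference holds rank 2, so W+ = 2
        # and 6 of the 8 sign patterns reach W >= 2
        assert signed_rank_right_p([2.0, -1.0, -3.0]) == pytest.approx(0.75)

    def test_all_negative_gives_one(self):
        assert signed_rank_right_p([-0.5, -1.5, -2.5]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_exact_reference_for_n10(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=10)
        ref = sstats.wilcoxon(d, alternative="greater", mode="exact").pvalue
        assert signed_rank_right_p(d) == pytest.approx(ref, abs=1e-12)

    def test_zero_difference_refused(self):
        with pytest.raises(ValueError):
            signed_rank_right_p([0.0, 1.0])
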