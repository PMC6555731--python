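"""Sarcomere period estimation, striation counting, and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import autocorr_period
from sarcoquant.errors import ProfileError, ValidationError
from sarcoquant.morphometry import (
    IntensityProfile, PeriodSearchRange, SeriesResult, compare_groups,
    count_series, estimate_period_fft, extract_profile, fraction_sarcomeric,
)
from sarcoquant.synthetic import (
    StriationSimConfig, simulate_striation_image, simulate_striation_profile,
)


def _peaks_profile(spacings, n=None, pixel=0.1):
    """Profile with unit impulses at cumulative spacings on a zero baseline."""
    idx = np.cumsum([10] + list(spacings))
    y = np.zeros(int(idx[-1]) + 10)
    y[idx] = 1.0
    return IntensityProfile(y, pixel)


class TestPeriodEstimation:
    def test_pure_cosine_recovered_to_hundredth_um(self, cosine_profile_24):
        est = estimate_period_fft(cosine_profile_24)
        assert est.in_range and est.period_um is not None
        assert abs(est.period_um - 2.4) <= 0.02

    def test_out_of_window_period_absent(self):
        p = simulate_striation_profile(StriationSimConfig(5.0, 0.1, 512, noise_sd=0))
        est = estimate_period_fft(p)
        assert est.period_um is None and not est.in_range

    def test_constant_profile_absent(self):
        est = estimate_period_fft(IntensityProfile(np.full(256, 3.0), 0.1))
        assert est.period_um is None and not est.in_range

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), offset=st.floats(-50.0, 50.0))
    def test_scale_and_offset_invariance(self, cosine_profile_24, scale, offset):
        base = estimate_period_fft(cosine_profile_24)
        scaled = IntensityProfile(
            cosine_profile_24.intensities * scale + offset, 0.1)
        est = estimate_period_fft(scaled)
        assert est.period_um == base.period_um
        assert est.peak_power == pytest.approx(base.peak_power, rel=1e-9)

    def test_resolution_consistency(self, cosine_profile_24):
        fine = simulate_striation_profile(
            StriationSimConfig(2.4, 0.05, 1024, noise_sd=0))
        e1 = estimate_period_fft(cosine_profile_24)
        e2 = estimate_period_fft(fine)
        assert abs(e1.period_um - e2.period_um) / e1.period_um < 0.005

    def test_agrees_with_autocorrelation_oracle_noiseless(self):
        rng = np.random.default_rng(7)
        for i in range(50):
            period = rng.uniform(1.8, 3.2)
            p = simulate_striation_profile(
                StriationSimConfig(period, 0.1, 512, noise_sd=0, seed=i))
            est = estimate_period_fft(p)
            oracle = autocorr_period(p)
            nfft = 2048
            bin_tol = est.period_um**2 * (1.0 / (nfft * 0.1))
            assert abs(est.period_um - oracle) <= bin_tol

    def test_noisy_recovery_mae(self):
        # noise sd = amplitude/2: mean absolute error <= 0.05 um over 100 seeds
        errs = []
        for seed in range(100):
            p = simulate_striation_profile(
                StriationSimConfig(2.0, 0.1, 512, amplitude=100,
                                   noise_sd=50, seed=seed))
            est = estimate_period_fft(p)
            assert est.period_um is not None
            errs.append(abs(est.period_um - 2.0))
        assert np.mean(errs) <= 0.05

    def test_error_monotone_in_noise(self):
        maes = []
        for noise_sd in (10.0, 50.0, 100.0):
            errs = []
            for seed in range(100):
                p = simulate_striation_profile(
                    StriationSimConfig(2.0, 0.1, 512, amplitude=100,
                                       noise_sd=noise_sd, seed=seed))
                est = estimate_period_fft(p)
                if est.period_um is not None:
                    errs.append(abs(est.period_um - 2.0))
            maes.append(np.mean(errs))
        assert maes[0] <= maes[1] <= maes[2]

    def test_validation(self):
        with pytest.raises(ProfileError):
            IntensityProfile(np.ones(4), 0.1)
        with pytest.raises(ProfileError):
            IntensityProfile(np.array([1.0, np.nan] + [0.0] * 8), 0.1)
        p = IntensityProfile(np.ones(64), 1.0)
        with pytest.raises(ProfileError):  # window below Nyquist at 1 um/px
            estimate_period_fft(p, PeriodSearchRange(1.6, 3.4))
        with pytest.raises(ValidationError):
            PeriodSearchRange(3.4, 1.6)


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        img = np.full((40, 60), 5.0)
        prof = extract_profile(img, (2, 10), (50, 10), pixel_size_um=0.2)
        assert np.allclose(prof.intensities, 5.0)

    def test_axis_aligned_stripes_period_in_samples(self):
        cfg = StriationSimConfig(2.4, 0.1, 256, noise_sd=0)
        img = simulate_striation_image(cfg, width_px=32)
        prof = extract_profile(img, (0, 16), (240, 16), pixel_size_um=0.1)
        # 24-sample period preserved exactly on the lattice
        assert np.allclose(prof.intensities[:-24], prof.intensities[24:], atol=1e-9)
        est = estimate_period_fft(prof)
        assert abs(est.period_um - 2.4) < 0.02

    def test_oblique_line_on_oblique_stripes(self):
        cfg = StriationSimConfig(2.4, 0.1, 400, noise_sd=0)
        img = simulate_striation_image(cfg, width_px=200, orientation_deg=30.0)
        c, s = np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30))
        L = 180
        prof = extract_profile(img, (5, 5), (5 + L * c, 5 + L * s), 0.1)
        est = estimate_period_fft(prof)
        assert est.period_um is not None
        assert abs(est.period_um - 2.4) / 2.4 < 0.02

    def test_along_stripe_direction_no_peak(self):
        cfg = StriationSimConfig(2.4, 0.1, 256, noise_sd=0)
        img = simulate_striation_image(cfg, width_px=128, orientation_deg=0.0)
        prof = extract_profile(img, (100, 5), (100, 120), 0.1)  # vertical line
        est = estimate_period_fft(prof)
        assert est.period_um is None

    def test_endpoint_validation(self):
        img = np.zeros((20, 20))
        with pytest.raises(ProfileError):
            extract_profile(img, (-1, 0), (10, 0), 0.1)
        with pytest.raises(ProfileError):
            extract_profile(img, (0, 0), (0, 0), 0.1)


class TestCountSeries:
    def test_twenty_even_peaks_qualify(self):
        prof = _peaks_profile([15] * 19)
        res = count_series(prof)
        assert res == SeriesResult(20, True, 15)

    def test_ten_peaks_do_not_qualify(self):
        res = count_series(_peaks_profile([15] * 9))
        assert res.n_striations_in_series == 10 and not res.qualifies

    def test_spacing_outlier_breaks_the_run(self):
        # 20 peaks, one 3x-median spacing in the middle: the longest
        # consistent run is the 10-peak block after the outlier
        spacings = [15] * 9 + [45] + [15] * 9
        res = count_series(_peaks_profile(spacings))
        assert res.n_striations_in_series == 10
        assert res.n_striations_in_series < 20

    def test_constant_profile_counts_zero(self):
        res = count_series(IntensityProfile(np.full(64, 2.0), 0.1))
        assert res.n_striations_in_series == 0 and not res.qualifies

    def test_threshold_boundary(self):
        assert count_series(_peaks_profile([15] * 14)).qualifies  # 15 peaks
        assert not count_series(_peaks_profile([15] * 13)).qualifies


class TestFractionSarcomeric:
    @pytest.mark.parametrize("flags,expected", [
        ((True, True, True, False), 0.75),
        ((False, False), 0.0),
        ((True, True), 1.0),
    ])
    def test_fraction(self, flags, expected):
        results = [SeriesResult(20 if q else 3, q, 15) for q in flags]
        assert fraction_sarcomeric(results) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            fraction_sarcomeric([])


class TestCompareGroups:
    def test_identical_groups_null(self):
        res = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_statistic == 0.0
        assert res.anova_p == 1.0
        assert set(res.pairwise) == {("a", "b")}

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups({"a": [1.0], "b": [1, 2]})
        with pytest.raises(ValidationError):
            compare_groups({"a": [1, 2]})

    def test_null_rejection_rate_near_alpha(self, rng):
        # three groups, equal means and variances: ANOVA size ~ 0.05
        rej = 0
        n_sim = 2000
        for _ in range(n_sim):
            groups = {k: rng.normal(0, 1, 25) for k in "abc"}
            if compare_groups(groups).anova_p < 0.05:
                rej += 1
        assert 0.03 <= rej / n_sim <= 0.07

    def test_pairwise_covers_all_pairs(self, rng):
        groups = {k: rng.normal(0, 1, 8) for k in "abcd"}
        res = compare_groups(groups)
        assert len(res.pairwise) == 6
        assert all(0 <= p <= 1 for p in res.pairwise.values())
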