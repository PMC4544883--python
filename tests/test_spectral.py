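"""Periodogram correctness against a direct projection oracle, Parseval,
band arithmetic and peak detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trichron as tc
from trichron.errors import BandError, DegenerateSpectrumError, LengthError

from conftest import make_series


def projection_periodogram(x):
    """O(n^2) oracle: ordinates from direct sine/cosine projections of the
    mean-removed series, normalised so they sum to the sample variance."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    t = np.arange(n)
    freqs, power = [], []
    for k in range(1, n // 2 + 1):
        w = 2.0 * math.pi * k / n
        c = sum(xc[i] * math.cos(w * i) for i in t)
        s = sum(xc[i] * math.sin(w * i) for i in t)
        p = (c * c + s * s) * 2.0 / n**2
        if n % 2 == 0 and k == n // 2:
            p /= 2.0
        freqs.append(w)
        power.append(p)
    return np.array(freqs), np.array(power)


class TestPeriodogram:
    @pytest.mark.parametrize("n", [8, 9, 16, 27, 64, 101, 128])
    def test_matches_projection_oracle(self, n, rng):
        x = rng.uniform(0.05, 0.5, size=n)
        spec = tc.periodogram(x)
        freqs, power = projection_periodogram(x)
        np.testing.assert_allclose(spec.frequencies, freqs, rtol=1e-12)
        np.testing.assert_allclose(spec.power, power, rtol=1e-9, atol=1e-18)

    def test_constant_series_zero_power(self):
        spec = tc.periodogram(make_series([0.2] * 64))
        np.testing.assert_allclose(spec.power, 0.0, atol=1e-20)

    def test_grid_cosine_single_ordinate(self, grid_cosine):
        series, freq = grid_cosine
        spec = tc.periodogram(series)
        at_peak = np.isclose(spec.frequencies, freq)
        assert at_peak.sum() == 1
        np.testing.assert_allclose(spec.power[~at_peak], 0.0, atol=1e-18)
        # the single ordinate carries the whole sample variance
        assert spec.power[at_peak][0] == pytest.approx(
            np.var(series.widths), rel=1e-9
        )

    def test_too_short_series(self):
        with pytest.raises(LengthError):
            tc.periodogram(make_series([0.2] * 7))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=8, max_value=96),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_parseval_property(self, n, seed):
        x = np.random.default_rng(seed).uniform(0.01, 1.0, size=n)
        spec = tc.periodogram(x)
        assert spec.total_variance == pytest.approx(np.var(x), rel=1e-9)


class TestFindPeak:
    def test_single_bin_band(self, grid_cosine):
        series, _ = grid_cosine
        spec = tc.periodogram(series)
        band = tc.Band(spec.frequencies[2] - 1e-9, spec.frequencies[2] + 1e-9)
        assert tc.find_peak(spec, band).frequency == spec.frequencies[2]

    def test_tie_broken_to_lower_frequency(self):
        # hand-built spectrum with two exactly equal maxima
        n = 16
        freqs = 2 * math.pi * np.arange(1, n // 2 + 1) / n
        power = np.full(freqs.size, 0.1)
        power[2] = power[5] = 1.0
        spec = tc.Spectrum(n=n, frequencies=freqs, power=power)
        peak = tc.find_peak(spec, tc.Band(0, math.pi))
        assert peak.frequency == pytest.approx(freqs[2], rel=1e-12)

    def test_empty_band_overlap(self, grid_cosine):
        series, _ = grid_cosine
        spec = tc.periodogram(series)
        with pytest.raises(BandError):
            tc.find_peak(spec, tc.Band(0.0, spec.frequencies[0] / 2))

    def test_synthetic_lf_peak_recovered(self):
        params = tc.SyntheticParams(
            n=504, mean_width=0.214, daily_amp=0.0, weekly_amp=0.04,
            noise_sd=0.02, seed=7,
        )
        spec = tc.periodogram(tc.generate_ri_series(params))
        peak = tc.find_peak(spec, tc.default_lf_band())
        assert abs(peak.frequency - 0.045) <= spec.bin_width


class TestBandVariance:
    def test_whole_grid_equals_sample_variance(self, rng):
        x = rng.uniform(0.05, 0.5, size=100)
        spec = tc.periodogram(x)
        assert tc.band_variance(spec, tc.Band(0, math.pi)) == pytest.approx(
            np.var(x), rel=1e-9
        )

    def test_additive_over_disjoint_bands(self, rng):
        x = rng.uniform(0.05, 0.5, size=100)
        spec = tc.periodogram(x)
        b1, b2 = tc.Band(0, 1.0), tc.Band(1.0, math.pi)
        assert tc.band_variance(spec, b1) + tc.band_variance(
            spec, b2
        ) == pytest.approx(tc.band_variance(spec, tc.Band(0, math.pi)), rel=1e-12)

    def test_band_excluding_tone_is_zero(self, grid_cosine):
        series, freq = grid_cosine
        spec = tc.periodogram(series)
        assert tc.band_variance(spec, tc.Band(freq + 0.01, math.pi)) == pytest.approx(
            0.0, abs=1e-18
        )


class TestLfhfSummary:
    def test_equal_power_ratio_one(self):
        n = 64
        t = np.arange(n)
        f_lf, f_hf = 2 * math.pi * 1 / n, 2 * math.pi * 20 / n
        x = 1.0 + 0.1 * np.cos(f_lf * t) + 0.1 * np.cos(f_hf * t)
        summary = tc.lfhf_summary(tc.periodogram(x))
        assert summary.lfhf_ratio == pytest.approx(1.0, rel=1e-9)

    def test_degenerate_when_hf_empty(self, rng):
        n = 64
        f_lf = 2 * math.pi * 1 / n  # 0.098 rad, inside the LF band
        x = 1.0 + 0.1 * np.cos(f_lf * np.arange(n))
        with pytest.raises(DegenerateSpectrumError):
            tc.lfhf_summary(tc.periodogram(x))

    def test_overlapping_bands_rejected(self, rng):
        x = rng.uniform(0.05, 0.5, size=64)
        with pytest.raises(BandError):
            tc.lfhf_summary(tc.periodogram(x), tc.Band(0, 0.5), tc.Band(0.3, 3.0))

    def test_sympathetic_preset_ratio_exceeds_control(self):
        control = tc.generate_ri_series(tc.preset_params("control", n=128, seed=11))
        case = tc.generate_ri_series(
            tc.preset_params("sympathetic_activation", n=128, seed=11)
        )
        r_control = tc.lfhf_summary(tc.periodogram(control)).lfhf_ratio
        r_case = tc.lfhf_summary(tc.periodogram(case)).lfhf_ratio
        assert r_case > r_control


class TestSlidingLfhf:
    def test_window_equal_n_gives_whole_series_ratio(self, rng):
        x = rng.uniform(0.05, 0.5, size=96)
        ratios = tc.sliding_lfhf_series(x, window=96, step=8)
        assert ratios.shape == (1,)
        assert ratios[0] == pytest.approx(
            tc.lfhf_summary(tc.periodogram(x)).lfhf_ratio
        )

    def test_count_formula(self, rng):
        x = rng.uniform(0.05, 0.5, size=200)
        ratios = tc.sliding_lfhf_series(x, window=64, step=8)
        assert ratios.size == (200 - 64) // 8 + 1

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            tc.sliding_lfhf_series(np.full(100, 0.2), window=64, step=8)

    def test_window_too_large(self, rng):
        with pytest.raises(LengthError):
            tc.sliding_lfhf_series(rng.uniform(0.1, 0.2, 50), window=64, step=8)
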