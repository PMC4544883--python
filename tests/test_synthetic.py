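"""Generator determinism, positivity, study geometry, spectral fidelity."""

import dataclasses
import math

import numpy as np
import pytest

import trichron as tc
from trichron.errors import ConfigurationError, DomainError
from trichron.synthetic import preset_params


class TestGenerateRiSeries:
    def test_zero_amplitudes_constant_series(self):
        params = tc.SyntheticParams(n=50, mean_width=0.2, daily_amp=0.0,
                                    weekly_amp=0.0, noise_sd=0.0, seed=1)
        series = tc.generate_ri_series(params)
        np.testing.assert_allclose(series.widths, 0.2)

    def test_fixed_seed_reproducible(self):
        params = tc.SyntheticParams(n=200, seed=42)
        a = tc.generate_ri_series(params)
        b = tc.generate_ri_series(params)
        np.testing.assert_array_equal(a.widths, b.widths)

    def test_all_widths_positive_under_heavy_noise(self):
        params = tc.SyntheticParams(n=500, mean_width=0.05, daily_amp=0.01,
                                    weekly_amp=0.0, noise_sd=0.05, seed=3)
        series = tc.generate_ri_series(params)
        assert np.all(series.widths > 0)

    def test_sample_mean_converges_to_mean_width(self):
        params = tc.SyntheticParams(n=10_000, mean_width=0.3, daily_amp=0.02,
                                    weekly_amp=0.01, noise_sd=0.02, seed=5)
        series = tc.generate_ri_series(params)
        tol = 3 * params.noise_sd / math.sqrt(params.n)
        assert abs(series.mean_width - 0.3) < 3 * tol  # sinusoid phase adds drift

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            tc.SyntheticParams(mean_width=-0.1)
        with pytest.raises(DomainError):
            tc.SyntheticParams(weekly_freq=0.5, daily_freq=0.3)

    def test_noiseless_spectrum_peaks_at_daily_frequency(self):
        for seed in range(10):
            params = tc.SyntheticParams(n=256, daily_amp=0.03, weekly_amp=0.0,
                                        noise_sd=0.0, seed=seed)
            spec = tc.periodogram(tc.generate_ri_series(params))
            peak = tc.find_peak(spec, tc.Band(0, math.pi))
            nearest = spec.frequencies[np.argmin(np.abs(spec.frequencies - 0.32))]
            assert peak.frequency == nearest

    def test_parameter_recovery_through_growth_rate(self):
        params = preset_params("zweeloo_long", n=504, seed=8)
        series = tc.generate_ri_series(params)
        peak = tc.find_peak(tc.periodogram(series), tc.default_hf_band())
        est = tc.growth_rate(params.mean_width, peak.frequency)
        implied = tc.growth_rate(params.mean_width, params.daily_freq)
        # one-bin frequency error propagated through the rate formula
        worst = tc.growth_rate(
            params.mean_width, params.daily_freq - 2 * math.pi / 504
        )
        assert abs(est.mm_per_day - implied.mm_per_day) <= (
            worst.mm_per_day - implied.mm_per_day
        ) + 1e-12


class TestPresets:
    def test_class_mean_widths(self):
        assert preset_params("zweeloo_short").mean_width == 0.132
        assert preset_params("zweeloo_long").mean_width == 0.214

    def test_sympathetic_scales_lf_and_noise(self):
        control = preset_params("control")
        symp = preset_params("sympathetic_activation")
        assert symp.weekly_amp == pytest.approx(2 * control.weekly_amp)
        assert symp.noise_sd == pytest.approx(1.5 * control.noise_sd)
        assert symp.daily_amp == control.daily_amp

    def test_unknown_preset(self):
        with pytest.raises(ConfigurationError):
            preset_params("nope")

    def test_ratio_contrast_over_paired_seeds(self):
        wins = 0
        reps = 200
        for seed in range(reps):
            c = tc.generate_ri_series(preset_params("control", n=128, seed=seed))
            s = tc.generate_ri_series(
                preset_params("sympathetic_activation", n=128, seed=10_000 + seed)
            )
            r_c = tc.lfhf_summary(tc.periodogram(c)).lfhf_ratio
            r_s = tc.lfhf_summary(tc.periodogram(s)).lfhf_ratio
            wins += r_s > r_c
        assert wins / reps >= 0.95


class TestGenerateStudy:
    def test_default_observation_totals(self):
        study = tc.generate_study(seed=1)
        assert study.n_control_observations == 212
        assert study.n_case_observations == 504
        assert len(study.controls) == 4
        assert len(study.cases) == 6

    def test_case_counts_proportional_to_remnant_length(self):
        study = tc.generate_study(seed=1)
        lengths = {r.hair_id: r.length_mm for r in study.case_remnants}
        counts = {s.hair_id: len(s) for s in study.cases}
        # longer remnant -> at least as many observations
        ordered = sorted(lengths, key=lengths.get)
        count_seq = [counts[h] for h in ordered]
        assert count_seq == sorted(count_seq)

    def test_remnant_lengths_are_reference_values(self):
        study = tc.generate_study(seed=0)
        assert sorted(r.length_mm for r in study.case_remnants) == [
            9.1, 10.4, 11.4, 12.2, 16.8, 17.9,
        ]

    def test_single_hair_groups(self):
        remnant = tc.HairRemnant("only", 10.0, tc.SizeClass.SHORT_MEDIUM)
        study = tc.generate_study(seed=2, n_control_hairs=1,
                                  control_total_obs=10, case_total_obs=10,
                                  remnants=[remnant])
        assert [len(s) for s in study.cases] == [10]
        assert [len(s) for s in study.controls] == [10]

    def test_study_deterministic_for_seed(self):
        a = tc.generate_study(seed=9)
        b = tc.generate_study(seed=9)
        for sa, sb in zip(a.cases + a.controls, b.cases + b.controls):
            np.testing.assert_array_equal(sa.widths, sb.widths)
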