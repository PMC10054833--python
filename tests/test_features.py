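"""Spectral, peak-valley, and feature-vector extraction."""

import cmath

import numpy as np
import pytest

from pdglove.features import (
    band_energy,
    bin_medication_label,
    extract_features,
    feature_table,
    peak_valley,
    spectral_summary,
    split_sections,
)
from pdglove.preprocess import UniformSignal, resample
from pdglove.synth import ParticipantProfile, generate_task_signal


def naive_band_power(x, fs, lo, hi):
    """Brute-force DFT band power: the independent spectral oracle."""
    x = [v - sum(x) / len(x) for v in x]
    n = len(x)
    total = 0.0
    for k in range(n // 2 + 1):
        Xk = sum(x[m] * cmath.exp(-2j * cmath.pi * k * m / n) for m in range(n))
        f = k * fs / n
        scale = 1.0 if k == 0 or (n % 2 == 0 and k == n // 2) else 2.0
        in_band = lo <= f < hi or (hi == fs / 2 and f == hi)
        if in_band:
            total += scale * abs(Xk) ** 2 / n**2
    return total


class TestBandEnergy:
    def test_agrees_with_brute_force_dft(self, rng):
        for _ in range(20):
            x = rng.standard_normal(64)
            for lo, hi in ((2.0, 5.0), (5.0, 10.0), (0.0, 32.0)):
                fast = band_energy(x, 64.0, lo, hi)
                slow = naive_band_power(list(x), 64.0, lo, hi)
                assert fast == pytest.approx(slow, rel=1e-6, abs=1e-12)

    def test_parseval_partition(self, rng):
        x = rng.standard_normal(300)
        bands = [(0.0, 2.0), (2.0, 5.0), (5.0, 10.0), (10.0, 32.0)]
        total = sum(band_energy(x, 64.0, lo, hi) for lo, hi in bands)
        assert total == pytest.approx(np.mean((x - x.mean()) ** 2), rel=1e-6)

    def test_sinusoid_lands_in_tremor_band(self):
        t = np.arange(640) / 64.0
        x = np.sin(2 * np.pi * 7.0 * t)
        total = np.mean((x - x.mean()) ** 2)
        assert band_energy(x, 64.0, 5.0, 10.0) >= 0.95 * total
        assert band_energy(x, 64.0, 2.0, 5.0) <= 0.01 * total

    def test_white_noise_power_proportional_to_bandwidth(self, rng):
        x = rng.standard_normal(64 * 60)
        narrow = band_energy(x, 64.0, 2.0, 5.0)
        wide = band_energy(x, 64.0, 5.0, 11.0)
        assert wide / narrow == pytest.approx(2.0, rel=0.2)

    def test_zero_signal_and_band_validation(self):
        assert band_energy(np.zeros(64), 64.0, 5.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            band_energy(np.zeros(64), 64.0, 5.0, 40.0)


class TestSpectralSummary:
    def test_pure_tone_centroid_and_peak(self):
        t = np.arange(640) / 64.0
        s = spectral_summary(np.sin(2 * np.pi * 7.0 * t), 64.0)
        bin_width = 64.0 / 640
        assert s.mean_frequency == pytest.approx(7.0, abs=bin_width)
        assert s.peak_frequency == pytest.approx(7.0, abs=bin_width)
        assert s.has_power

    def test_two_tone_centroid_is_midpoint(self):
        t = np.arange(640) / 64.0
        x = np.sin(2 * np.pi * 3.0 * t) + np.sin(2 * np.pi * 9.0 * t)
        s = spectral_summary(x, 64.0)
        assert s.mean_frequency == pytest.approx(6.0, abs=64.0 / 640)

    def test_zero_signal_flagged(self):
        s = spectral_summary(np.zeros(128), 64.0)
        assert s == (0.0, 0.0, False)


class TestPeakValley:
    def ft_signal(self, profile, fs_out=64.0, seed=0):
        ch, truth = generate_task_signal("FT", profile, "pre", fs=128.0,
                                         seed=seed, noise_scale=0.0)
        t_us = np.arange(len(ch["flex_index"])) * 1e6 / 128.0
        sig = resample(t_us, ch["flex_index"], fs_out)
        return sig.data["x"], truth

    def test_clean_train_recovered_exactly(self, zero_profile):
        x, truth = self.ft_signal(zero_profile)
        pv = peak_valley(x, 64.0)
        assert pv.n_peaks == 10
        true_interval = np.diff(truth.tap_times_s).mean()
        assert pv.intervals.mean() == pytest.approx(true_interval, rel=0.05)

    def test_monotone_ramp_has_no_peaks(self):
        pv = peak_valley(np.linspace(0, 1, 200), 64.0)
        assert pv.n_peaks == 0
        assert len(pv.intervals) == 0

    def test_decrementing_train_slope_matches_truth(self, brady_profile):
        x, truth = self.ft_signal(brady_profile, seed=3)
        pv = peak_valley(x, 64.0)
        truth_slope = np.polyfit(truth.tap_times_s, truth.tap_amplitudes, 1)[0]
        assert pv.amplitude_slope() < 0
        assert pv.amplitude_slope() == pytest.approx(truth_slope, rel=0.1)

    def test_alternation_invariants(self, rng):
        x = rng.standard_normal(500).cumsum()
        pv = peak_valley(x, 64.0)
        if pv.n_peaks >= 2:
            assert len(pv.valley_times) == pv.n_peaks - 1
            assert len(pv.intervals) == pv.n_peaks - 1
            order = np.sort(np.concatenate([pv.peak_times, pv.valley_times]))
            merged = np.empty(2 * pv.n_peaks - 1)
            merged[0::2] = pv.peak_times
            merged[1::2] = pv.valley_times
            assert np.array_equal(order, merged)  # strict alternation
        assert np.all(pv.amplitudes >= 0)


class TestSplitSections:
    @pytest.mark.parametrize("n, k, lengths", [
        (300, 3, [100, 100, 100]),
        (301, 3, [101, 100, 100]),
        (640, 2, [320, 320]),
    ])
    def test_lengths(self, n, k, lengths):
        parts = split_sections(np.arange(n), k)
        assert [len(p) for p in parts] == lengths
        assert np.array_equal(np.concatenate(parts), np.arange(n))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            split_sections(np.arange(2), 3)


class TestExtractFeatures:
    def make_segment(self, task, profile, med_state, seed=0, noise=0.0):
        ch, _ = generate_task_signal(task, profile, med_state, fs=128.0,
                                     seed=seed, noise_scale=noise)
        n = len(ch["pitch"])
        t_us = np.arange(n) * 1e6 / 128.0
        return resample(t_us, ch, 64.0)

    def test_zero_severity_ft_has_constant_amplitudes(self, zero_profile):
        seg = self.make_segment("FT", zero_profile, "pre")
        v = extract_features(seg, "FT", "left")
        assert v.features["ft_left_flex_index_whole_amp_std"] == pytest.approx(0.0, abs=1e-3)
        assert v.features["ft_left_flex_index_whole_amp_slope"] == pytest.approx(0.0, abs=1e-3)
        assert v.features["ft_left_flex_index_whole_peak_count"] == 10

    def test_tremor_band_energy_larger_pre_medication(self, tremor_profile):
        pre = self.make_segment("RH", tremor_profile, "pre", seed=5)
        post = self.make_segment("RH", tremor_profile, "post", seed=5)
        fpre = extract_features(pre, "RH", "right").features
        fpost = extract_features(post, "RH", "right").features
        for half in ("h1", "h2"):
            assert fpre[f"rh_right_pitch_{half}_tremor_band"] > fpost[f"rh_right_pitch_{half}_tremor_band"]

    def test_bradykinetic_amplitude_declines_across_sections(self, brady_profile):
        seg = self.make_segment("FT", brady_profile, "pre", seed=9)
        f = extract_features(seg, "FT", "left").features
        assert f["ft_left_flex_index_end_amp_mean"] < f["ft_left_flex_index_start_amp_mean"]

    def test_all_features_finite_and_named_by_scheme(self, rng):
        profile = ParticipantProfile("P", tremor_severity=0.5, brady_severity=0.5,
                                     dyskinesia_severity=0.5)
        for task in ("FT", "OC", "HF", "HH", "FN", "RH"):
            seg = self.make_segment(task, profile, "post", seed=13, noise=1.0)
            v = extract_features(seg, task, "right")
            assert v.features
            for name, value in v.features.items():
                assert np.isfinite(value)
                assert name.startswith(f"{task.lower()}_right_")

    def test_unknown_task_rejected(self, zero_profile):
        seg = self.make_segment("FT", zero_profile, "pre")
        with pytest.raises(ValueError):
            extract_features(seg, "ZZ", "left")

    def test_feature_table_layout(self, zero_profile):
        seg = self.make_segment("RH", zero_profile, "pre")
        v = extract_features(seg, "RH", "left", participant_id="P01",
                             session_datetime="2024-01-15T09:00:00", med_state=0)
        table = feature_table([v])
        assert list(table.columns[:5]) == ["participant_id", "task", "hand",
                                           "session_datetime", "med_state"]
        assert table.loc[0, "med_state"] == 0


class TestMedicationBinning:
    @pytest.mark.parametrize("raw, label", [
        ("0–3 h", 0),   # en dash, as printed on the questionnaire
        ("0-3 h", 0),
        ("4+ h", 1),
        ("2 h", 0),
        (2, 0),
        (5.5, 1),
    ])
    def test_binning(self, raw, label):
        assert bin_medication_label(raw) == label

    def test_invert_switch(self):
        assert bin_medication_label("0-3 h", invert=True) == 1
        assert bin_medication_label("4+ h", invert=True) == 0

    def test_unknown_bin_rejected(self):
        with pytest.raises(ValueError):
            bin_medication_label("sometime yesterday")
        with pytest.raises(ValueError):
            bin_medication_label(-1)
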