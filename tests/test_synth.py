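"""Synthetic Parkinsonian-movement generator."""

import numpy as np
import pytest

from pdglove.features import band_energy
from pdglove.synth import (
    ParticipantProfile,
    generate_session,
    generate_task_signal,
    random_profile,
)
from pdglove.tasks import KINETIC_TASKS, TASK_ORDER


def total_power(x):
    x = x - x.mean()
    return float(np.mean(x**2))


class TestProfiles:
    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            ParticipantProfile("X", tremor_severity=1.5)
        with pytest.raises(ValueError):
            ParticipantProfile("X", tremor_freq_hz=2.0)
        with pytest.raises(ValueError):
            ParticipantProfile("X", med_dyskinesia_gain=-0.1)

    def test_random_profile_within_ranges(self, rng):
        for _ in range(20):
            p = random_profile(rng, "P")
            assert 0.2 <= p.tremor_severity <= 0.8
            assert 3.0 <= p.tremor_freq_hz <= 10.0


class TestTaskSignals:
    def test_zero_severity_ft_is_clean_constant_pulse_train(self, zero_profile):
        ch, truth = generate_task_signal("FT", zero_profile, "pre", seed=0, noise_scale=0.0)
        flex = ch["flex_index"]
        # ten pulses of constant amplitude
        assert len(truth.tap_times_s) == 10
        assert np.allclose(truth.tap_amplitudes, truth.tap_amplitudes[0])
        # essentially no energy in the tremor band (pulse train lives < 5 Hz)
        tremor = band_energy(flex, 128.0, 5.0, 10.0)
        assert tremor < 0.02 * total_power(flex)

    def test_tremor_peak_at_profile_frequency(self, tremor_profile):
        ch, _ = generate_task_signal("RH", tremor_profile, "pre", seed=3, noise_scale=0.0)
        x = ch["pitch"] - ch["pitch"].mean()
        freqs = np.fft.rfftfreq(len(x), 1 / 128.0)
        power = np.abs(np.fft.rfft(x)) ** 2
        assert abs(freqs[np.argmax(power)] - 7.0) <= 0.2

    @pytest.mark.parametrize("freq", [4.0, 7.0, 9.5])
    def test_spectral_placement_of_stationary_tremor(self, freq):
        profile = ParticipantProfile("T", tremor_severity=1.0, tremor_freq_hz=freq)
        ch, _ = generate_task_signal("HH", profile, "pre", seed=5, noise_scale=0.0)
        x = ch["pitch"]
        lo, hi = max(0.1, freq - 1.0), min(63.9, freq + 1.0)
        assert band_energy(x, 128.0, lo, hi) >= 0.9 * total_power(x)

    def test_full_bradykinesia_strictly_decreasing_amplitudes(self, brady_profile):
        _, truth = generate_task_signal("FT", brady_profile, "pre", seed=2)
        assert np.all(np.diff(truth.tap_amplitudes) < 0)

    def test_decrement_monotone_in_severity(self):
        ratios = []
        for sev in (0.0, 0.3, 0.6, 1.0):
            p = ParticipantProfile("B", brady_severity=sev)
            _, truth = generate_task_signal("FT", p, "pre", seed=4)
            ratios.append(truth.tap_amplitudes[-1] / truth.tap_amplitudes[0])
        assert np.all(np.diff(ratios) <= 0)

    def test_medication_modulates_generating_parameters(self, rng):
        profile = random_profile(rng, "P")
        _, pre = generate_task_signal("RH", profile, "pre", seed=6)
        _, post = generate_task_signal("RH", profile, "post", seed=6)
        assert pre.tremor_amp > post.tremor_amp
        assert post.dyskinesia_amp > pre.dyskinesia_amp == 0.0
        _, pre_ft = generate_task_signal("FT", profile, "pre", seed=6)
        _, post_ft = generate_task_signal("FT", profile, "post", seed=6)
        assert pre_ft.decrement > post_ft.decrement

    def test_dyskinesia_band_activity_post_only(self):
        profile = ParticipantProfile("D", dyskinesia_severity=1.0, med_dyskinesia_gain=1.0)
        pre, _ = generate_task_signal("RH", profile, "pre", seed=7, noise_scale=0.0)
        post, _ = generate_task_signal("RH", profile, "post", seed=7, noise_scale=0.0)
        assert band_energy(post["pitch"], 128.0, 2.0, 5.0) > 10 * band_energy(pre["pitch"], 128.0, 2.0, 5.0)

    def test_stationary_tasks_last_ten_seconds(self, zero_profile):
        for task in ("HH", "RH"):
            ch, truth = generate_task_signal(task, zero_profile, "pre", seed=0)
            assert truth.duration_s == pytest.approx(10.0)
            assert len(ch["pitch"]) == 1280

    def test_all_eleven_channels_emitted(self, zero_profile):
        ch, _ = generate_task_signal("OC", zero_profile, "pre", seed=0)
        assert len(ch) == 11

    def test_deterministic_under_fixed_seed(self, rng):
        profile = random_profile(rng, "P")
        a, _ = generate_task_signal("FN", profile, "post", seed=11)
        b, _ = generate_task_signal("FN", profile, "post", seed=11)
        for name in a:
            assert np.array_equal(a[name], b[name])

    def test_invalid_inputs_rejected(self, zero_profile, tremor_profile):
        with pytest.raises(ValueError):
            generate_task_signal("XX", zero_profile, "pre")
        with pytest.raises(ValueError):
            generate_task_signal("RH", tremor_profile, "pre", fs=10.0)  # aliasing
        with pytest.raises(ValueError):
            generate_task_signal("RH", zero_profile, "mid")


class TestSessions:
    def test_session_structure_and_truth(self, rng):
        profile = random_profile(rng, "P")
        session = generate_session(profile, "pre", seed=9)
        for hand in ("left", "right"):
            t = np.array([f.t for f in session.frames[hand]])
            assert np.all(np.diff(t) > 0)
            assert list(session.task_boundaries[hand]) == list(TASK_ORDER)
        for task in KINETIC_TASKS:
            assert len(session.truth[("left", task)].tap_times_s) == 10

    def test_zero_loss_keeps_every_sample(self, zero_profile):
        session = generate_session(zero_profile, "pre", loss_rate=0.0, seed=1)
        t = np.array([f.t for f in session.frames["left"]])
        assert np.allclose(np.diff(t), 1e6 / 128.0, atol=1.0)

    def test_loss_rate_yields_expected_effective_rate(self, rng):
        # 34.5% payload loss at 128 Hz -> ~84 Hz surviving, averaged over
        # the fixed-duration stationary windows of several sessions
        profile = random_profile(rng, "P")
        rates = []
        for seed in range(5):
            session = generate_session(profile, "pre", loss_rate=0.345, seed=seed)
            for hand in ("left", "right"):
                t = np.array([f.t for f in session.frames[hand]])
                for task in ("HH", "RH"):
                    a, b = session.task_boundaries[hand][task]
                    n = np.count_nonzero((t >= a) & (t <= b))
                    rates.append(n / 10.0)
        assert abs(np.mean(rates) - 84.0) <= 3.0

    def test_sessions_identical_under_same_seed(self, rng):
        profile = random_profile(rng, "P")
        a = generate_session(profile, "post", loss_rate=0.2, seed=21)
        b = generate_session(profile, "post", loss_rate=0.2, seed=21)
        assert a.frames == b.frames
        assert a.task_boundaries == b.task_boundaries

    def test_loss_rate_validated(self, zero_profile):
        with pytest.raises(ValueError):
            generate_session(zero_profile, "pre", loss_rate=1.0)
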