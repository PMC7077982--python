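"""Synthetic-data generators: determinism, spectral content, renewal
statistics, plant dynamics, and puncta ground truth."""

import numpy as np
import pytest

import tremorkit as tk


class TestDeterminism:
    def test_tremor_byte_identical(self):
        cfg = tk.harmaline_config(duration_s=5.0, seed=42)
        a = tk.gen_tremor_signal(cfg)
        b = tk.gen_tremor_signal(cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seed_differs(self):
        a = tk.gen_tremor_signal(tk.harmaline_config(duration_s=5.0, seed=1))
        b = tk.gen_tremor_signal(tk.harmaline_config(duration_s=5.0, seed=2))
        assert not np.array_equal(a.samples, b.samples)

    def test_spike_train_byte_identical(self):
        cfg = tk.SpikeSynthConfig(duration_s=30.0, seed=9)
        a = tk.gen_spike_train(cfg)
        b = tk.gen_spike_train(cfg)
        assert np.array_equal(a.times_s, b.times_s)
        assert np.array_equal(a.labels, b.labels)

    def test_emg_and_puncta_byte_identical(self):
        a = tk.gen_emg_signal(10.0, 2.0, seed=3)
        b = tk.gen_emg_signal(10.0, 2.0, seed=3)
        assert np.array_equal(a.samples, b.samples)
        img_a, truth_a = tk.gen_puncta_image(tk.PunctaSynthConfig(seed=3))
        img_b, truth_b = tk.gen_puncta_image(tk.PunctaSynthConfig(seed=3))
        assert np.array_equal(img_a, img_b)
        assert truth_a.count == truth_b.count


class TestTremorSignal:
    def test_harmaline_peak_at_12p5_hz(self, harmaline_trace):
        trace = tk.align_bins(tk.remove_offset(harmaline_trace), 0.25)
        ps = tk.power_spectrum(trace, 16384)
        peak = tk.peak_frequency(ps, 1.0, 25.0)
        assert abs(peak - 12.5) <= 0.25

    def test_peak_within_one_bin_across_seeds(self):
        hits = 0
        for seed in range(10):
            trace = tk.gen_tremor_signal(
                tk.harmaline_config(duration_s=30.0, seed=seed)
            )
            trace = tk.align_bins(tk.remove_offset(trace), 0.5)
            ps = tk.power_spectrum(trace, 8192)
            if abs(tk.peak_frequency(ps, 1.0, 25.0) - 12.5) <= 0.5:
                hits += 1
        assert hits == 10

    def test_null_signal(self):
        cfg = tk.TremorSynthConfig(
            duration_s=1.0, peak_amp_v=0.0, noise_floor_v=0.0
        )
        assert np.allclose(tk.gen_tremor_signal(cfg).samples, 0.0)

    def test_pure_sinusoid_variance(self):
        cfg = tk.TremorSynthConfig(
            duration_s=10.0, peak_amp_v=0.4, am_depth=0.0, noise_floor_v=0.0
        )
        trace = tk.gen_tremor_signal(cfg)
        assert np.var(trace.samples) == pytest.approx(0.4**2 / 2, rel=1e-3)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            tk.TremorSynthConfig(duration_s=1.0, mode="severe")

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            tk.TremorSynthConfig(duration_s=1.0, fs_hz=20.0, peak_freq_hz=12.5)

    def test_entrained_mode_follows_command(self):
        trace = tk.gen_tremor_signal(tk.entrained_config(7.0, duration_s=30.0, seed=2))
        trace = tk.align_bins(tk.remove_offset(trace), 0.5)
        ps = tk.power_spectrum(trace, 8192)
        assert abs(tk.peak_frequency(ps, 1.0, 25.0) - 7.0) <= 0.5


class TestSpikeTrainGenerator:
    def test_tonic_cv_matches_gamma_shape(self):
        cfg = tk.SpikeSynthConfig(duration_s=140.0, gamma_shape=4.0, seed=5)
        isis = tk.isi(tk.gen_spike_train(cfg), tk.SIMPLE)
        assert tk.cv(isis) == pytest.approx(0.5, rel=0.02)

    def test_isi_mean_within_2_percent(self, tonic_train_10k):
        isis = tk.isi(tonic_train_10k, tk.SIMPLE)
        assert isis.size >= 10_000
        assert isis.mean() == pytest.approx(1 / 77.63, rel=0.02)

    def test_near_infinite_shape_is_regular(self):
        cfg = tk.SpikeSynthConfig(
            duration_s=60.0, gamma_shape=1e6, cs_rate_hz=0.0, seed=1
        )
        isis = tk.isi(tk.gen_spike_train(cfg), tk.SIMPLE)
        assert tk.cv(isis) == pytest.approx(0.0, abs=0.01)
        assert tk.cv2(isis) == pytest.approx(0.0, abs=0.01)

    def test_bursts_led_by_complex_spike(self):
        cfg = tk.SpikeSynthConfig(duration_s=20.0, mode="bursting", seed=0)
        train = tk.gen_spike_train(cfg)
        cs_times = train.select(tk.COMPLEX)
        assert cs_times.size >= 2
        assert train.labels[0] == tk.COMPLEX
        # pause before each complex spike exceeds the intra-burst interval
        pre, post = tk.cs_pauses(train)
        assert pre > post

    def test_strictly_increasing_times(self, tonic_train_10k):
        assert np.all(np.diff(tonic_train_10k.times_s) > 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            tk.SpikeSynthConfig(duration_s=1.0, ss_rate_hz=-1.0)

    def test_bursting_needs_spikes(self):
        with pytest.raises(ValueError):
            tk.SpikeSynthConfig(duration_s=1.0, mode="bursting", spikes_per_burst=0)


class TestEmg:
    def test_spectral_peak_at_tremor_frequency(self):
        trace = tk.gen_emg_signal(10.0, 30.0, seed=1)
        trace = tk.align_bins(tk.remove_offset(trace), 0.5)
        ps = tk.power_spectrum(trace, 8192)
        assert abs(tk.peak_frequency(ps, 1.0, 25.0) - 10.0) <= 0.5

    def test_unmodulated_rate_has_no_line(self):
        mod = tk.gen_emg_signal(10.0, 30.0, seed=1)
        flat = tk.gen_emg_signal(10.0, 30.0, seed=1, mod_depth=0.0)

        def line_power(trace):
            trace = tk.align_bins(tk.remove_offset(trace), 0.5)
            ps = tk.power_spectrum(trace, 8192)
            return tk.band_power(ps, 9.5, 10.5).power_v2

        assert line_power(mod) > 10 * line_power(flat)

    def test_kernel_amplitude_squares_into_power(self):
        a = tk.gen_emg_signal(10.0, 10.0, seed=6, kernel_amp_v=1.0)
        b = tk.gen_emg_signal(10.0, 10.0, seed=6, kernel_amp_v=2.0)
        ps_a = tk.power_spectrum(tk.remove_offset(a), 8192)
        ps_b = tk.power_spectrum(tk.remove_offset(b), 8192)
        ratio = tk.band_power(ps_b, 8, 19.5).power_v2 / tk.band_power(
            ps_a, 8, 19.5
        ).power_v2
        assert ratio == pytest.approx(4.0, rel=1e-6)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            tk.gen_emg_signal(10.0, 1.0, fs_hz=500.0)


class TestPlant:
    def make_plant(self, **kw):
        tremor = tk.harmaline_config(duration_s=10.0, seed=3)
        return tk.PlantConfig(tremor=tremor, **kw)

    def test_stim_off_identity(self):
        plant = self.make_plant()
        n = int(plant.tremor.duration_s * plant.tremor.fs_hz)
        out = tk.run_plant(plant, np.zeros(n, dtype=bool))
        raw = tk.gen_tremor_signal(plant.tremor)
        assert np.array_equal(out.samples, raw.samples)

    def test_sustained_stim_reaches_floor_power(self):
        tremor = tk.harmaline_config(duration_s=20.0, seed=3, noise_floor_v=0.0)
        plant = tk.PlantConfig(
            tremor=tremor, suppression_tau_s=0.2, floor_fraction=0.3
        )
        n = int(tremor.duration_s * tremor.fs_hz)
        out = tk.run_plant(plant, np.ones(n, dtype=bool))
        raw = tk.gen_tremor_signal(tremor)
        tail = slice(n // 2, None)  # long after the suppression transient
        ratio = np.mean(out.samples[tail] ** 2) / np.mean(raw.samples[tail] ** 2)
        assert ratio == pytest.approx(0.3**2, rel=0.02)

    def test_envelope_monotone_during_on_epoch(self):
        tremor = tk.harmaline_config(
            duration_s=4.0, seed=0, noise_floor_v=0.0, am_depth=0.0
        )
        plant = tk.PlantConfig(tremor=tremor, suppression_tau_s=0.5)
        n = int(tremor.duration_s * tremor.fs_hz)
        stim = np.zeros(n, dtype=bool)
        stim[n // 4 : 3 * n // 4] = True
        out = tk.run_plant(plant, stim)
        x = out.samples[n // 4 : 3 * n // 4]
        # cycle-by-cycle peak amplitude decreases monotonically
        cycle = int(tremor.fs_hz / tremor.peak_freq_hz)
        peaks = [
            np.abs(x[i : i + cycle]).max() for i in range(0, len(x) - cycle, cycle)
        ]
        assert np.all(np.diff(peaks) <= 1e-12)

    def test_mismatched_length_rejected(self):
        plant = self.make_plant()
        with pytest.raises(ValueError):
            tk.run_plant(plant, np.zeros(10, dtype=bool))


class TestPunctaGenerator:
    def test_blank_image_when_no_puncta(self):
        cfg = tk.PunctaSynthConfig(n_puncta=0, noise_sigma=1.0, seed=0)
        image, truth = tk.gen_puncta_image(cfg)
        assert truth.count == 0
        assert image.max() < 10  # noise only

    def test_ground_truth_consistency(self):
        cfg = tk.PunctaSynthConfig(n_puncta=30, seed=8)
        image, truth = tk.gen_puncta_image(cfg)
        assert truth.count == 30
        assert truth.centers_px.shape == (30, 2)
        assert truth.areas_px.shape == (30,)
        assert 0 < truth.foreground_fraction < 1

    def test_clumped_pairs_recorded(self):
        cfg = tk.PunctaSynthConfig(n_puncta=20, clump_fraction=0.2, seed=8)
        _, truth = tk.gen_puncta_image(cfg)
        assert len(truth.touching_pairs) == 2
        for i, j in truth.touching_pairs:
            d = np.linalg.norm(truth.centers_px[i] - truth.centers_px[j])
            assert d < truth.radii_px[i] + truth.radii_px[j]  # overlapping

    def test_overfull_image_rejected(self):
        cfg = tk.PunctaSynthConfig(
            size_px=32, n_puncta=200, radius_px=5.0, seed=0
        )
        with pytest.raises(ValueError):
            tk.gen_puncta_image(cfg)
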