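"""Spectral reduction: trimming, amplitude spectra, SNR, oddball responses."""

import numpy as np
import pytest

from fpvs.cluster import AdjacencyGraph, build_adjacency
from fpvs.simulate import SimulationConfig, TrialRecording, make_layout, simulate_trial
from fpvs.spectral import (
    AmplitudeSpectrum,
    Epoch,
    OddballTargets,
    ResponseDataset,
    amplitude_spectrum,
    interpolate_channels,
    oddball_bins,
    oddball_response,
    snr_spectrum,
    trim_and_average,
)

FS = 250.0


def sine_epoch(freq, amplitude, duration, n_sensors=1, phase=0.0):
    t = np.arange(int(round(duration * FS))) / FS
    data = np.tile(amplitude * np.cos(2 * np.pi * freq * t + phase), (n_sensors, 1))
    return Epoch(data, FS)


class TestTrimAndAverage:
    def test_reference_trim_gives_58s_epoch_and_0171_grid(self):
        trials = [TrialRecording(np.zeros((2, int(60 * FS))), FS)]
        epoch = trim_and_average(trials, head_trim=1.667, tail_trim=0.0)
        assert epoch.duration == pytest.approx(58.333, abs=2e-3)
        spacing = amplitude_spectrum(epoch).bin_spacing
        assert round(spacing, 4) == 0.0171

    def test_full_trim_variant(self):
        trials = [TrialRecording(np.zeros((1, int(60 * FS))), FS)]
        epoch = trim_and_average(trials, head_trim=1.667, tail_trim=0.833)
        assert epoch.duration == pytest.approx(57.5, abs=2e-3)

    def test_mean_of_identical_trials_is_identity(self, rng):
        data = rng.normal(size=(3, 500))
        trials = [TrialRecording(data, FS) for _ in range(4)]
        epoch = trim_and_average(trials, 0.0, 0.0)
        assert np.allclose(epoch.data, data)

    def test_opposite_trials_cancel(self, rng):
        data = rng.normal(size=(2, 400))
        epoch = trim_and_average(
            [TrialRecording(data, FS), TrialRecording(-data, FS)], 0.0, 0.0
        )
        assert np.all(epoch.data == 0)

    def test_empty_and_mismatched_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            trim_and_average([], 0.0, 0.0)
        with pytest.raises(ValueError):
            trim_and_average(
                [
                    TrialRecording(rng.normal(size=(2, 100)), FS),
                    TrialRecording(rng.normal(size=(2, 99)), FS),
                ],
                0.0,
                0.0,
            )

    def test_excessive_trim_rejected(self):
        with pytest.raises(ValueError):
            trim_and_average([TrialRecording(np.zeros((1, 250)), FS)], 0.6, 0.5)


class TestAmplitudeSpectrum:
    def test_cosine_at_exact_bin_gives_half_amplitude(self):
        epoch = sine_epoch(freq=2.0, amplitude=3.0, duration=10.0)
        amp = amplitude_spectrum(epoch)
        k = 20
        assert amp.values[0, k] == pytest.approx(1.5, abs=1e-9)
        others = np.delete(amp.values[0], [0, k])
        assert np.all(others < 1e-9)

    def test_constant_signal_appears_at_dc(self):
        epoch = Epoch(np.full((1, 1000), -2.5), FS)
        amp = amplitude_spectrum(epoch)
        assert amp.values[0, 0] == pytest.approx(2.5)
        assert np.all(amp.values[0, 1:] < 1e-12)

    def test_grid_is_k_over_duration(self):
        epoch = sine_epoch(1.0, 1.0, 4.0)
        amp = amplitude_spectrum(epoch)
        assert np.allclose(amp.freq_grid, np.arange(len(amp.freq_grid)) / 4.0)

    def test_energy_concentrates_in_signal_bin(self):
        """Parseval-style check: one sinusoid owns >99.99% of non-DC energy."""
        epoch = sine_epoch(freq=3.4, amplitude=1.0, duration=10.0, phase=1.1)
        amp = amplitude_spectrum(epoch)
        energy = amp.values[0, 1:] ** 2
        k = 34
        assert energy[k - 1] / energy.sum() > 0.9999


class TestSNRSpectrum:
    def test_flat_spectrum_normalizes_to_one(self):
        amp = AmplitudeSpectrum(np.full((2, 101), 3.7), np.arange(101) * 0.1, 101)
        snr = snr_spectrum(amp)
        assert np.allclose(snr.values[:, snr.valid_mask], 1.0)
        assert np.all(np.isnan(snr.values[:, ~snr.valid_mask]))
        assert snr.valid_mask.sum() == 101 - 2 * 11

    def test_isolated_peak_reads_its_own_height(self):
        vals = np.ones((1, 101))
        vals[0, 50] = 21.0
        snr = snr_spectrum(AmplitudeSpectrum(vals, np.arange(101) * 0.1, 101))
        assert snr.values[0, 50] == pytest.approx(21.0)
        # the peak sits in the gap of its direct neighbors, so they stay ~1
        assert snr.values[0, 49] == pytest.approx(1.0)

    def test_peak_excluded_from_adjacent_bin_baseline_via_gap(self):
        vals = np.ones((1, 101))
        vals[0, 50] = 21.0
        snr = snr_spectrum(AmplitudeSpectrum(vals, np.arange(101) * 0.1, 101))
        # bin 49's baseline covers 37..47 and 51..61 -> includes nothing odd
        assert snr.values[0, 49] == pytest.approx(1.0)
        # bin 45's baseline (33..43, 47..57) contains the peak once
        assert snr.values[0, 45] == pytest.approx(1.0 / ((19 + 21) / 20))

    def test_scale_invariance(self, rng):
        epoch = Epoch(rng.normal(size=(3, 2000)), FS)
        a = snr_spectrum(amplitude_spectrum(epoch))
        scaled = Epoch(7.3 * epoch.data, FS)
        b = snr_spectrum(amplitude_spectrum(scaled))
        m = a.valid_mask
        assert np.allclose(a.values[:, m], b.values[:, m], atol=1e-12)

    def test_too_short_spectrum_rejected(self):
        amp = AmplitudeSpectrum(np.ones((1, 20)), np.arange(20) * 0.1, 20)
        with pytest.raises(ValueError):
            snr_spectrum(amp)


class TestOddballBins:
    def test_nearest_bin_rounding(self):
        grid = np.arange(100) * 0.1
        targets = oddball_bins(grid, 0.26, n_harmonics=1)
        assert targets.bins[0] == 3
        assert targets.freqs[0] == pytest.approx(0.3)

    def test_midway_tie_breaks_to_lower_bin(self):
        grid = np.arange(100) * 0.1
        targets = oddball_bins(grid, 0.25, n_harmonics=1)
        assert targets.bins[0] == 2

    def test_harmonics_are_exact_multiples_of_realized_fundamental(self):
        # a grid whose nearest bin to 1.2 Hz realizes 1.1962 Hz
        df = 1.1962 / 70
        grid = np.arange(2000) * df
        targets = oddball_bins(grid, 1.2, n_harmonics=4)
        assert list(targets.bins) == [70, 140, 210, 280]
        assert np.round(targets.freqs, 4).tolist() == [
            1.1962,
            2.3924,
            3.5886,
            4.7848,
        ]

    def test_target_beyond_grid_rejected(self):
        with pytest.raises(ValueError):
            oddball_bins(np.arange(10) * 0.1, 0.4, n_harmonics=4)


class TestOddballResponse:
    def make_snr(self, values_at_targets):
        vals = np.ones((1, 200))
        bins = np.array([30, 60, 90, 120])
        vals[0, bins] = values_at_targets
        amp = AmplitudeSpectrum(np.ones((1, 200)), np.arange(200) * 0.04, 200)
        snr = snr_spectrum(amp)
        snr.values[:] = 1.0
        snr.values[0, bins] = values_at_targets
        return snr, OddballTargets(bins=bins, freqs=bins * 0.04)

    def test_mean_of_constant_targets(self):
        snr, targets = self.make_snr([2.0, 2.0, 2.0, 2.0])
        assert oddball_response(snr, targets).values[0] == pytest.approx(2.0)

    def test_mean_of_varying_targets(self):
        snr, targets = self.make_snr([1.0, 2.0, 3.0, 4.0])
        assert oddball_response(snr, targets).values[0] == pytest.approx(2.5)

    def test_invalid_target_bin_named_in_error(self):
        snr, _ = self.make_snr([1.0, 2.0, 3.0, 4.0])
        bad = OddballTargets(bins=np.array([2]), freqs=np.array([0.08]))
        with pytest.raises(ValueError, match="bin 2"):
            oddball_response(snr, bad)


class TestAveragingReducesNoise:
    def test_noise_scales_inverse_sqrt_n_signal_unchanged(self):
        """Trial averaging: noise amplitude ~ 1/sqrt(N), signal bins fixed."""
        cfg = SimulationConfig(
            n_sensors=2,
            trial_duration=20.0,
            n_trials=1,
            base_amplitudes=(0.0,),
            oddball_amplitudes=(1.0,),
            noise_scale=0.0,
            white_scale=1.0,
            subject_sd=0.0,
        )
        phases = (np.zeros(1), np.zeros(1))
        k_sig = int(round(1.2 * 20))
        levels = {}
        sig = {}
        for n in (1, 4, 16):
            noise_amps, sig_amps = [], []
            for rep in range(12):
                trials = [
                    simulate_trial(cfg, 1.0, 1000 * n + 10 * rep + i, phases)
                    for i in range(n)
                ]
                amp = amplitude_spectrum(trim_and_average(trials, 0.0, 0.0))
                mask = np.ones(amp.values.shape[1], bool)
                mask[[0, k_sig]] = False
                noise_amps.append(amp.values[:, mask].mean())
                sig_amps.append(amp.values[0, k_sig])
            levels[n] = np.mean(noise_amps)
            sig[n] = np.mean(sig_amps)
        assert levels[1] / levels[4] == pytest.approx(2.0, rel=0.1)
        assert levels[4] / levels[16] == pytest.approx(2.0, rel=0.1)
        assert sig[1] == pytest.approx(0.5, abs=0.01)
        assert sig[16] == pytest.approx(0.5, abs=0.01)


class TestInterpolation:
    def test_neighbors_with_identical_signal_reproduce_it(self):
        lay = make_layout(16)
        adj = build_adjacency(lay)
        x = np.sin(np.linspace(0, 10, 200))
        data = np.tile(x, (16, 1))
        data[3] = 99.0
        fixed = interpolate_channels(TrialRecording(data, FS), {3}, adj)
        assert np.allclose(fixed.data[3], x)
        assert np.array_equal(fixed.data[4], data[4])

    def test_empty_bad_set_is_identity(self):
        lay = make_layout(8)
        adj = build_adjacency(lay)
        rec = TrialRecording(np.random.default_rng(0).normal(size=(8, 50)), FS)
        assert interpolate_channels(rec, set(), adj) is rec

    def test_equidistant_neighbors_average(self):
        positions = np.array(
            [[0.0, 0.0, 1.0], [0.1, 0.0, 1.0], [-0.1, 0.0, 1.0], [0.0, 0.5, 1.0]]
        )
        adj = AdjacencyGraph(
            neighbors=[{1, 2}, {0, 3}, {0, 3}, {1, 2}],
            positions=positions,
        )
        data = np.zeros((4, 10))
        data[1] = 0.0
        data[2] = 2.0
        fixed = interpolate_channels(TrialRecording(data, FS), {0}, adj)
        assert np.allclose(fixed.data[0], 1.0)

    def test_isolated_bad_sensor_rejected(self):
        lay = make_layout(5)
        adj = build_adjacency(lay)
        rec = TrialRecording(np.zeros((5, 10)), FS)
        bad = {0} | set(adj.neighbors[0])
        if len(bad) < 5:
            with pytest.raises(ValueError, match="no good neighbor"):
                interpolate_channels(rec, bad, adj)


class TestSerialization:
    def test_epoch_hdf5_roundtrip(self, tmp_path, rng):
        from fpvs.spectral import load_epoch, save_epoch

        epoch = Epoch(rng.normal(size=(3, 400)), FS)
        save_epoch(epoch, tmp_path / "epoch.h5")
        back = load_epoch(tmp_path / "epoch.h5")
        assert np.array_equal(back.data, epoch.data)
        assert back.sampling_rate == FS

    def test_spectrum_hdf5_roundtrip(self, tmp_path, rng):
        from fpvs.spectral import load_spectrum, save_spectrum

        amp = amplitude_spectrum(Epoch(rng.normal(size=(2, 300)), FS))
        save_spectrum(amp, tmp_path / "amp.h5")
        back = load_spectrum(tmp_path / "amp.h5")
        assert np.array_equal(back.values, amp.values)
        assert np.array_equal(back.freq_grid, amp.freq_grid)
        assert back.n_points == amp.n_points


class TestResponseDataset:
    def test_size_is_product_of_dimensions(self, rng):
        ds = ResponseDataset(
            rng.normal(size=(4, 2, 10)),
            list(range(4)),
            [0, 3],
            [f"s{i}" for i in range(10)],
        )
        assert ds.size == 80

    def test_long_tsv_roundtrip(self, tmp_path, rng):
        ds = ResponseDataset(
            rng.normal(size=(3, 2, 5)),
            list(range(3)),
            [0, 1],
            [f"MEG{i:03d}" for i in range(5)],
        )
        ds.write(tmp_path / "resp.tsv")
        back = ResponseDataset.read(tmp_path / "resp.tsv")
        assert np.allclose(back.tensor, ds.tensor)
        assert back.conditions == ds.conditions

    def test_condition_matrix_slices(self, rng):
        t = rng.normal(size=(3, 2, 4))
        ds = ResponseDataset(t, [0, 1, 2], [0, 3], list("abcd"))
        assert np.array_equal(ds.condition_matrix(3), t[:, 1, :])


class TestTopographyRecovery:
    def test_seeded_sensors_order_above_silent_ones(self):
        """Weight-1 sensors must outrank weight-0 sensors for strong effects."""
        topo = np.zeros(16)
        topo[[2, 5, 9]] = 1.0
        cfg = SimulationConfig(
            n_sensors=16,
            trial_duration=20.0,
            n_trials=2,
            topography=topo,
            oddball_amplitudes=(0.3, 0.2, 0.15, 0.1),
            subject_sd=0.0,
        )
        wins = 0
        for seed in range(20):
            phases = (
                np.random.default_rng(seed).uniform(0, 2 * np.pi, 2),
                np.random.default_rng(seed + 99).uniform(0, 2 * np.pi, 4),
            )
            trials = [
                simulate_trial(cfg, 1.0, 31 * seed + i, phases) for i in range(2)
            ]
            amp = amplitude_spectrum(trim_and_average(trials, 1.667, 0.0))
            snr = snr_spectrum(amp)
            targets = oddball_bins(amp.freq_grid, 1.2)
            resp = oddball_response(snr, targets).values
            if resp[topo == 1].mean() > resp[topo == 0].max():
                wins += 1
        assert wins == 20
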