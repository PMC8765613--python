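import numpy as np
import pytest

from odorosc import spectral
from odorosc.spectral import (AmplitudeStack, TrialTensor, amplitude_stack,
                              baseline_correct, build_filter_bank,
                              circular_shift_zmap, condition_difference_zmap,
                              decompose_evoked_induced, epoch)

FS = 500.0


class TestFilterBank:
    def test_endpoint_centers(self, bank):
        assert bank.centers[0] == pytest.approx(1.0)
        assert bank.centers[-1] == pytest.approx(200.0)

    def test_band_95_center(self, bank):
        assert round(bank.kept_centers[-1], 2) == 153.04

    def test_pac_subset_count_and_bounds(self, bank):
        idx = bank.pac_band_indices()
        centers = bank.kept_centers[idx]
        assert len(centers) == 47
        assert round(centers[0], 2) == 13.05
        assert round(centers[-1], 2) == 153.04

    def test_band_49_center(self, bank):
        assert round(bank.kept_centers[48], 2) == 13.05

    def test_centers_strictly_increasing(self, bank):
        assert np.all(np.diff(bank.centers) > 0)
        assert np.all(np.diff(bank.widths) > 0)


class TestAmplitudeStack:
    def test_unit_sinusoid_amplitude(self, bank):
        t = np.arange(int(40 * FS)) / FS
        x = np.sin(2 * np.pi * 19.0 * t)
        k = int(np.argmin(np.abs(bank.kept_centers - 19.0)))
        st = amplitude_stack(x, FS, bank, band_indices=np.array([k]))
        mid = st.amplitudes[0, int(5 * FS):-int(5 * FS)]
        assert abs(mid.mean() - 1.0) < 0.1
        assert np.ptp(mid) < 0.05

    def test_noise_amplitude_grows_with_bandwidth(self, bank):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(120 * FS))
        idx = np.array([30, 50, 70, 90])
        st = amplitude_stack(x, FS, bank, band_indices=idx)
        means = st.amplitudes.mean(axis=1)
        assert np.all(np.diff(means) > 0)

    def test_zero_signal_zero_amplitude(self, bank):
        st = amplitude_stack(np.zeros(4000), FS, bank, band_indices=np.array([40]))
        assert np.all(st.amplitudes == 0)

    def test_band_above_nyquist_skipped_with_warning(self, bank):
        x = np.random.default_rng(1).standard_normal(4000)
        with pytest.warns(UserWarning, match="Nyquist"):
            st = amplitude_stack(x, 250.0, bank, band_indices=np.array([40, 94]))
        assert len(st.band_centers) == 1

    def test_amplitudes_nonnegative(self, bank):
        x = np.random.default_rng(2).standard_normal(int(20 * FS))
        st = amplitude_stack(x, FS, bank, band_indices=np.array([10, 60]))
        assert np.all(st.amplitudes >= 0)


def toy_stack(n_seconds=60.0, n_bands=3, fill=None, seed=0):
    n = int(n_seconds * FS)
    if fill is None:
        data = np.abs(np.random.default_rng(seed).standard_normal((n_bands, n))) + 1.0
    else:
        data = np.full((n_bands, n), float(fill))
    return AmplitudeStack(data, np.arange(n_bands) + 1.0, FS)


class TestEpoch:
    def test_window_arithmetic(self):
        st = toy_stack()
        trials = epoch(st, np.array([10.0]), window=(-2.0, 4.0))
        assert trials.amplitudes.shape == (1, 3, 3000)
        assert trials.times[0] == pytest.approx(-2.0)
        assert trials.times[-1] == pytest.approx(4.0 - 1.0 / FS)

    def test_out_of_bounds_event_dropped(self):
        st = toy_stack()
        with pytest.warns(UserWarning, match="dropped 1"):
            trials = epoch(st, np.array([1.0, 30.0]), window=(-2.0, 4.0))
        assert trials.n_trials == 1
        assert trials.n_dropped == 1

    def test_constant_stack_identical_epochs(self):
        st = toy_stack(fill=5.0)
        trials = epoch(st, np.array([10.0, 20.0, 30.0]))
        assert np.all(trials.amplitudes == 5.0)
        np.testing.assert_array_equal(trials.amplitudes[0], trials.amplitudes[1])


class TestBaseline:
    def test_constant_amplitude_zeroed(self):
        st = toy_stack(fill=5.0)
        trials = epoch(st, np.array([10.0, 20.0]))
        out = baseline_correct(trials, st, np.array([8.0, 18.0]))
        assert np.allclose(out.amplitudes, 0.0)
        assert np.allclose(out.baseline_means, 5.0)

    def test_step_recovered(self):
        st = toy_stack(fill=1.0)
        st.amplitudes[:, int(10.0 * FS):] += 2.0
        trials = epoch(st, np.array([10.0]), window=(-1.0, 2.0))
        out = baseline_correct(trials, st, np.array([9.0]))
        post = out.amplitudes[0, :, out.times >= 0.1]
        assert np.allclose(post, 2.0)

    def test_baseline_mean_equals_direct_window_mean(self):
        st = toy_stack(seed=3)
        trials = epoch(st, np.array([12.0]))
        out = baseline_correct(trials, st, np.array([9.5]), window=(-0.55, -0.05))
        i0 = int(round((9.5 - 0.55) * FS))
        i1 = i0 + int(round(0.5 * FS))
        direct = st.amplitudes[:, i0:i1].mean(axis=1)
        np.testing.assert_allclose(out.baseline_means[0], direct)

    def test_missing_cue_excluded(self):
        st = toy_stack()
        trials = epoch(st, np.array([10.0, 20.0]))
        with pytest.warns(UserWarning, match="missing cue"):
            out = baseline_correct(trials, st, np.array([8.0, np.nan]))
        assert out.n_trials == 1


class TestCircularShiftZmap:
    def test_null_calibration(self):
        fracs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(300 * 100)
            st = AmplitudeStack(np.abs(rng.standard_normal((4, n))) + 1.0,
                                np.arange(4) + 1.0, 100.0)
            sniffs = np.sort(rng.uniform(15, 280, 24))
            z = circular_shift_zmap(st, sniffs, sniffs - 1.0,
                                    window=(-0.5, 1.0), baseline_window=(-0.4, -0.1),
                                    n_perm=300, q=0.05, seed=seed)
            fracs.append(z.significance_mask.mean())
        assert np.mean(fracs) <= 0.07

    def test_injected_burst_detected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            fs = 100.0
            n = int(300 * fs)
            data = np.abs(rng.standard_normal((2, n))) + 1.0
            sniffs = np.sort(rng.uniform(15, 280, 24))
            sniffs = sniffs[np.diff(np.concatenate([[0], sniffs])) > 3][:20]
            for s in sniffs:
                i0 = int((s + 0.1) * fs)
                data[0, i0:i0 + int(0.5 * fs)] += 3.0
            st = AmplitudeStack(data, np.array([1.0, 2.0]), fs)
            z = circular_shift_zmap(st, sniffs, sniffs - 1.0, window=(-0.5, 1.0),
                                    baseline_window=(-0.4, -0.1), n_perm=300,
                                    q=0.05, seed=seed)
            sel = (z.times >= 0.1) & (z.times <= 0.6)
            if z.significance_mask[0, sel].mean() > 0.5:
                hits += 1
        assert hits >= 4

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(0)
        n = int(200 * 100)
        base = np.abs(rng.standard_normal((2, n))) + 1.0
        sniffs = np.sort(rng.uniform(15, 180, 15))
        kwargs = dict(window=(-0.5, 1.0), baseline_window=(-0.4, -0.1),
                      n_perm=50, seed=1)
        z1 = circular_shift_zmap(AmplitudeStack(base, np.array([1.0, 2.0]), 100.0),
                                 sniffs, sniffs - 1.0, **kwargs)
        z2 = circular_shift_zmap(AmplitudeStack(base + 10.0, np.array([1.0, 2.0]), 100.0),
                                 sniffs, sniffs - 1.0, **kwargs)
        np.testing.assert_allclose(z1.z, z2.z, atol=1e-8)

    def test_too_short_recording_rejected(self):
        st = toy_stack(n_seconds=10.0)
        with pytest.raises(ValueError):
            circular_shift_zmap(st, np.array([4.0, 6.0]), np.array([3.0, 5.0]),
                                window=(-2.0, 4.0), n_perm=10)


class TestConditionDifferenceZmap:
    @staticmethod
    def toy_tensors(seed, na=15, nb=18, shift=0.0):
        rng = np.random.default_rng(seed)
        times = np.arange(100) / FS
        a = TrialTensor(rng.standard_normal((na, 3, 100)), times, np.arange(3) + 1.0)
        b = TrialTensor(rng.standard_normal((nb, 3, 100)) + shift, times,
                        np.arange(3) + 1.0)
        return a, b

    def test_null_calibration(self):
        fracs = []
        for seed in range(10):
            a, b = self.toy_tensors(seed)
            z = condition_difference_zmap(a, b, n_perm=300, seed=seed)
            fracs.append(z.significance_mask.mean())
        assert np.mean(fracs) <= 0.07

    def test_large_offset_fully_significant(self):
        a, b = self.toy_tensors(1, shift=-1.0)
        b.amplitudes += 0.0
        a.amplitudes += 1.0  # A = B + 2 after construction shift
        z = condition_difference_zmap(a, b, n_perm=300, seed=0)
        assert z.significance_mask.mean() > 0.95
        assert np.all(z.z > 0)

    def test_swap_antisymmetry(self):
        a, b = self.toy_tensors(2)
        z_ab = condition_difference_zmap(a, b, n_perm=200, seed=7)
        z_ba = condition_difference_zmap(b, a, n_perm=200, seed=7)
        # same label-shuffle family; z flips sign up to permutation noise
        assert np.corrcoef(z_ab.z.ravel(), -z_ba.z.ravel())[0, 1] > 0.95

    def test_empty_condition_rejected(self):
        a, b = self.toy_tensors(3)
        empty = TrialTensor(a.amplitudes[:0], a.times, a.band_centers)
        with pytest.raises(ValueError):
            condition_difference_zmap(a, empty, n_perm=10)


class TestEvokedInduced:
    def test_identical_trials_all_evoked(self, bank):
        fs = FS
        t = np.arange(int(3 * fs)) / fs
        wave = np.sin(2 * np.pi * 19.0 * t) * np.exp(-((t - 1.5) ** 2) / 0.1)
        epochs = np.tile(wave, (12, 1))
        k = int(np.argmin(np.abs(bank.kept_centers - 19.0)))
        evoked, induced, centers = decompose_evoked_induced(
            epochs, fs, bank, band_indices=np.array([k]))
        assert induced.amplitudes.max() < 0.05 * evoked.max()

    def test_random_phase_trials_all_induced(self, bank):
        fs = FS
        rng = np.random.default_rng(0)
        t = np.arange(int(3 * fs)) / fs
        epochs = np.stack([np.sin(2 * np.pi * 19.0 * t + rng.uniform(0, 2 * np.pi))
                           for _ in range(60)])
        k = int(np.argmin(np.abs(bank.kept_centers - 19.0)))
        evoked, induced, centers = decompose_evoked_induced(
            epochs, fs, bank, band_indices=np.array([k]))
        mid = slice(int(0.5 * fs), int(2.5 * fs))
        assert evoked[0, mid].max() < 0.2
        assert abs(induced.amplitudes[:, 0, mid].mean() - 1.0) < 0.15

    def test_mixture_recovers_both_components(self, bank):
        fs = FS
        rng = np.random.default_rng(1)
        t = np.arange(int(3 * fs)) / fs
        locked = np.sin(2 * np.pi * 7.0 * t)          # identical every trial
        epochs = np.stack([locked + np.sin(2 * np.pi * 40.0 * t
                                           + rng.uniform(0, 2 * np.pi))
                           for _ in range(60)])
        k7 = int(np.argmin(np.abs(bank.kept_centers - 7.0)))
        k40 = int(np.argmin(np.abs(bank.kept_centers - 40.0)))
        evoked, induced, centers = decompose_evoked_induced(
            epochs, fs, bank, band_indices=np.array([k7, k40]))
        mid = slice(int(0.5 * fs), int(2.5 * fs))
        ev = evoked[:, mid].mean(axis=1)
        ind = induced.amplitudes[:, :, mid].mean(axis=(0, 2))
        assert ev[0] > 3 * ev[1]      # locked component lives in the 7 Hz band
        assert ind[1] > 3 * ind[0]    # induced component lives in the 40 Hz band

    def test_few_trials_warns(self, bank):
        with pytest.warns(UserWarning, match="fewer than 5"):
            decompose_evoked_induced(np.random.default_rng(0).standard_normal((3, 500)),
                                     FS, bank, band_indices=np.array([40]))
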