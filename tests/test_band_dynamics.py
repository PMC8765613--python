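import numpy as np
import pytest

from odorosc import band_dynamics as dyn
from odorosc.spectral import TrialTensor, build_filter_bank

FS = 500.0


def tensor_with(centers, values):
    """(2 trials, bands, 50 samples) tensor with per-band constant values."""
    n_b = len(centers)
    amp = np.tile(np.asarray(values, dtype=float)[None, :, None], (2, 1, 50))
    return TrialTensor(amp, np.arange(50) / FS, np.asarray(centers, dtype=float))


class TestBandAverage:
    def test_constant_inside_band(self):
        t = tensor_with([5.0, 6.0, 20.0], [3.0, 3.0, 0.0])
        out = dyn.band_average(t, dyn.THETA)
        assert np.allclose(out, 3.0)

    def test_theta_selection_matches_enumerated_centers(self, bank):
        centers = bank.kept_centers
        expected = centers[(centers >= 4.0) & (centers <= 8.0)]
        t = TrialTensor(np.zeros((1, len(centers), 10)), np.arange(10) / FS, centers)
        sel = (t.band_centers >= dyn.THETA.lo) & (t.band_centers <= dyn.THETA.hi)
        np.testing.assert_array_equal(t.band_centers[sel], expected)
        assert len(expected) == int(np.sum((centers >= 4) & (centers <= 8)))

    def test_gamma_excludes_top_band(self, bank):
        centers = bank.kept_centers
        sel = (centers >= dyn.GAMMA.lo) & (centers <= dyn.GAMMA.hi)
        assert round(centers[-1], 2) == 153.04
        assert not sel[-1]

    def test_no_overlap_rejected(self):
        t = tensor_with([50.0], [1.0])
        with pytest.raises(ValueError):
            dyn.band_average(t, dyn.THETA)


class TestPercentChange:
    def test_arithmetic(self):
        # baseline-corrected amplitude 5 on baseline 10 -> 0.5
        series = np.full((1, 4), 5.0)
        assert np.allclose(dyn.percent_change(series, np.array([10.0])), 0.5)

    def test_zero_when_amplitude_equals_baseline(self):
        series = np.zeros((1, 4))
        assert np.allclose(dyn.percent_change(series, np.array([10.0])), 0.0)

    def test_scale_invariance(self):
        series = np.full((1, 4), 5.0)
        a = dyn.percent_change(series, np.array([10.0]))
        b = dyn.percent_change(2 * series, np.array([20.0]))
        np.testing.assert_allclose(a, b)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            dyn.percent_change(np.ones((1, 4)), np.array([0.0]))


class TestPointwiseTest:
    def test_identical_inputs_empty_mask(self):
        x = np.random.default_rng(0).standard_normal((10, 40))
        res = dyn.pointwise_condition_test(x, x.copy(), np.arange(40) / FS)
        assert not res.mask.any()
        assert res.onset is None

    def test_step_onset_latency(self):
        rng = np.random.default_rng(1)
        times = np.arange(200) / FS
        t0 = 0.2
        a = 0.01 * rng.standard_normal((20, 200))
        b = a + np.where(times >= t0, 5.0, 0.0)
        res = dyn.pointwise_condition_test(b, a, times)
        assert res.onset is not None
        assert abs(res.onset - t0) <= 3.0 / FS

    def test_fdr_never_rescues(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((12, 60))
        b = a + 0.5 * rng.standard_normal((12, 60))
        res = dyn.pointwise_condition_test(a, b, np.arange(60) / FS, q=0.05)
        assert np.all(res.p[res.mask] < 0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            dyn.pointwise_condition_test(np.ones((2, 5)), np.ones((2, 5)),
                                         np.arange(5) / FS)


class TestBootstrapMap:
    def test_fixed_seed_reproducible(self):
        x = np.random.default_rng(0).standard_normal((20, 30))
        m1 = dyn.bootstrap_band_map(x, reps=50, seed=9)
        m2 = dyn.bootstrap_band_map(x, reps=50, seed=9)
        np.testing.assert_array_equal(m1, m2)
        assert m1.shape == (50, 30)

    def test_column_sd_shrinks_with_trial_count(self):
        rng = np.random.default_rng(3)
        n = 50
        x1 = rng.standard_normal((n, 20))
        x4 = rng.standard_normal((4 * n, 20))
        s1 = dyn.bootstrap_band_map(x1, reps=800, seed=1).std(axis=0).mean()
        s4 = dyn.bootstrap_band_map(x4, reps=800, seed=1).std(axis=0).mean()
        assert abs(s1 / s4 - 2.0) < 0.4   # 1/sqrt(n) law within 20%

    def test_mean_matches_plain_average(self):
        x = np.random.default_rng(4).standard_normal((30, 10))
        m = dyn.bootstrap_band_map(x, reps=4000, seed=2)
        np.testing.assert_allclose(m.mean(axis=0), x.mean(axis=0), atol=0.1)


class TestClusterMass:
    def test_negation_symmetry(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((15, 80))
        x[:, 20:40] += 1.5
        times = np.arange(80) / FS
        r_pos = dyn.cluster_mass_test(x, times, n_perm=200, seed=3)
        r_neg = dyn.cluster_mass_test(-x, times, n_perm=200, seed=3)
        masses_pos = sorted(c.mass for c in r_pos.clusters)
        masses_neg = sorted(-c.mass for c in r_neg.clusters)
        np.testing.assert_allclose(masses_pos, masses_neg, rtol=1e-10)
        np.testing.assert_allclose([c.p for c in r_pos.clusters],
                                   [c.p for c in r_neg.clusters])

    def test_injected_burst_detected(self):
        hits = 0
        times = np.arange(350) / FS
        window = (times >= 0.1) & (times <= 0.6)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((25, 350))
            x[:, window] += 3.0
            res = dyn.cluster_mass_test(x, times, n_perm=300, seed=seed)
            best = None
            for c in res.significant_clusters:
                overlap = (min(c.end_s, 0.6) - max(c.start_s, 0.1)) / 0.5
                best = max(best or 0, overlap)
            if best is not None and best >= 0.8:
                hits += 1
        assert hits >= 9

    def test_no_suprathreshold_points_is_empty_not_error(self):
        x = 1e-6 * np.random.default_rng(0).standard_normal((12, 40))
        x -= x.mean(axis=0, keepdims=True)
        res = dyn.cluster_mass_test(x + 0, np.arange(40) / FS, n_perm=50, seed=0)
        assert isinstance(res.clusters, list)

    def test_power_monotone_in_snr(self):
        times = np.arange(200) / FS
        window = (times >= 0.1) & (times <= 0.3)
        rates = []
        for snr in (0.5, 1.5, 3.0):
            hits = 0
            for seed in range(8):
                rng = np.random.default_rng(1000 + seed)
                x = rng.standard_normal((20, 200))
                x[:, window] += snr
                res = dyn.cluster_mass_test(x, times, n_perm=200, seed=seed)
                hits += bool(res.significant_clusters)
            rates.append(hits)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 7


class TestCircularStats:
    def test_identical_angles(self):
        angles = np.full(100, np.pi / 3)
        assert dyn.plv(angles) == pytest.approx(1.0)
        z, p = dyn.rayleigh_test(angles)
        assert z == pytest.approx(100.0)
        assert p < 1e-10

    def test_antipodal_cancellation(self):
        assert dyn.plv(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_angles_null(self):
        ok = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            _, p = dyn.rayleigh_test(rng.uniform(-np.pi, np.pi, 1000))
            ok += p > 0.05
        assert ok >= 0.9 * 40

    def test_z_equals_n_plv_squared(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-np.pi, np.pi, 257)
        z, _ = dyn.rayleigh_test(angles)
        assert z == pytest.approx(len(angles) * dyn.plv(angles) ** 2)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        angles = rng.vonmises(0.5, 2.0, 300)
        rot = 1.1
        s1 = dyn.phase_stats(angles)
        s2 = dyn.phase_stats(angles + rot)
        assert s2.plv == pytest.approx(s1.plv)
        assert s2.rayleigh_z == pytest.approx(s1.rayleigh_z)
        d = np.angle(np.exp(1j * (s2.mean_angle - s1.mean_angle - rot)))
        assert abs(d) < 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dyn.plv(np.array([]))


class TestPeakPhaseBootstrap:
    def test_degenerate_peak_at_phase_zero(self):
        fs = 100.0
        times = np.arange(-100, 300) / fs
        resp = np.tile(np.cos(2 * np.pi * times / 4.0), (12, 1))
        amp = np.tile(np.exp(-0.5 * ((times - 0.0) / 0.05) ** 2), (12, 1))
        stats = dyn.peak_phase_bootstrap(amp, resp, times, fs, reps=100,
                                         window=(-0.5, 3.0), seed=0)
        assert stats.plv == pytest.approx(1.0)
        assert abs(stats.mean_angle) < 0.1

    def test_rayleigh_identity_on_output(self):
        fs = 100.0
        times = np.arange(-50, 250) / fs
        rng = np.random.default_rng(2)
        resp = np.tile(np.cos(2 * np.pi * times / 4.0), (15, 1))
        amp = rng.random((15, times.size))
        stats = dyn.peak_phase_bootstrap(amp, resp, times, fs, reps=64,
                                         window=(0.0, 2.0), seed=1)
        n = len(stats.angles)
        assert stats.rayleigh_z == pytest.approx(n * stats.plv**2)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            dyn.peak_phase_bootstrap(np.zeros((5, 10)), np.zeros((5, 11)),
                                     np.arange(10) / FS, FS)
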