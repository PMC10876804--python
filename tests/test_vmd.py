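"""Variational-mode-decomposition solver checks against spectral oracles."""

import numpy as np
import pytest

from vmdoc.vmd import (ModeSet, VMDConfig, check_convergence, crop_to_original,
                       decompose, extend_signal, reconstruct)


def fft_peak_freqs(x, k):
    """Independent oracle: the k largest well-separated power-spectrum peaks
    (cycles/sample)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x))
    order = np.argsort(spec)[::-1]
    peaks = []
    for i in order:
        if all(abs(freqs[i] - p) > 0.01 for p in peaks):
            peaks.append(freqs[i])
        if len(peaks) == k:
            break
    return sorted(peaks)


class TestExtendCrop:
    @pytest.mark.parametrize("n", [4, 5, 8, 17, 100])
    def test_round_trip_identity(self, n, rng):
        x = rng.standard_normal(n)
        assert np.array_equal(crop_to_original(extend_signal(x), n), x)

    def test_even_length_doubles(self):
        assert extend_signal(np.arange(8.0)).shape[0] == 16

    def test_mirrored_ends(self):
        ext = extend_signal(np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.array_equal(ext, [2, 1, 1, 2, 3, 4, 4, 3])

    def test_constant_stays_constant(self):
        ext = extend_signal(np.full(10, 3.5))
        assert np.all(ext == 3.5)


class TestCheckConvergence:
    def test_fixed_point_is_converged(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert check_convergence(m, m, 1e-7, 1e-7)

    def test_hand_computed_sums_reject(self):
        # relative sum = 1, absolute sum = 1; both at their thresholds
        assert not check_convergence(np.array([[1.0, 0.0]]),
                                     np.array([[1.0, 1.0]]), 0.5, 0.5)

    def test_relative_criterion_accepts(self):
        # relative sum = 0.01/1 < 0.02 even though absolute fails
        assert check_convergence(np.array([[1.0, 0.0]]),
                                 np.array([[1.0, 0.1]]), 0.02, 1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            check_convergence(np.zeros((2, 3)), np.zeros((2, 4)), 1e-7, None)


class TestDecompose:
    def test_zero_signal_gives_zero_modes(self):
        ms = decompose(np.zeros(64), VMDConfig(n_modes=2))
        assert np.all(ms.modes == 0)
        assert ms.residual_energy == 0.0
        assert ms.converged

    def test_single_tone_center_frequency(self):
        n = np.arange(1024)
        x = np.cos(2 * np.pi * 0.05 * n)
        ms = decompose(x, VMDConfig(n_modes=1, alpha=2000))
        oracle = fft_peak_freqs(x, 1)[0]
        assert abs(ms.omegas[0] - oracle) / oracle < 0.01

    def test_two_tone_recovery_and_mode_purity(self):
        n = np.arange(2048)
        x = np.cos(2 * np.pi * 0.02 * n) + np.cos(2 * np.pi * 0.20 * n)
        ms = decompose(x, VMDConfig(n_modes=2, alpha=2000, tau=0.0))
        oracle = fft_peak_freqs(x, 2)
        for w, f in zip(ms.omegas, oracle):
            assert abs(w - f) / f < 0.05
        for k, f in enumerate([0.02, 0.20]):
            tone = np.cos(2 * np.pi * f * n)
            assert abs(np.corrcoef(ms.modes[k], tone)[0, 1]) >= 0.95

    def test_tone_partition_is_bijective(self):
        # each tone's spectral peak falls in exactly one mode's dominant band
        n = np.arange(2048)
        tones = [0.03, 0.12, 0.30]
        x = sum(np.cos(2 * np.pi * f * n) for f in tones)
        ms = decompose(x, VMDConfig(n_modes=3))
        assignment = [int(np.argmin(np.abs(ms.omegas - f))) for f in tones]
        assert sorted(assignment) == [0, 1, 2]

    def test_spectral_localization_of_modes(self):
        # power-weighted mean frequency of each mode close to its omega
        n = np.arange(2048)
        x = np.cos(2 * np.pi * 0.05 * n) + 0.8 * np.cos(2 * np.pi * 0.22 * n)
        ms = decompose(x, VMDConfig(n_modes=2))
        freqs = np.fft.rfftfreq(2048)
        for mode, w in zip(ms.modes, ms.omegas):
            p = np.abs(np.fft.rfft(mode)) ** 2
            centroid = (freqs * p).sum() / p.sum()
            assert abs(centroid - w) < 0.05  # 10% of Nyquist

    def test_pure_tone_matches_ideal_narrowband_filter(self):
        n = np.arange(1024)
        x = np.cos(2 * np.pi * 0.05 * n) + 0.05 * np.sin(2 * np.pi * 0.3 * n)
        ms = decompose(x, VMDConfig(n_modes=1))
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(1024)
        spec[np.abs(freqs - 0.05) > 0.02] = 0
        ideal = np.fft.irfft(spec, 1024)
        assert np.corrcoef(ms.modes[0], ideal)[0, 1] >= 0.99

    def test_three_tone_reconstruction_error(self):
        n = np.arange(2048)
        x = sum(np.cos(2 * np.pi * f * n) for f in [0.03, 0.12, 0.30])
        ms = decompose(x, VMDConfig(n_modes=3))
        err = np.linalg.norm(x - reconstruct(ms)) / np.linalg.norm(x)
        assert err <= 0.05

    def test_omegas_sorted_ascending(self, rng):
        x = rng.standard_normal(512)
        ms = decompose(x, VMDConfig(n_modes=4))
        assert np.all(np.diff(ms.omegas) >= 0)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(512)
        cfg = VMDConfig(n_modes=3, omega_init="random", random_seed=42)
        a, b = decompose(x, cfg), decompose(x, cfg)
        assert np.array_equal(a.modes, b.modes)
        assert np.array_equal(a.omegas, b.omegas)
        assert a.n_iter == b.n_iter

    def test_stopping_needs_more_than_one_iteration(self):
        n = np.arange(1024)
        x = np.cos(2 * np.pi * 0.05 * n) + np.cos(2 * np.pi * 0.2 * n)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            early = decompose(x, VMDConfig(n_modes=2, max_iter=2))
        assert not early.converged
        full = decompose(x, VMDConfig(n_modes=2))
        assert full.converged and full.n_iter > 2

    def test_nonfinite_input_raises(self):
        x = np.ones(64)
        x[10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            decompose(x, VMDConfig(n_modes=1))

    def test_too_many_modes_raises(self):
        with pytest.raises(ValueError, match="too large"):
            decompose(np.ones(16), VMDConfig(n_modes=9))

    def test_dual_ascent_tightens_reconstruction(self, rng):
        # with tau > 0 the mode sum's spectrum tracks the signal spectrum
        n = np.arange(1024)
        x = np.cos(2 * np.pi * 0.05 * n) + 0.5 * np.cos(2 * np.pi * 0.2 * n)
        loose = decompose(x, VMDConfig(n_modes=2, tau=0.0))
        tight = decompose(x, VMDConfig(n_modes=2, tau=1.0))
        assert tight.residual_energy <= loose.residual_energy + 1e-12
        assert tight.residual_energy < 0.01


class TestReconstruct:
    def test_single_mode_identity(self, rng):
        m = rng.standard_normal(32)
        ms = ModeSet(modes=m[np.newaxis], omegas=np.array([0.1]),
                     n_iter=1, converged=True, residual_energy=0.0)
        assert np.array_equal(reconstruct(ms), m)

    def test_two_mode_addition(self):
        ms = ModeSet(modes=np.array([[1.0, 1.0], [2.0, 2.0]]),
                     omegas=np.array([0.1, 0.2]), n_iter=1, converged=True,
                     residual_energy=0.0)
        assert np.array_equal(reconstruct(ms), [3.0, 3.0])

    def test_empty_mode_set_raises(self):
        ms = ModeSet(modes=np.empty((0, 0)), omegas=np.empty(0),
                     n_iter=0, converged=True, residual_energy=0.0)
        with pytest.raises(ValueError, match="empty"):
            reconstruct(ms)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_modes": 0}, {"alpha": 0}, {"tau": -1},
        {"rel_tol": 0, "abs_tol": None}, {"omega_init": "bogus"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VMDConfig(**kwargs)

    def test_defaults_match_study_settings(self):
        cfg = VMDConfig()
        assert cfg.n_modes == 5 and cfg.alpha == 2000.0 and cfg.tau == 0.0

    def test_uniform_init_strictly_inside_open_interval(self):
        from vmdoc.vmd import _init_omegas
        om = _init_omegas(VMDConfig(n_modes=5))
        assert np.all(om > 0) and np.all(om < 0.5)
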