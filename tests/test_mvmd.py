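"""Decomposition core: spectral ops against brute-force oracles, and the
solver's equivariance/alignment/reconstruction properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mvmdeeg.mvmd import (
    ModeSet,
    MultichannelSignal,
    MVMDConfig,
    SpectralState,
    analytic_half_spectrum,
    decompose,
    has_converged,
    update_center_freqs,
    update_duals,
    update_modes,
)

from .oracles import fft_peak_freqs, vmd_fixed_point


def make_state(x_hat, u_hat, omega, lam=None, fs=1.0):
    F = x_hat.shape[1]
    grid = np.linspace(0, 0.5, F)
    return SpectralState(
        x_hat=x_hat,
        grid=grid,
        u_hat=u_hat,
        lambda_hat=np.zeros_like(x_hat) if lam is None else lam,
        omega=np.asarray(omega, float),
        n_ext=0,
        fs=fs,
    )


class TestAnalyticHalfSpectrum:
    def test_zero_signal_gives_zero_spectra(self):
        st_ = analytic_half_spectrum(MultichannelSignal(np.zeros((2, 64)), 64.0))
        assert np.all(st_.x_hat == 0)

    def test_pure_tone_dominant_bin_matches_dft(self):
        fs, N = 100.0, 1000
        t = np.arange(N) / fs
        x = np.cos(2 * np.pi * 10 * t)
        st_ = analytic_half_spectrum(
            MultichannelSignal(x[None], fs), mirror_extend=False
        )
        # direct DFT oracle on the same record
        ref = np.abs(np.fft.rfft(x))
        assert np.allclose(np.abs(st_.x_hat[0]), ref)
        peak = st_.grid[np.argmax(np.abs(st_.x_hat[0]))]
        assert peak == pytest.approx(0.1, abs=1e-9)

    def test_linearity_across_channels(self, rng):
        x = rng.standard_normal(128)
        sig = MultichannelSignal(np.stack([x, 2 * x]), 64.0)
        st_ = analytic_half_spectrum(sig)
        assert np.allclose(st_.x_hat[1], 2 * st_.x_hat[0])

    def test_mirror_extension_recorded(self):
        sig = MultichannelSignal(np.random.default_rng(0).standard_normal((1, 100)), 10.0)
        assert analytic_half_spectrum(sig, mirror_extend=True).n_ext == 50
        assert analytic_half_spectrum(sig, mirror_extend=False).n_ext == 0

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MultichannelSignal(np.array([[0.0, np.nan, 1.0, 2.0]]), 4.0)


class TestUpdateModes:
    def test_huge_alpha_kills_off_center_content(self, rng):
        x_hat = rng.standard_normal((1, 8)) + 1j * rng.standard_normal((1, 8))
        state = make_state(x_hat, np.zeros((1, 1, 8), complex), [0.25])
        update_modes(state, alpha=1e12)
        on_center = np.argmin(np.abs(state.grid - 0.25))
        off = np.setdiff1d(np.arange(8), [on_center])
        assert np.all(np.abs(state.u_hat[0, 0, off]) < 1e-9)

    def test_at_center_frequency_equals_residual(self, rng):
        x_hat = rng.standard_normal((1, 8)) + 1j * rng.standard_normal((1, 8))
        state = make_state(x_hat, np.zeros((1, 1, 8), complex), [state_omega := 0.5])
        update_modes(state, alpha=123.0)
        # at w == w_k the denominator is exactly 1
        k_bin = np.argmin(np.abs(state.grid - state_omega))
        assert state.u_hat[0, 0, k_bin] == pytest.approx(x_hat[0, k_bin])

    def test_single_mode_update_matches_hand_evaluated_wiener_filter(self):
        # 4-bin toy spectrum, K=1, lambda=0: u = x / (1 + 2a(w - w1)^2)
        x_hat = np.array([[1 + 1j, 2.0, 0 + 3j, -1.0]])
        alpha, w1 = 10.0, 0.2
        state = make_state(x_hat, np.zeros((1, 1, 4), complex), [w1])
        update_modes(state, alpha)
        grid = state.grid
        expected = np.array(
            [x_hat[0, f] / (1 + 2 * alpha * (grid[f] - w1) ** 2) for f in range(4)]
        )
        assert np.allclose(state.u_hat[0, 0], expected, atol=1e-12)

    def test_sequential_sweep_sees_fresh_previous_modes(self, rng):
        # after the sweep, mode 2's residual must exclude mode 1's *new* value
        x_hat = rng.standard_normal((1, 16)) + 1j * rng.standard_normal((1, 16))
        state = make_state(x_hat, np.zeros((2, 1, 16), complex), [0.1, 0.4])
        update_modes(state, alpha=5.0)
        den2 = 1 + 2 * 5.0 * (state.grid - 0.4) ** 2
        expected2 = (x_hat[0] - state.u_hat[0, 0]) / den2
        assert np.allclose(state.u_hat[1, 0], expected2)

    def test_nonpositive_alpha_rejected(self, rng):
        state = make_state(np.zeros((1, 4), complex), np.zeros((1, 1, 4), complex), [0.1])
        with pytest.raises(ValueError):
            update_modes(state, alpha=0.0)


class TestUpdateCenterFreqs:
    def test_single_bin_spectrum_returns_that_bin(self):
        u = np.zeros((1, 1, 9), complex)
        u[0, 0, 4] = 3.0
        state = make_state(np.zeros((1, 9), complex), u, [0.0])
        update_center_freqs(state)
        assert state.omega[0] == pytest.approx(state.grid[4])

    def test_two_equal_bins_average(self):
        u = np.zeros((1, 1, 11), complex)
        grid = np.linspace(0, 0.5, 11)
        i1, i2 = np.argmin(np.abs(grid - 0.1)), np.argmin(np.abs(grid - 0.3))
        u[0, 0, i1] = u[0, 0, i2] = 1.0
        state = make_state(np.zeros((1, 11), complex), u, [0.0])
        update_center_freqs(state)
        assert state.omega[0] == pytest.approx(0.2)

    def test_random_spectra_match_brute_force_weighted_mean(self, rng):
        u = rng.standard_normal((3, 2, 8)) + 1j * rng.standard_normal((3, 2, 8))
        state = make_state(np.zeros((2, 8), complex), u.copy(), [0.1, 0.2, 0.3])
        update_center_freqs(state)
        for k in range(3):
            num = den = 0.0
            for c in range(2):
                for f in range(8):
                    p = abs(u[k, c, f]) ** 2
                    num += state.grid[f] * p
                    den += p
            assert state.omega[k] == pytest.approx(num / den, rel=1e-12)

    def test_zero_mode_keeps_omega_and_warns(self):
        u = np.zeros((1, 1, 8), complex)
        state = make_state(np.zeros((1, 8), complex), u, [0.33])
        with pytest.warns(RuntimeWarning, match="all-zero"):
            update_center_freqs(state)
        assert state.omega[0] == 0.33


class TestUpdateDuals:
    def test_zero_step_leaves_duals(self, rng):
        x_hat = rng.standard_normal((1, 8)) + 0j
        state = make_state(x_hat, np.zeros((1, 1, 8), complex), [0.1])
        update_duals(state, tau=0.0)
        assert np.all(state.lambda_hat == 0)

    def test_exact_reconstruction_leaves_duals(self, rng):
        x_hat = rng.standard_normal((1, 8)) + 1j * rng.standard_normal((1, 8))
        u = x_hat[None].copy()
        state = make_state(x_hat, u, [0.1])
        update_duals(state, tau=2.5)
        assert np.allclose(state.lambda_hat, 0)

    def test_unit_step_adds_residual(self):
        x_hat = np.zeros((1, 4), complex)
        x_hat[0, 2] = 5.0
        state = make_state(x_hat, np.zeros((1, 1, 4), complex), [0.1])
        update_duals(state, tau=1.0)
        assert state.lambda_hat[0, 2] == pytest.approx(5.0)


class TestConvergenceStatistic:
    def test_identical_modes_converged(self):
        u = np.ones((2, 3, 8), complex)
        conv, stat = has_converged(u, u.copy(), tol=1e-12)
        assert conv and stat == 0.0

    def test_doubling_gives_one_per_term(self):
        u = np.random.default_rng(1).standard_normal((2, 3, 8)) + 0j
        conv, stat = has_converged(u, 2 * u, tol=1e-3)
        assert stat == pytest.approx(2 * 3 * 1.0)
        assert not conv

    @given(st.integers(0, 2**31 - 1))
    def test_random_perturbation_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        prev = r.standard_normal((2, 2, 6)) + 1j * r.standard_normal((2, 2, 6))
        curr = prev + 0.01 * r.standard_normal((2, 2, 6))
        _, stat = has_converged(prev, curr, tol=1.0)
        brute = 0.0
        for k in range(2):
            for c in range(2):
                brute += (np.abs(curr[k, c] - prev[k, c]) ** 2).sum() / (
                    np.abs(prev[k, c]) ** 2
                ).sum()
        assert stat == pytest.approx(brute, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            has_converged(np.zeros((1, 1, 4)), np.zeros((1, 1, 5)), 1.0)


class TestDecompose:
    def test_two_channels_four_modes_gives_eight_series(self, two_tone_snr20):
        ms = decompose(two_tone_snr20.signal, MVMDConfig(n_modes=4))
        assert ms.modes.shape[:2] == (4, 2)
        assert ms.n_modes * ms.n_channels == 8

    def test_zero_signal_yields_zero_modes(self):
        ms = decompose(
            MultichannelSignal(np.zeros((2, 64)), 64.0), MVMDConfig(n_modes=3)
        )
        assert np.all(ms.modes == 0)

    def test_recovers_shared_tone_frequencies(self, two_tone_snr20, mvmd_cfg):
        ms = decompose(two_tone_snr20.signal, mvmd_cfg)
        truth = fft_peak_freqs(two_tone_snr20.signal.samples, 128.0, 2)
        assert np.all(np.abs(ms.center_freqs - truth) < 0.5)
        assert np.all(np.abs(ms.center_freqs - [10.0, 25.0]) < 0.5)

    def test_single_channel_matches_independent_vmd_oracle(self, rng):
        fs, N = 64.0, 256
        t = np.arange(N) / fs
        x = np.cos(2 * np.pi * 5 * t) + 0.7 * np.cos(2 * np.pi * 19 * t + 0.4)
        x += 0.05 * rng.standard_normal(N)
        ms = decompose(MultichannelSignal(x, fs), MVMDConfig(n_modes=2, alpha=2000))
        ref_modes, ref_omega = vmd_fixed_point(x, K=2, alpha=2000)
        rms = np.sqrt(((ms.modes[:, 0, :] - ref_modes) ** 2).mean())
        assert rms < 1e-6
        assert np.allclose(ms.center_freqs, ref_omega * fs, atol=1e-6)

    def test_too_many_modes_rejected(self):
        sig = MultichannelSignal(np.random.default_rng(0).standard_normal((1, 16)), 16.0)
        with pytest.raises(ValueError, match="n_modes"):
            decompose(sig, MVMDConfig(n_modes=8))

    def test_unconverged_result_still_returned(self, two_tone_snr20):
        ms = decompose(
            two_tone_snr20.signal, MVMDConfig(n_modes=2, tol=1e-30, max_iter=3)
        )
        assert not ms.converged
        assert ms.n_iter == 3
        assert ms.modes.shape == (2, 2, 512)


class TestSolverProperties:
    def test_scale_equivariance(self, two_tone_snr20, mvmd_cfg):
        sig = two_tone_snr20.signal
        scaled = MultichannelSignal(3.0 * sig.samples, sig.fs)
        a = decompose(sig, mvmd_cfg)
        b = decompose(scaled, mvmd_cfg)
        assert np.allclose(b.center_freqs, a.center_freqs, atol=1e-9)
        assert np.allclose(b.modes, 3.0 * a.modes, atol=1e-9)

    def test_channel_permutation_equivariance(self, two_tone_snr20, mvmd_cfg):
        sig = two_tone_snr20.signal
        perm = MultichannelSignal(sig.samples[::-1], sig.fs)
        a = decompose(sig, mvmd_cfg)
        b = decompose(perm, mvmd_cfg)
        assert np.allclose(b.center_freqs, a.center_freqs, atol=1e-9)
        assert np.allclose(b.modes, a.modes[:, ::-1, :], atol=1e-9)

    def test_mode_alignment_one_frequency_per_mode(self, two_tone_snr20):
        ms = decompose(two_tone_snr20.signal, MVMDConfig(n_modes=3))
        assert ms.center_freqs.shape == (3,)
        assert np.all(np.diff(ms.center_freqs) >= 0)
        assert np.all((ms.center_freqs >= 0) & (ms.center_freqs <= 64.0))

    def test_noiseless_reconstruction_within_five_percent(self, two_tone_noiseless):
        # dual ascent enforces the reconstruction constraint on clean data
        ms = decompose(
            two_tone_noiseless.signal, MVMDConfig(n_modes=2, alpha=2000, tau=0.5)
        )
        x = two_tone_noiseless.signal.samples
        rel = np.linalg.norm(x - ms.reconstruction()) / np.linalg.norm(x)
        assert rel <= 0.05

    def test_convergence_statistic_tail_nonincreasing(self, two_tone_noiseless):
        ms = decompose(
            two_tone_noiseless.signal, MVMDConfig(n_modes=2, alpha=2000, tau=0.5)
        )
        tail = ms.residual_history[-10:]
        assert len(tail) == 10
        assert np.all(np.diff(tail) <= 1e-9)

    def test_init_schemes_all_converge_on_tones(self, two_tone_snr20):
        for scheme in ("uniform", "zero", "random"):
            ms = decompose(
                two_tone_snr20.signal,
                MVMDConfig(n_modes=2, init_scheme=scheme, seed=3),
            )
            assert ms.converged


class TestModeSetValidation:
    def test_descending_center_freqs_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            ModeSet(
                modes=np.zeros((2, 1, 8)),
                center_freqs=np.array([5.0, 1.0]),
                n_iter=1,
                converged=True,
                final_residual=0.0,
                fs=32.0,
            )

    def test_out_of_band_center_freqs_rejected(self):
        with pytest.raises(ValueError, match="fs/2"):
            ModeSet(
                modes=np.zeros((1, 1, 8)),
                center_freqs=np.array([100.0]),
                n_iter=1,
                converged=True,
                final_residual=0.0,
                fs=32.0,
            )
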