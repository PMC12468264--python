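"""Independent brute-force oracles used to validate the implementation.

These deliberately use naive per-bin loops and share no code with the
package internals.
"""

import numpy as np


def vmd_fixed_point(x, K, alpha, tau=0.0, tol=1e-7, max_iter=500):
    """Single-channel variational mode decomposition, naive fixed-point
    iteration on the mirror-extended half-spectrum grid.

    Returns (modes (K, N) sorted by center frequency, normalized center
    frequencies).
    """
    x = np.asarray(x, float)
    N = len(x)
    n = N // 2
    ext = np.concatenate([x[:n][::-1], x, x[-n:][::-1]])
    T = len(ext)
    F = T // 2 + 1
    grid = np.fft.rfftfreq(T)
    x_hat = np.fft.rfft(ext)
    u = np.zeros((K, F), complex)
    lam = np.zeros(F, complex)
    omega = 0.5 * np.arange(1, K + 1) / (K + 1)
    for it in range(1, max_iter + 1):
        prev = u.copy()
        for k in range(K):
            others = np.zeros(F, complex)
            for i in range(K):
                if i != k:
                    others += u[i]
            for f in range(F):
                u[k, f] = (x_hat[f] - others[f] + lam[f] / 2.0) / (
                    1.0 + 2.0 * alpha * (grid[f] - omega[k]) ** 2
                )
        for k in range(K):
            num = 0.0
            den = 0.0
            for f in range(F):
                p = abs(u[k, f]) ** 2
                num += grid[f] * p
                den += p
            if den > 0:
                omega[k] = num / den
        lam = lam + tau * (x_hat - u.sum(axis=0))
        stat = 0.0
        for k in range(K):
            d = float((np.abs(u[k] - prev[k]) ** 2).sum())
            nn = float((np.abs(prev[k]) ** 2).sum())
            if nn > 0:
                stat += d / nn
        if stat < tol and it > 1:
            break
    modes = np.fft.irfft(u, n=T, axis=1)[:, n : n + N]
    order = np.argsort(omega, kind="stable")
    return modes[order], omega[order]


def fft_peak_freqs(signal, fs, n_peaks, min_sep_hz=3.0):
    """Dominant spectral peaks of a multichannel signal, by channel-summed
    periodogram with greedy separation."""
    spec = (np.abs(np.fft.rfft(signal, axis=-1)) ** 2).sum(axis=0)
    freqs = np.fft.rfftfreq(signal.shape[-1], d=1.0 / fs)
    order = np.argsort(spec)[::-1]
    picked = []
    for idx in order:
        f = freqs[idx]
        if all(abs(f - p) >= min_sep_hz for p in picked):
            picked.append(f)
        if len(picked) == n_peaks:
            break
    return np.sort(picked)


def stft_frames_oracle(series, nperseg, hop, nfft):
    """Frame-by-frame windowed DFT magnitudes with zero boundary padding
    of nperseg//2 on each side, scaled like a spectrum (1/sum(window))."""
    from scipy.signal import get_window

    win = get_window("hann", nperseg)
    pad = nperseg // 2
    ext = np.concatenate([np.zeros(pad), np.asarray(series, float), np.zeros(pad)])
    starts = range(0, len(ext) - nperseg + 1, hop)
    mags = []
    for s in starts:
        frame = ext[s : s + nperseg] * win
        mags.append(np.abs(np.fft.rfft(frame, n=nfft)) / win.sum())
    return np.array(mags).T  # (F, T)


def gru_step_oracle(x, h, W_z, W_r, W_h, b_z, b_r, b_h):
    """Hand evaluation of the gated-recurrent update on 1-D arrays."""

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    hx = np.concatenate([h, x])
    z = sig(hx @ W_z + b_z)
    r = sig(hx @ W_r + b_r)
    rhx = np.concatenate([r * h, x])
    h_cand = np.tanh(rhx @ W_h + b_h)
    return (1 - z) * h + z * h_cand
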