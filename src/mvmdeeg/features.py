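"""Spectrogram features: per-IMF short-time Fourier magnitudes.

Every IMF series of every channel is turned into a Hann-windowed STFT
magnitude map, cropped to the analysis passband, and the maps are stacked
channel-major into the classifier's input tensor. With a transform length
equal to the sampling rate the frequency bins fall on a 1 Hz grid, so an
inclusive 0-50 Hz crop keeps 51 bins; zero boundary padding of half a
window at each end makes a one-second epoch yield ceil(N/hop)+1 = 9
frames at both 512 Hz (nperseg 128, overlap 64) and 256 Hz (64/32).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .mvmd import ModeSet

__all__ = ["STFTConfig", "FeatureTensor", "stft_magnitude", "crop_band", "build_feature_tensor"]


@dataclass
class STFTConfig:
    """STFT dialect. ``nfft`` of None means "use the sampling rate"."""

    window: str = "hann"
    nperseg: int = 128
    overlap: int = 64
    nfft: int | None = None
    band_keep: tuple[float, float] = (0.0, 50.0)
    boundary_pad: bool = True
    normalize: bool = False

    def __post_init__(self) -> None:
        if not self.overlap < self.nperseg:
            raise ValueError("overlap must be smaller than nperseg")
        if self.nfft is not None and self.nfft < self.nperseg:
            raise ValueError("nfft must be >= nperseg")

    def resolve_nfft(self, fs: float) -> int:
        return int(fs) if self.nfft is None else self.nfft


@dataclass
class FeatureTensor:
    """(K*C) x F x T nonnegative magnitudes, channel-major / mode-minor."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D")
        if np.any(self.values < 0):
            raise ValueError("magnitudes must be nonnegative")
        if self.values.shape[1:] != (len(self.freqs), len(self.times)):
            raise ValueError("axis metadata inconsistent with values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def stft_magnitude(
    series: np.ndarray, cfg: STFTConfig, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude spectrogram of one series.

    Returns (magnitudes F x T, freqs in Hz, frame times in s). Hop is
    ``nperseg - overlap``; with boundary padding the series is extended
    with nperseg//2 zeros at both ends so frames are centered on samples
    0, hop, 2*hop, ...
    """
    series = np.asarray(series, float)
    nfft = cfg.resolve_nfft(fs)
    freqs, times, Z = sps.stft(
        series,
        fs=fs,
        window=cfg.window,
        nperseg=cfg.nperseg,
        noverlap=cfg.overlap,
        nfft=nfft,
        boundary="zeros" if cfg.boundary_pad else None,
        padded=cfg.boundary_pad,
        detrend=False,
        return_onesided=True,
        scaling="spectrum",
    )
    return np.abs(Z), freqs, times


def crop_band(
    spec: np.ndarray, freqs: np.ndarray, low: float, high: float
) -> tuple[np.ndarray, np.ndarray]:
    """Keep rows with low <= f <= high (inclusive at both edges)."""
    if low >= high:
        raise ValueError("need low < high")
    keep = (freqs >= low) & (freqs <= high)
    if not np.any(keep):
        raise ValueError(f"no frequency bins inside [{low}, {high}] Hz")
    return spec[keep], freqs[keep]


def build_feature_tensor(modes: ModeSet, cfg: STFTConfig) -> FeatureTensor:
    """Stack per-(channel, mode) spectrograms into the classifier input.

    The first axis enumerates channel-major, mode-minor: slice
    ``c * K + k`` holds the spectrogram of mode k on channel c, so all
    modes of a channel are contiguous.
    """
    K, C = modes.n_modes, modes.n_channels
    slabs = []
    freqs_kept = times = None
    for c in range(C):
        for k in range(K):
            mag, freqs, times = stft_magnitude(modes.modes[k, c], cfg, modes.fs)
            mag, freqs_kept = crop_band(mag, freqs, *cfg.band_keep)
            slabs.append(mag)
    values = np.stack(slabs, axis=0)
    if cfg.normalize:
        # scale (not center) so magnitudes stay nonnegative
        sd = values.std()
        if sd > 0:
            values = values / sd
    return FeatureTensor(values=values, freqs=freqs_kept, times=times)
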