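"""EEG preprocessing: power-line notch, band-pass, epoching, channel pick-out.

Filters are realized as a quality-factor-30 IIR notch and a 4th-order
Butterworth band-pass, applied forward-backward (zero phase) by default,
the usual choice for offline EEG. Epoching slices non-overlapping
one-second windows; overlapped sliding windows provide simple
minority-class augmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .mvmd import MultichannelSignal

__all__ = [
    "PreprocessConfig",
    "notch_filter",
    "bandpass_filter",
    "epoch_segment",
    "sliding_window_augment",
    "select_channels",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    notch_hz: float = 50.0
    notch_q: float = 30.0
    band: tuple[float, float] = (0.5, 50.0)
    filter_order: int = 4
    epoch_seconds: float = 1.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("need 0 < band.low < band.high")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")


def notch_filter(
    signal: MultichannelSignal, f0: float, q: float = 30.0, zero_phase: bool = True
) -> MultichannelSignal:
    """Suppress a narrow band around ``f0`` Hz (power-line interference)."""
    if f0 >= signal.fs / 2:
        raise ValueError(f"notch frequency {f0} Hz at or above Nyquist")
    b, a = sps.iirnotch(f0, q, fs=signal.fs)
    if zero_phase:
        y = sps.filtfilt(b, a, signal.samples, axis=1)
    else:
        y = sps.lfilter(b, a, signal.samples, axis=1)
    return MultichannelSignal(y, signal.fs)


def bandpass_filter(
    signal: MultichannelSignal,
    low: float,
    high: float,
    order: int = 4,
    zero_phase: bool = True,
) -> MultichannelSignal:
    """Butterworth band-pass keeping [low, high] Hz.

    The zero-phase variant applies the forward-backward response
    |H(w)|^2 spectrally on a mirror-extended copy of the signal: this is
    the filtfilt steady-state response with exactly zero phase, exact
    linearity and no start-up transients -- the state of a recursion
    whose low-edge pole sits at 0.5 Hz would otherwise ring across an
    entire short record. The causal variant is an ordinary sosfilt.
    """
    if not 0 < low < high < signal.fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) Hz at fs={signal.fs}")
    sos = sps.butter(order, (low, high), btype="bandpass", fs=signal.fs, output="sos")
    if zero_phase:
        x = signal.samples
        N = x.shape[1]
        ext = np.concatenate([x[:, ::-1], x, x[:, ::-1]], axis=1)
        freqs = np.fft.rfftfreq(ext.shape[1], d=1.0 / signal.fs)
        _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs / signal.fs)
        spec = np.fft.rfft(ext, axis=1) * np.abs(h) ** 2
        y = np.fft.irfft(spec, n=ext.shape[1], axis=1)[:, N : 2 * N]
    else:
        y = sps.sosfilt(sos, signal.samples, axis=1)
    return MultichannelSignal(y, signal.fs)


def epoch_segment(
    signal: MultichannelSignal, epoch_seconds: float = 1.0
) -> list[MultichannelSignal]:
    """Cut into consecutive non-overlapping epochs; trailing remainder dropped."""
    epoch_len = int(round(epoch_seconds * signal.fs))
    n_epochs = signal.n_samples // epoch_len
    if n_epochs == 0:
        warnings.warn("signal shorter than one epoch", RuntimeWarning, stacklevel=2)
        return []
    return [
        MultichannelSignal(
            signal.samples[:, i * epoch_len : (i + 1) * epoch_len], signal.fs
        )
        for i in range(n_epochs)
    ]


def sliding_window_augment(
    signal: MultichannelSignal,
    epoch_seconds: float = 1.0,
    overlap_fraction: float = 0.5,
    quota: int | None = None,
) -> list[MultichannelSignal]:
    """Overlapping-window sampling to augment under-represented classes.

    Windows of ``epoch_seconds`` advance by ``epoch_len * (1 -
    overlap_fraction)`` samples; extraction stops at ``quota`` epochs or
    the signal end. Start indices are unique, so no window is duplicated.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if quota is not None and quota <= 0:
        raise ValueError("quota must be positive")
    epoch_len = int(round(epoch_seconds * signal.fs))
    step = max(1, int(round(epoch_len * (1 - overlap_fraction))))
    out: list[MultichannelSignal] = []
    for start in range(0, signal.n_samples - epoch_len + 1, step):
        out.append(
            MultichannelSignal(signal.samples[:, start : start + epoch_len], signal.fs)
        )
        if quota is not None and len(out) >= quota:
            break
    return out


def _canon(label: str) -> str:
    """Canonicalize an electrode label: case, 'EEG ' prefix, reference suffix."""
    s = label.strip().upper()
    if s.startswith("EEG "):
        s = s[4:]
    for suffix in ("-REF", "-LE", "-AVG", "-A1", "-A2"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    return s


def select_channels(
    samples: np.ndarray,
    fs: float,
    available: list[str],
    requested: list[str],
) -> MultichannelSignal:
    """Pick and order channels by electrode label.

    Matching is case-insensitive and tolerant of 'EEG ' prefixes and
    reference suffixes ('FP1', 'EEG FP1-REF', 'fp1-LE' all resolve to
    FP1). A label that cannot be resolved raises, naming it.
    """
    lut: dict[str, int] = {}
    for i, name in enumerate(available):
        lut.setdefault(_canon(name), i)
    rows = []
    for want in requested:
        key = _canon(want)
        if key not in lut:
            raise KeyError(f"channel label {want!r} not found in recording")
        rows.append(lut[key])
    return MultichannelSignal(np.asarray(samples, float)[rows], fs)


def preprocess(
    signal: MultichannelSignal, cfg: PreprocessConfig
) -> list[MultichannelSignal]:
    """Notch + band-pass + epoching with one config."""
    y = notch_filter(signal, cfg.notch_hz, cfg.notch_q, cfg.zero_phase)
    y = bandpass_filter(y, *cfg.band, order=cfg.filter_order, zero_phase=cfg.zero_phase)
    return epoch_segment(y, cfg.epoch_seconds)
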