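"""End-to-end wiring: epochs -> MVMD -> spectrogram tensors -> classifier.

Thin convenience layer shared by the CLI and scripted experiments; each
step just calls the corresponding module.
"""

from __future__ import annotations

import numpy as np

from .features import STFTConfig, build_feature_tensor
from .mvmd import ModeSet, MultichannelSignal, MVMDConfig, decompose

__all__ = ["decompose_epochs", "featurize_epochs", "default_stft_config"]


def default_stft_config(fs: float) -> STFTConfig:
    """Per-rate STFT dialect: quarter-second Hann windows with half
    overlap, 1 Hz bins (nfft = fs), inclusive 0-50 Hz crop."""
    nperseg = max(8, int(fs) // 4)
    return STFTConfig(nperseg=nperseg, overlap=nperseg // 2, nfft=None)


def decompose_epochs(
    epochs: np.ndarray, fs: float, cfg: MVMDConfig
) -> list[ModeSet]:
    """Run MVMD independently on each (C, N) epoch."""
    return [decompose(MultichannelSignal(e, fs), cfg) for e in epochs]


def featurize_epochs(
    epochs: np.ndarray,
    fs: float,
    mvmd_cfg: MVMDConfig,
    stft_cfg: STFTConfig | None = None,
) -> np.ndarray:
    """Feature tensors for a stack of epochs, shape (n, K*C, F, T)."""
    if stft_cfg is None:
        stft_cfg = default_stft_config(fs)
    out = []
    for mode_set in decompose_epochs(epochs, fs, mvmd_cfg):
        out.append(build_feature_tensor(mode_set, stft_cfg).values)
    return np.stack(out)
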