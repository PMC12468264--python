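"""File readers and writers.

Supported formats:

* two-column ASCII signal-pair files (the intracranial focal/non-focal
  dialect: one channel per column, comma- or whitespace-delimited);
* EDF recordings, read through :mod:`mne`; a minimal EDF writer is
  included for building synthetic fixture recordings (plain ASCII header
  plus little-endian int16 samples);
* self-describing ``.npz`` containers for intermediate mode sets and
  feature tensors (arrays plus axis metadata);
* YAML run logs capturing config, seeds and library versions.
"""

from __future__ import annotations

import datetime
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .features import FeatureTensor
from .mvmd import ModeSet, MultichannelSignal
from .preprocess import _canon

__all__ = [
    "PairRecord",
    "read_pair_text",
    "write_pair_text",
    "read_edf_channels",
    "write_edf",
    "save_modes",
    "load_modes",
    "save_features",
    "load_features",
    "write_run_log",
]


@dataclass
class PairRecord:
    """One aligned two-channel record with its label and provenance."""

    x: np.ndarray
    y: np.ndarray
    fs: float
    label: str | None
    source: str

    def as_signal(self) -> MultichannelSignal:
        return MultichannelSignal(np.stack([self.x, self.y]), self.fs)


def _infer_pair_label(name: str, label_map: dict[str, str]) -> str | None:
    """Label from the filename prefix convention (e.g. Data_F_001 -> focal)."""
    stem = Path(name).stem.upper()
    tokens = stem.replace("-", "_").split("_")
    for tok in tokens:
        if tok in label_map:
            return label_map[tok]
    return None


def read_pair_text(
    path,
    fs: float = 512.0,
    label_map: dict[str, str] | None = None,
) -> PairRecord:
    """Parse a two-column numeric text file into a signal pair.

    The delimiter (comma or whitespace) is auto-detected per line; ragged
    rows or non-numeric cells raise with the offending line number. The
    label is inferred from the filename prefix convention ('F' -> focal,
    'N' -> non-focal by default).
    """
    if label_map is None:
        label_map = {"F": "focal", "N": "non-focal"}
    path = Path(path)
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as e:
                raise ValueError(f"{path.name}:{lineno}: non-numeric cell") from e
    return PairRecord(
        x=np.asarray(xs),
        y=np.asarray(ys),
        fs=fs,
        label=_infer_pair_label(path.name, label_map),
        source=str(path),
    )


def write_pair_text(path, x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise ValueError("pair channels must have equal length")
    np.savetxt(path, np.column_stack([x, y]), fmt="%.6f", delimiter=",")


# -- EDF ---------------------------------------------------------------
def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, samples: np.ndarray, fs: float, labels: list[str]) -> None:
    """Write a minimal EDF file (for synthetic fixture recordings).

    ``samples`` is (C, N) in microvolts; N must be a whole number of
    one-second records. Each channel is scaled to its own physical range
    over the 16-bit digital span.
    """
    samples = np.atleast_2d(np.asarray(samples, float))
    C, N = samples.shape
    spr = int(round(fs))
    if spr != fs:
        raise ValueError("EDF writer requires an integer sampling rate")
    if N % spr:
        raise ValueError("signal length must be a whole number of 1-s records")
    if len(labels) != C:
        raise ValueError("one label per channel required")
    n_records = N // spr

    pmin = samples.min(axis=1)
    pmax = samples.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    dmin, dmax = -32768, 32767

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + C)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(C), 4),
        ]
    )
    sig_fields = [
        [_pad(f"EEG {lab}-REF", 16) for lab in labels],
        [_pad("AgAgCl electrode", 80)] * C,
        [_pad("uV", 8)] * C,
        [_pad(f"{pmin[c]:.8g}"[:8], 8) for c in range(C)],
        [_pad(f"{pmax[c]:.8g}"[:8], 8) for c in range(C)],
        [_pad(str(dmin), 8)] * C,
        [_pad(str(dmax), 8)] * C,
        [_pad("", 80)] * C,
        [_pad(str(spr), 8)] * C,
        [_pad("", 32)] * C,
    ]
    header += b"".join(b"".join(f) for f in sig_fields)

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((samples - pmin[:, None]) * scale[:, None] + dmin).astype(
        "<i2"
    )
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for c in range(C):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())


def read_edf_channels(
    path, labels: list[str], expected_fs: float | None = None
) -> MultichannelSignal:
    """Extract labeled channels from an EDF recording, in request order.

    Values are returned in microvolts. Label matching is case-insensitive
    and tolerant of 'EEG ' prefixes and reference suffixes. A sampling
    rate differing from ``expected_fs`` raises -- no silent resampling.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise ValueError(f"sampling rate {fs} Hz does not match expected {expected_fs}")
    lut: dict[str, int] = {}
    for i, name in enumerate(raw.ch_names):
        lut.setdefault(_canon(name), i)
    rows = []
    for want in labels:
        key = _canon(want)
        if key not in lut:
            raise KeyError(f"channel label {want!r} not found in {Path(path).name}")
        rows.append(lut[key])
    data = raw.get_data(picks=rows, units="uV")
    return MultichannelSignal(data, fs)


# -- npz containers ----------------------------------------------------
def save_modes(path, mode_sets: list[ModeSet]) -> None:
    """Store a list of per-epoch mode sets with axis metadata."""
    arrays = {}
    meta = []
    for i, ms in enumerate(mode_sets):
        arrays[f"modes_{i}"] = ms.modes
        arrays[f"cfs_{i}"] = ms.center_freqs
        meta.append(
            dict(n_iter=ms.n_iter, converged=bool(ms.converged), fs=ms.fs,
                 final_residual=ms.final_residual)
        )
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_modes(path) -> list[ModeSet]:
    out = []
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        for i, m in enumerate(meta):
            out.append(
                ModeSet(
                    modes=z[f"modes_{i}"],
                    center_freqs=z[f"cfs_{i}"],
                    n_iter=m["n_iter"],
                    converged=m["converged"],
                    final_residual=m["final_residual"],
                    fs=m["fs"],
                )
            )
    return out


def save_features(path, tensors: list[FeatureTensor], labels: np.ndarray | None = None) -> None:
    stacked = np.stack([t.values for t in tensors])
    arrays = dict(values=stacked, freqs=tensors[0].freqs, times=tensors[0].times)
    if labels is not None:
        arrays["labels"] = np.asarray(labels, dtype=int)
    np.savez(path, **arrays)


def load_features(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    with np.load(path, allow_pickle=False) as z:
        labels = z["labels"] if "labels" in z.files else None
        return z["values"], z["freqs"], z["times"], labels


def write_run_log(path, command: str, config: dict, seed: int | None) -> None:
    """Reproducibility log: command, config, seeds, library versions."""
    import scipy

    import mvmdeeg

    entry = {
        "command": command,
        "argv": sys.argv,
        "config": config,
        "seed": seed,
        "versions": {
            "mvmdeeg": getattr(mvmdeeg, "__version__", "unknown"),
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(entry, fh, sort_keys=False)
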