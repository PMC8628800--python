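"""Epoch slicing and 1-20 Hz power-spectrum matrices from EEG.

Each scoring window is cut into non-overlapping 1-s bins; the squared
DFT magnitude at integer frequencies 1..20 Hz of each bin forms one
column of the epoch's spectrogram. Bins are rectangular-windowed, so an
integer-Hz tone is recovered leakage-free and Parseval's theorem holds
exactly per bin. Normalization is per-matrix min-max to [0, 1], keeping
every epoch image self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SignalRecord",
    "EpochSpectrogram",
    "FREQ_LO_HZ",
    "FREQ_HI_HZ",
    "epoch_slices",
    "compute_power_spectrum",
    "normalize_spectrogram",
    "load_edf",
]

FREQ_LO_HZ = 1
FREQ_HI_HZ = 20
N_FREQ_BINS = FREQ_HI_HZ - FREQ_LO_HZ + 1  # 20 rows, 1..20 Hz inclusive


@dataclass
class SignalRecord:
    """Paired EEG/EMG sample arrays (µV) with sampling rate and epoch length."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float
    epoch_length_s: float = 20.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape or self.eeg.ndim != 1:
            raise ValueError(
                f"eeg and emg must be equal-length 1-D arrays, got "
                f"{self.eeg.shape} and {self.emg.shape}"
            )
        if not (np.isfinite(self.eeg).all() and np.isfinite(self.emg).all()):
            raise ValueError("signals must be finite")
        if self.fs <= 0 or self.epoch_length_s <= 0:
            raise ValueError("fs and epoch_length_s must be positive")

    @property
    def samples_per_epoch(self) -> int:
        n = self.fs * self.epoch_length_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"fs*epoch_length_s={n} is not an integer")
        return int(round(n))

    @property
    def n_epochs(self) -> int:
        return len(self.eeg) // self.samples_per_epoch


def epoch_slices(record: SignalRecord) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous, non-overlapping (eeg, emg) epoch pairs in temporal order."""
    n_per = record.samples_per_epoch
    total = len(record.eeg)
    if total % n_per:
        raise ValueError(
            f"signal length {total} is not a multiple of the epoch size "
            f"{n_per} (fs={record.fs} Hz x {record.epoch_length_s} s)"
        )
    return [
        (record.eeg[i:i + n_per], record.emg[i:i + n_per])
        for i in range(0, total, n_per)
    ]


def compute_power_spectrum(eeg_window: np.ndarray, fs: float) -> np.ndarray:
    """Raw power matrix (20 frequency rows x one column per second).

    Row ``r`` holds |DFT|² at ``r+1`` Hz for each non-overlapping 1-s
    bin of the window; column order is time order.
    """
    if fs < 2 * FREQ_HI_HZ:
        raise ValueError(f"fs={fs} Hz is below Nyquist for the {FREQ_HI_HZ} Hz band")
    n_bin = fs * 1.0
    if abs(n_bin - round(n_bin)) > 1e-9:
        raise ValueError("sampling rate must give an integer number of samples per second")
    n_bin = int(round(n_bin))
    x = np.asarray(eeg_window, dtype=float)
    if x.ndim != 1 or x.size == 0 or x.size % n_bin:
        raise ValueError(
            f"window length {x.size} must be a positive multiple of fs={n_bin}"
        )
    bins = x.reshape(-1, n_bin)  # (seconds, fs)
    spec = np.fft.rfft(bins, axis=1)  # bin k is exactly k Hz for 1-s segments
    power = np.abs(spec[:, FREQ_LO_HZ:FREQ_HI_HZ + 1]) ** 2
    return power.T.copy()  # (20, seconds)


@dataclass
class EpochSpectrogram:
    """Normalized 1-20 Hz x 1-s-bin power matrix for one scoring window."""

    power: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2 or self.power.shape[0] != N_FREQ_BINS:
            raise ValueError(
                f"spectrogram must have {N_FREQ_BINS} frequency rows, "
                f"got shape {self.power.shape}"
            )
        if self.normalized and (self.power.min() < 0 or self.power.max() > 1):
            raise ValueError("normalized spectrogram values must lie in [0, 1]")

    @property
    def window_s(self) -> int:
        return self.power.shape[1]


def normalize_spectrogram(raw: np.ndarray, log_power: bool = False) -> EpochSpectrogram:
    """Min-max scale a raw power matrix to [0, 1] over the whole matrix.

    A constant matrix maps to all zeros. ``log_power`` applies
    log10(power + eps) before scaling (off by default).
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("power matrix must be finite")
    if (raw < 0).any():
        raise ValueError("power matrix must be non-negative")
    vals = np.log10(raw + 1e-12) if log_power else raw
    lo, hi = vals.min(), vals.max()
    if hi - lo <= 0:
        return EpochSpectrogram(np.zeros_like(vals), normalized=True)
    return EpochSpectrogram((vals - lo) / (hi - lo), normalized=True)


def load_edf(
    path: str | Path,
    eeg_channel: str | int = 0,
    emg_channel: str | int = 1,
    epoch_length_s: float = 20.0,
) -> SignalRecord:
    """Read an EDF recording's EEG and EMG channels (requires ``mne``)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF input requires the optional dependency 'mne' "
            "(pip install sleepscore[edf])"
        ) from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")

    def pick(ch):
        if isinstance(ch, int):
            return ch
        if ch not in raw.ch_names:
            raise ValueError(f"channel {ch!r} not in {raw.ch_names}")
        return raw.ch_names.index(ch)

    data = raw.get_data() * 1e6  # volts -> microvolts
    eeg = data[pick(eeg_channel)]
    emg = data[pick(emg_channel)]
    fs = float(raw.info["sfreq"])
    n_per = int(round(fs * epoch_length_s))
    n_full = (len(eeg) // n_per) * n_per  # trim a trailing partial epoch
    return SignalRecord(eeg=eeg[:n_full], emg=emg[:n_full], fs=fs,
                        epoch_length_s=epoch_length_s)
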