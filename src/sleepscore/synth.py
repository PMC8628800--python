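"""Synthetic mouse EEG/EMG generator.

Simulates hypnograms from a first-order Markov chain over
(WAKE, NREM, REM) and renders stage-conditioned signals carrying the
canonical electrophysiological signatures: NREM pairs low EMG amplitude
with high delta-band (1-4 Hz) EEG power, REM pairs muscle atonia with
theta-band (6-9 Hz) dominance, and wake shows high EMG with mixed
broadband EEG. The default chain's stationary distribution is exactly
10:10:1 (wake:NREM:REM) — the class imbalance that motivates the
GAN-based augmentation downstream — and REM is reachable only from
NREM, matching the physiological NREM->REM transition.

EEG synthesis uses a fixed comb of sinusoids per band with per-epoch
random phases and small frequency jitter, so expected band powers have
a closed form (amplitude a contributes a^2/2) and spectral tests can be
checked against an independent DFT oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import SignalRecord
from .stages import N_STAGES, STAGE_NAMES, Hypnogram, Stage

__all__ = [
    "StageParams",
    "TransitionConfig",
    "simulate_hypnogram",
    "synthesize_signals",
    "write_signals",
    "read_signals",
    "DEFAULT_TRANSITIONS",
]

# Component frequencies (Hz) of each band's sinusoid comb. Delta and
# theta combs sit inside their textbook bands; the broadband comb spans
# the 1-20 Hz display range to mimic desynchronized cortical activity.
_BAND_FREQS = {
    "delta": (1.5, 2.5, 3.5),
    "theta": (6.5, 7.5, 8.5),
    "broadband": (2.0, 5.0, 8.0, 11.0, 14.0, 17.0),
}
_FREQ_JITTER_HZ = 0.3


@dataclass
class StageParams:
    """Per-stage signal parameters (relative amplitudes in µV).

    ``band_weights[stage]`` is ``(delta, theta, broadband)``; each band
    weight w spreads over that band's comb so the band's expected power
    is w²/2. ``emg_rms`` sets the per-stage EMG noise scale (µV RMS).
    """

    band_weights: dict[Stage, tuple[float, float, float]] = field(
        default_factory=lambda: {
            Stage.WAKE: (5.0, 5.0, 8.0),
            Stage.NREM: (25.0, 6.0, 6.0),
            Stage.REM: (4.0, 20.0, 5.0),
        }
    )
    emg_rms: dict[Stage, float] = field(
        default_factory=lambda: {Stage.WAKE: 30.0, Stage.NREM: 8.0, Stage.REM: 4.0}
    )
    noise_level: float = 2.0  # 1/f background amplitude scale (µV)
    fs: float = 128.0
    epoch_length_s: float = 20.0
    band_freqs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: v for k, v in _BAND_FREQS.items()}
    )
    freq_jitter_hz: float = _FREQ_JITTER_HZ

    def validate(self) -> None:
        for st, (d, t, b) in self.band_weights.items():
            if min(d, t, b) < 0:
                raise ValueError(f"negative band weight for {st.name}")
        if any(v < 0 for v in self.emg_rms.values()) or self.noise_level < 0:
            raise ValueError("amplitudes must be non-negative")
        if set(self.band_freqs) != set(_BAND_FREQS) or self.freq_jitter_hz < 0:
            raise ValueError("band_freqs must define delta, theta and broadband combs")
        top = max(
            max(f for fs_ in self.band_freqs.values() for f in fs_) + self.freq_jitter_hz,
            20.0,
        )
        if self.fs < 2 * top:
            raise ValueError(f"fs={self.fs} below Nyquist for {top} Hz content")
        d, t, _ = self.band_weights[Stage.NREM]
        if not d > t:
            raise ValueError("NREM delta weight must exceed its theta weight")
        d, t, _ = self.band_weights[Stage.REM]
        if not t > d:
            raise ValueError("REM theta weight must exceed its delta weight")
        if not (
            self.emg_rms[Stage.WAKE] > self.emg_rms[Stage.NREM] >= self.emg_rms[Stage.REM]
        ):
            raise ValueError("EMG scales must satisfy wake > NREM >= REM")


# Default chain: high self-transition for wake/NREM, REM entered only
# from NREM. Stationary distribution solves to exactly 10:10:1
# (pi_R = pi_N * 0.035/0.35, pi_W = pi_N); mean REM bout 1/0.35 ≈ 2.9
# epochs (~1 min at 20 s epochs), in the several-minute-cycle regime of
# polyphasic mouse sleep.
DEFAULT_TRANSITIONS = np.array(
    [
        [0.93, 0.07, 0.00],  # WAKE ->
        [0.04, 0.925, 0.035],  # NREM ->
        [0.30, 0.05, 0.65],  # REM  ->
    ]
)


@dataclass
class TransitionConfig:
    """Stage-transition matrix (rows: from-stage) and initial distribution."""

    matrix: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    initial: np.ndarray = field(
        default_factory=lambda: np.array([10.0, 10.0, 1.0]) / 21.0
    )

    def validate(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_STAGES, N_STAGES):
            raise ValueError(f"transition matrix must be 3x3, got {m.shape}")
        for i, row in enumerate(m):
            if (row < 0).any():
                raise ValueError(
                    f"negative transition probability in row {STAGE_NAMES[i]}: {row}"
                )
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"row {STAGE_NAMES[i]} sums to {row.sum():.12f}, expected 1"
                )
        init = np.asarray(self.initial, dtype=float)
        if init.shape != (N_STAGES,) or (init < 0).any() or abs(init.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must be a length-3 probability vector")

    def stationary(self) -> np.ndarray:
        """Stationary distribution via eigen-decomposition of the transpose."""
        vals, vecs = np.linalg.eig(np.asarray(self.matrix, dtype=float).T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        return pi / pi.sum()


def simulate_hypnogram(
    n_epochs: int,
    config: TransitionConfig | None = None,
    seed: int = 0,
    epoch_length_s: float = 20.0,
) -> Hypnogram:
    """Sample a stage sequence from the Markov chain; reproducible from seed."""
    if n_epochs < 0:
        raise ValueError("n_epochs must be >= 0")
    config = config or TransitionConfig()
    config.validate()
    if n_epochs == 0:
        return Hypnogram(np.empty(0, dtype=np.int8), epoch_length_s)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(np.asarray(config.matrix, dtype=float), axis=1)
    u = rng.random(n_epochs)
    stages = np.empty(n_epochs, dtype=np.int8)
    stages[0] = np.searchsorted(np.cumsum(config.initial), u[0], side="right")
    for t in range(1, n_epochs):
        stages[t] = np.searchsorted(cum[stages[t - 1]], u[t], side="right")
    np.clip(stages, 0, N_STAGES - 1, out=stages)
    return Hypnogram(stages, epoch_length_s)


def _epoch_rng(seed: int, epoch_index: int) -> np.random.Generator:
    # counter-based sub-seeding: one independent stream per epoch, so a
    # record sliced at epoch boundaries is reproducible epoch by epoch
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(epoch_index)]))


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Background noise with ~1/f amplitude spectrum, unit scale."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return x / (np.std(x) + 1e-12)


def synthesize_signals(
    hypnogram: Hypnogram,
    params: StageParams | None = None,
    seed: int = 0,
) -> SignalRecord:
    """Render stage-conditioned EEG/EMG for each epoch of a hypnogram."""
    params = params or StageParams()
    params.validate()
    if len(hypnogram) == 0:
        raise ValueError("hypnogram must be non-empty")
    fs, ep = params.fs, hypnogram.epoch_length_s
    n_per = fs * ep
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(f"epoch_length_s * fs = {n_per} is not an integer sample count")
    n_per = int(round(n_per))
    t = np.arange(n_per) / fs

    eeg = np.empty(len(hypnogram) * n_per)
    emg = np.empty_like(eeg)
    band_names = ("delta", "theta", "broadband")
    for i, code in enumerate(hypnogram.stages):
        rng = _epoch_rng(seed, i)
        stage = Stage(int(code))
        x = np.zeros(n_per)
        for w, name in zip(params.band_weights[stage], band_names):
            comb = params.band_freqs[name]
            if w <= 0:
                # keep the rng call pattern identical regardless of weight
                rng.uniform(size=len(comb))
                rng.uniform(size=len(comb))
                continue
            a = w / np.sqrt(len(comb))
            j = params.freq_jitter_hz
            jit = rng.uniform(-j, j, size=len(comb)) if j > 0 else np.zeros(len(comb))
            ph = rng.uniform(0, 2 * np.pi, size=len(comb))
            for f0, dj, p in zip(comb, jit, ph):
                x += a * np.sin(2 * np.pi * (f0 + dj) * t + p)
        if params.noise_level > 0:
            x += params.noise_level * _one_over_f_noise(rng, n_per, fs)
        eeg[i * n_per:(i + 1) * n_per] = x
        emg[i * n_per:(i + 1) * n_per] = params.emg_rms[stage] * rng.standard_normal(n_per)
    return SignalRecord(eeg=eeg, emg=emg, fs=fs, epoch_length_s=ep)


# ---- plain-text IO ---------------------------------------------------

def write_signals(record: SignalRecord, out_dir: str | Path, stem: str = "signals") -> Path:
    """Write a record as two-column CSV plus a JSON sidecar; returns CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    data = np.column_stack([record.eeg, record.emg])
    header = "eeg_uV,emg_uV"
    np.savetxt(csv_path, data, delimiter=",", header=header, comments="", fmt="%.6f")
    sidecar = {
        "fs": record.fs,
        "epoch_length_s": record.epoch_length_s,
        "n_epochs": record.n_epochs,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_signals(csv_path: str | Path) -> SignalRecord:
    csv_path = Path(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    return SignalRecord(
        eeg=data[:, 0], emg=data[:, 1],
        fs=float(sidecar["fs"]), epoch_length_s=float(sidecar["epoch_length_s"]),
    )
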