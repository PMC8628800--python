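"""Deterministic rasterization of epoch images.

Each scoring window becomes a square grayscale image: the top half is
the raw EMG trace drawn against a fixed vertical range (so muscle tone
is comparable across images), the bottom half is the normalized 1-20 Hz
EEG spectrogram heatmap with low frequencies at the bottom. Rendering
is pure array painting — no plotting toolkit — so images are
bit-identical across platforms. Axis decorations are constant across
images and carry no class information, so none are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocess import (
    EpochSpectrogram,
    N_FREQ_BINS,
    SignalRecord,
    compute_power_spectrum,
    normalize_spectrogram,
)
from .stages import Hypnogram, Stage

__all__ = [
    "EpochImage",
    "render_epoch_image",
    "build_window_images",
    "default_emg_range",
    "downscale",
    "save_png",
    "load_png",
]

DEFAULT_IMAGE_PX = 180  # training size; originals render at 800
EMG_RANGE_SIGMA = 6.0  # fixed axis = this many global EMG standard deviations


@dataclass
class EpochImage:
    """H x W grayscale pixels in [0,1] with label and provenance."""

    pixels: np.ndarray
    label: Stage | None = None
    window_s: float = 20.0
    epoch_index: int = 0
    subject_id: str = ""
    provenance: str = "real"  # real | duplicated | generated

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"pixels must be square 2-D, got {px.shape}")
        if px.size and (px.min() < -1e-6 or px.max() > 1 + 1e-6):
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]


def render_epoch_image(
    emg_window: np.ndarray,
    spectrogram: EpochSpectrogram,
    emg_range: float,
    out_px: int = DEFAULT_IMAGE_PX,
) -> EpochImage:
    """Rasterize one window: EMG polyline on top, spectrogram heatmap below."""
    emg = np.asarray(emg_window, dtype=float)
    if emg.size == 0:
        raise ValueError("EMG window is empty")
    if emg_range <= 0:
        raise ValueError("emg_range must be positive")
    if out_px < 32 or out_px % 2:
        raise ValueError("out_px must be an even integer >= 32")
    if not spectrogram.normalized:
        raise ValueError("spectrogram must be normalized before rendering")

    half = out_px // 2
    img = np.zeros((out_px, out_px), dtype=np.float32)

    # --- top panel: vertical-span waveform rendering -----------------
    v = np.clip(emg, -emg_range, emg_range)
    rows = np.rint((1.0 - (v + emg_range) / (2.0 * emg_range)) * (half - 1)).astype(int)
    cols = (np.arange(emg.size) * out_px) // emg.size
    for c in range(out_px):
        sel = rows[cols == c]
        if sel.size == 0:
            continue
        lo, hi = sel.min(), sel.max()
        if c > 0:
            prev = rows[cols == c - 1]
            if prev.size:  # bridge to the previous column's last sample
                lo, hi = min(lo, prev[-1]), max(hi, prev[-1])
        img[lo:hi + 1, c] = 1.0

    # --- bottom panel: heatmap, low frequency at the bottom ----------
    spec = spectrogram.power
    T = spec.shape[1]
    freq_of_row = (N_FREQ_BINS - 1) - (np.arange(half) * N_FREQ_BINS) // half
    time_of_col = (np.arange(out_px) * T) // out_px
    img[half:, :] = spec[np.ix_(freq_of_row, time_of_col)].astype(np.float32)

    return EpochImage(img, window_s=float(T))


def default_emg_range(record: SignalRecord) -> float:
    """Fixed vertical EMG axis: a global multiple of the record's EMG std."""
    sd = float(np.std(record.emg))
    return EMG_RANGE_SIGMA * sd if sd > 0 else 1.0


def build_window_images(
    record: SignalRecord,
    labels: Hypnogram,
    epochs_per_image: int = 1,
    window_s_override: float | None = None,
    out_px: int = DEFAULT_IMAGE_PX,
    emg_range: float | None = None,
    subject_id: str = "",
    log_power: bool = False,
) -> list[EpochImage]:
    """Render one labeled image per scorable epoch.

    1-epoch mode gives one image per epoch. 2-epoch mode prepends the
    preceding epoch as context and labels the image by the latter
    epoch; the record's first epoch has no predecessor and is dropped.
    ``window_s_override`` trims each window to its most recent
    ``window_s`` seconds before rendering (the 40 -> 35 -> 30 -> 25 ->
    20 s ladder).
    """
    if epochs_per_image not in (1, 2):
        raise ValueError("epochs_per_image must be 1 or 2")
    n_epochs = record.n_epochs
    if len(labels) != n_epochs:
        raise ValueError(
            f"label count {len(labels)} does not match epoch count {n_epochs}"
        )
    n_per = record.samples_per_epoch
    full_window_s = epochs_per_image * record.epoch_length_s
    window_s = full_window_s if window_s_override is None else float(window_s_override)
    if not 0 < window_s <= full_window_s:
        raise ValueError(
            f"window override {window_s} s must lie in (0, {full_window_s}] s"
        )
    n_win = int(round(window_s * record.fs))
    if abs(window_s * record.fs - n_win) > 1e-9 or abs(window_s - round(window_s)) > 1e-9:
        raise ValueError("window length must be a whole number of seconds")
    if emg_range is None:
        emg_range = default_emg_range(record)

    images: list[EpochImage] = []
    first = 0 if epochs_per_image == 1 else 1
    for i in range(first, n_epochs):
        end = (i + 1) * n_per
        eeg_w = record.eeg[end - n_win:end]  # most recent window_s seconds
        emg_w = record.emg[end - n_win:end]
        spec = normalize_spectrogram(
            compute_power_spectrum(eeg_w, record.fs), log_power=log_power
        )
        img = render_epoch_image(emg_w, spec, emg_range, out_px)
        img.label = labels[i]
        img.window_s = window_s
        img.epoch_index = i
        img.subject_id = subject_id
        images.append(img)
    return images


def downscale(pixels: np.ndarray, out_px: int) -> np.ndarray:
    """Area-average a square grayscale array to out_px x out_px."""
    im = Image.fromarray(np.asarray(pixels, dtype=np.float32), mode="F")
    return np.asarray(im.resize((out_px, out_px), Image.BOX), dtype=np.float32)


# ---- PNG IO ----------------------------------------------------------

def save_png(image: EpochImage, path: str | Path) -> None:
    arr = np.rint(image.pixels * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def load_png(path: str | Path, **meta) -> EpochImage:
    arr = np.asarray(Image.open(str(path)).convert("L"), dtype=np.float32) / 255.0
    return EpochImage(arr, **meta)
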