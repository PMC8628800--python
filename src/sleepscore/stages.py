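"""Sleep-stage alphabet and the hypnogram container.

Mouse sleep is scored per epoch (20 s by default) into three stages:
WAKE (high muscle tone, desynchronized EEG), NREM (delta-dominant EEG,
low EMG) and REM (theta-dominant EEG, muscle atonia).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np


class Stage(IntEnum):
    """Three-stage scoring alphabet, ordered WAKE < NREM < REM.

    The integer codes double as class indices for the classifier; argmax
    ties break toward the smaller code, i.e. toward WAKE.
    """

    WAKE = 0
    NREM = 1
    REM = 2

    @classmethod
    def from_label(cls, label: "str | int | Stage") -> "Stage":
        if isinstance(label, Stage):
            return label
        if isinstance(label, (int, np.integer)):
            return cls(int(label))
        key = str(label).strip().upper()
        key = {"W": "WAKE", "N": "NREM", "R": "REM"}.get(key, key)
        try:
            return cls[key]
        except KeyError:
            raise ValueError(
                f"unknown stage label {label!r}; expected one of "
                f"{[s.name for s in cls]}"
            ) from None


STAGE_NAMES = tuple(s.name for s in Stage)
N_STAGES = len(Stage)


@dataclass
class Hypnogram:
    """Per-epoch stage sequence with its epoch length in seconds."""

    stages: np.ndarray  # int8 codes, values in {0, 1, 2}
    epoch_length_s: float = 20.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.stages)
        if arr.dtype.kind in "UO":  # labels given as strings
            arr = np.array([Stage.from_label(s) for s in arr], dtype=np.int8)
        else:
            arr = arr.astype(np.int8)
        if arr.ndim != 1:
            raise ValueError("hypnogram stages must be a 1-D sequence")
        if arr.size and (arr.min() < 0 or arr.max() >= N_STAGES):
            bad = arr[(arr < 0) | (arr >= N_STAGES)][0]
            raise ValueError(f"stage code {bad} outside the 3-stage alphabet")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        self.stages = arr

    @classmethod
    def from_labels(
        cls, labels: Iterable[str | int | Stage], epoch_length_s: float = 20.0
    ) -> "Hypnogram":
        codes = np.array([Stage.from_label(l) for l in labels], dtype=np.int8)
        return cls(codes, epoch_length_s)

    def __len__(self) -> int:
        return int(self.stages.size)

    def __iter__(self) -> Iterator[Stage]:
        return (Stage(int(c)) for c in self.stages)

    def __getitem__(self, idx: int) -> Stage:
        return Stage(int(self.stages[idx]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.epoch_length_s == other.epoch_length_s
            and np.array_equal(self.stages, other.stages)
        )

    @property
    def labels(self) -> list[str]:
        return [STAGE_NAMES[c] for c in self.stages]

    def stage_counts(self) -> dict[str, int]:
        counts = np.bincount(self.stages, minlength=N_STAGES)
        return {STAGE_NAMES[i]: int(counts[i]) for i in range(N_STAGES)}

    def fractions(self) -> dict[str, float]:
        n = max(len(self), 1)
        return {k: v / n for k, v in self.stage_counts().items()}

    # ---- plain-text IO: one label per line, header optional ----

    def to_csv(self, path: str | Path) -> None:
        Path(path).write_text("stage\n" + "".join(l + "\n" for l in self.labels))

    @classmethod
    def from_csv(cls, path: str | Path, epoch_length_s: float = 20.0) -> "Hypnogram":
        lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
        if lines and lines[0].lower() in ("stage", "label"):
            lines = lines[1:]
        return cls.from_labels(lines, epoch_length_s)


def as_codes(labels: "Hypnogram | Sequence[str | int | Stage]") -> np.ndarray:
    """Coerce a hypnogram or label sequence to an int8 code array."""
    if isinstance(labels, Hypnogram):
        return labels.stages
    return Hypnogram.from_labels(labels).stages
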