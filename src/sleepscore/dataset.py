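"""Labeled image collections: subject-wise splits and class balancing.

Evaluation is always split by subject (animal), never by random epoch,
so no animal contributes to both training and scoring. Two balancing
strategies address the ~10:10:1 wake:NREM:REM imbalance: plain
duplication of minority-class images, and appending GAN-generated
fakes. Generated images are flagged by provenance and are barred from
evaluation sets by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import EpochImage, load_png, save_png
from .stages import STAGE_NAMES, Stage

__all__ = [
    "ImageDataset",
    "split_by_subject",
    "balance_with_duplicates",
    "balance_with_generated",
    "save_dataset",
    "load_dataset",
]


@dataclass
class ImageDataset:
    """A list of EpochImage sharing one pixel size."""

    images: list[EpochImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        sides = {im.side_px for im in self.images}
        if len(sides) > 1:
            raise ValueError(f"images have mixed pixel sizes: {sorted(sides)}")
        missing = [i for i, im in enumerate(self.images) if im.label is None]
        if missing:
            raise ValueError(f"image {missing[0]} has no stage label")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    @property
    def side_px(self) -> int:
        if not self.images:
            raise ValueError("empty dataset has no pixel size")
        return self.images[0].side_px

    @property
    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(STAGE_NAMES, 0)
        for im in self.images:
            counts[im.label.name] += 1
        return counts

    @property
    def subject_ids(self) -> set[str]:
        return {im.subject_id for im in self.images}

    def subset(self, stage: Stage | None = None,
               provenance: str | None = None) -> "ImageDataset":
        sel = [
            im for im in self.images
            if (stage is None or im.label == stage)
            and (provenance is None or im.provenance == provenance)
        ]
        return ImageDataset(sel)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """NHWC float32 batch in [0,1] plus int label vector."""
        if not self.images:
            n = 0
            return np.zeros((0, 1, 1, 1), np.float32), np.zeros(0, np.int64)
        X = np.stack([im.pixels for im in self.images]).astype(np.float32)
        y = np.array([int(im.label) for im in self.images], dtype=np.int64)
        return X[..., None], y


def split_by_subject(
    ds: ImageDataset, train_ids: set[str], eval_ids: set[str]
) -> tuple[ImageDataset, ImageDataset]:
    """Route every image by subject_id; a subject never lands in both."""
    train_ids, eval_ids = set(train_ids), set(eval_ids)
    overlap = train_ids & eval_ids
    if overlap:
        raise ValueError(f"train/eval subject sets overlap: {sorted(overlap)}")
    known = ds.subject_ids if len(ds) else set()
    unknown = (train_ids | eval_ids) - known
    if unknown:
        raise ValueError(
            f"unknown subject ids {sorted(unknown)}; known ids: {sorted(known)}"
        )
    train = [im for im in ds if im.subject_id in train_ids]
    evl = [im for im in ds if im.subject_id in eval_ids]
    return ImageDataset(train), ImageDataset(evl)


def balance_with_duplicates(
    ds: ImageDataset, stage: Stage, factor: int
) -> ImageDataset:
    """Replicate one stage's images so its count becomes factor x original.

    Copies are flagged ``duplicated``; real images are untouched.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    originals = [im for im in ds if im.label == stage]
    if not originals:
        warnings.warn(f"stage {stage.name} absent from dataset; duplication is a no-op")
        return ImageDataset(list(ds.images))
    copies = [
        EpochImage(im.pixels.copy(), label=im.label, window_s=im.window_s,
                   epoch_index=im.epoch_index, subject_id=im.subject_id,
                   provenance="duplicated")
        for _ in range(factor - 1) for im in originals
    ]
    return ImageDataset(list(ds.images) + copies)


def balance_with_generated(
    ds: ImageDataset,
    fakes: list[EpochImage],
    stage: Stage,
    mode: str = "equalize",
    k: int = 10,
) -> ImageDataset:
    """Append GAN fakes of one stage.

    ``equalize`` appends fakes until the stage count reaches the
    largest other-class count (no-op if already the majority);
    ``times_k`` appends (k-1) x the real count so the stage totals k x
    its real count — e.g. k=10 appends 9 fakes per real image.
    """
    wrong = [im for im in fakes if im.label != stage]
    if wrong:
        raise ValueError(
            f"{len(wrong)} fake images are not labeled {stage.name}"
        )
    counts = ds.class_counts
    n_real = counts[stage.name]
    if mode == "equalize":
        target = max(v for s, v in counts.items() if s != stage.name)
        n_needed = max(0, target - n_real)
    elif mode == "times_k":
        if k < 1:
            raise ValueError("k must be >= 1")
        n_needed = (k - 1) * n_real
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'equalize' or 'times_k'")
    if n_needed > len(fakes):
        raise ValueError(
            f"need {n_needed} fake {stage.name} images but only {len(fakes)} provided "
            f"(shortfall {n_needed - len(fakes)})"
        )
    extra = []
    for im in fakes[:n_needed]:
        extra.append(
            EpochImage(im.pixels, label=stage, window_s=im.window_s,
                       epoch_index=im.epoch_index, subject_id=im.subject_id,
                       provenance="generated")
        )
    return ImageDataset(list(ds.images) + extra)


# ---- directory IO: PNGs + index CSV ---------------------------------

def save_dataset(ds: ImageDataset, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(ds):
        fname = f"img_{i:06d}.png"
        save_png(im, out_dir / fname)
        rows.append({
            "filename": fname, "subject": im.subject_id,
            "epoch_index": im.epoch_index, "label": im.label.name,
            "window_s": im.window_s, "provenance": im.provenance,
        })
    index = out_dir / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def load_dataset(index_csv: str | Path) -> ImageDataset:
    index_csv = Path(index_csv)
    df = pd.read_csv(index_csv, keep_default_na=False)
    images = []
    for row in df.itertuples():
        images.append(load_png(
            index_csv.parent / row.filename,
            label=Stage.from_label(row.label),
            window_s=float(row.window_s),
            epoch_index=int(row.epoch_index),
            subject_id=str(row.subject),
            provenance=str(row.provenance),
        ))
    return ImageDataset(images)
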