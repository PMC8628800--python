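"""Shared fixtures.

The expensive artifacts — the 2000-epoch synthetic benchmark, its three
seeded classifier trainings, and the REM WGAN-GP with the augmentation
experiment — are session-scoped so every test that needs them reuses
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from sleepscore import (
    ClassifierConfig,
    SleepStageCNN,
    balance_with_duplicates,
    balance_with_generated,
    make_subject_images,
    sample_fake_images,
    split_by_subject,
    train_wgan,
)
from sleepscore.dataset import ImageDataset
from sleepscore.gan import GanConfig, build_wgan_gp
from sleepscore.metrics import score_by_subject
from sleepscore.stages import Hypnogram, Stage

BENCH_SEED = 42
BENCH_SUBJECTS = 6  # 4 for fitting (3 train + 1 validation), 2 held out
BENCH_EPOCHS_PER_SUBJECT = 333  # ~2000 epochs total
BENCH_PX = 64
BENCH_TRAIN_SEEDS = (0, 1, 2)

AUG_SEED = 11
AUG_SUBJECTS = 5  # 2 train, 1 validation, 2 held out
AUG_EPOCHS_PER_SUBJECT = 250
AUG_TRAIN_EPOCHS = 5

GAN_SMOKE_IMAGES = 200
GAN_SMOKE_STEPS = 300


def desk_config(seed: int, input_px: int = BENCH_PX, **overrides) -> ClassifierConfig:
    """The scaled-down training profile: halved filters, lr 1e-3."""
    opts = dict(learning_rate=1e-3, max_epochs=12, patience=3, seed=seed)
    opts.update(overrides)
    return ClassifierConfig().scaled_down(input_px, **opts)


def evaluate_per_subject(model: SleepStageCNN, ds: ImageDataset) -> dict:
    """Per-subject-averaged scores of a model on a labeled image set."""
    hyp, _ = model.predict(ds)
    truth = Hypnogram(np.array([int(im.label) for im in ds], dtype=np.int8))
    subjects = np.array([im.subject_id for im in ds])
    _, agg = score_by_subject(truth, hyp, subjects)
    return agg


@pytest.fixture(scope="session")
def bench_data():
    """~2000 synthetic epochs over 6 subjects, rendered as 64 px images."""
    ds, hyps = make_subject_images(
        BENCH_SUBJECTS, BENCH_EPOCHS_PER_SUBJECT, BENCH_SEED, out_px=BENCH_PX
    )
    sids = sorted(ds.subject_ids)
    fit_ids, eval_ids = set(sids[:4]), set(sids[4:])
    fit_ds, eval_ds = split_by_subject(ds, fit_ids, eval_ids)
    train_ds, val_ds = split_by_subject(fit_ds, set(sorted(fit_ids)[:3]),
                                        {sorted(fit_ids)[3]})
    return {"train": train_ds, "val": val_ds, "eval": eval_ds, "hyps": hyps}


@pytest.fixture(scope="session")
def bench_results(bench_data):
    """Three seeded end-to-end trainings scored per held-out subject."""
    results = {}
    for seed in BENCH_TRAIN_SEEDS:
        model = SleepStageCNN(desk_config(seed))
        model.fit(bench_data["train"], bench_data["val"], seed=seed)
        results[seed] = {
            "model": model,
            "scores": evaluate_per_subject(model, bench_data["eval"]),
        }
    return results


@pytest.fixture(scope="session")
def aug_data():
    """Smaller imbalanced set for the augmentation experiment."""
    ds, _ = make_subject_images(
        AUG_SUBJECTS, AUG_EPOCHS_PER_SUBJECT, AUG_SEED, out_px=BENCH_PX
    )
    sids = sorted(ds.subject_ids)
    train_ds, rest = split_by_subject(ds, set(sids[:2]), set(sids[2:]))
    val_ds, eval_ds = split_by_subject(rest, {sids[2]}, set(sids[3:]))
    return {"train": train_ds, "val": val_ds, "eval": eval_ds}


@pytest.fixture(scope="session")
def rem_corpus():
    """200 REM epochs rendered from the stage-conditioned generator."""
    from sleepscore.imaging import build_window_images
    from sleepscore.synth import synthesize_signals

    hyp = Hypnogram(np.full(GAN_SMOKE_IMAGES, Stage.REM, dtype=np.int8))
    rec = synthesize_signals(hyp, seed=901)
    return ImageDataset(build_window_images(rec, hyp, out_px=BENCH_PX,
                                            subject_id="remsrc"))


@pytest.fixture(scope="session")
def trained_gan(rem_corpus):
    """REM WGAN-GP smoke-trained for 300 steps on the REM corpus."""
    gan = build_wgan_gp(GanConfig(resolution=BENCH_PX, seed=0))
    train_wgan(gan, rem_corpus, steps=GAN_SMOKE_STEPS, seed=0)
    return gan


@pytest.fixture(scope="session")
def aug_results(aug_data, trained_gan):
    """Held-out REM recall for baseline vs GAN-equalized vs x10 duplication."""
    counts = aug_data["train"].class_counts
    n_fakes = max(counts.values()) - counts["REM"]
    fakes = sample_fake_images(trained_gan, n_fakes + 10, Stage.REM, seed=5)
    gan_ds = balance_with_generated(aug_data["train"], fakes, Stage.REM,
                                    mode="equalize")
    dup_ds = balance_with_duplicates(aug_data["train"], Stage.REM, 10)

    recalls = {"base": [], "gan": [], "dup": []}
    for seed in BENCH_TRAIN_SEEDS:
        for name, ds in (("base", aug_data["train"]), ("gan", gan_ds),
                         ("dup", dup_ds)):
            cfg = desk_config(seed, max_epochs=AUG_TRAIN_EPOCHS,
                              patience=AUG_TRAIN_EPOCHS + 1)
            model = SleepStageCNN(cfg)
            model.fit(ds, aug_data["val"], seed=seed)
            agg = evaluate_per_subject(model, aug_data["eval"])
            recalls[name].append(agg["recall"]["REM"])
    return recalls
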