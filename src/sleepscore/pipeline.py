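"""End-to-end workflow runner with a content-addressed manifest.

Stages mirror the scoring workflow: simulate synthetic subjects,
render images, train the classifier, train a REM GAN and sample fakes,
retrain on the augmented set, predict held-out subjects, smooth the
prediction, score it. Each stage reads its inputs from the run
directory and writes its outputs there; a manifest records the config
hash, derived seeds and SHA-256 digests of every artifact, so a rerun
with the same config reproduces identical digests for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, SleepStageCNN
from .dataset import ImageDataset, balance_with_generated, load_dataset, save_dataset, split_by_subject
from .gan import GanConfig, build_wgan_gp, sample_fake_images, train_wgan
from .imaging import save_png
from .metrics import score_by_subject
from .postfilter import smooth_rem_in_wake
from .stages import Hypnogram, Stage
from .synth import StageParams, write_signals
from .workflow import derive_seed, make_subject_images

log = logging.getLogger("sleepscore")

STAGE_ORDER = ("simulate", "images", "train", "gan", "retrain",
               "predict", "filter", "score")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # synthetic study size
    n_train_subjects: int = 4
    n_eval_subjects: int = 2
    epochs_per_subject: int = 333
    # imaging
    image_px: int = 64
    epochs_per_image: int = 1
    window_s: float | None = None
    # classifier (desk-scale defaults; the full profile is 180 px)
    filters_per_block: tuple[int, ...] = (8, 16, 32, 64, 64)
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 12
    patience: int = 3
    # GAN
    gan_steps: int = 150
    gan_resolution: int = 64
    gan_stage: str = "REM"
    # post-filter
    max_bout: int = 1

    def classifier_config(self, seed: int) -> ClassifierConfig:
        return ClassifierConfig(
            input_px=self.image_px,
            filters_per_block=tuple(self.filters_per_block),
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=seed,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Executes stages in workflow order inside one run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.dir = Path(config.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seeds": {},
            "artifacts": {},
        }

    # -- helpers ------------------------------------------------------
    def _record(self, *paths: Path) -> None:
        for p in paths:
            self.manifest["artifacts"][str(p.relative_to(self.dir))] = _sha256(p)

    def _require(self, path: Path, produced_by: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing artifact {path.name}; run the '{produced_by}' stage first"
            )
        return path

    def _seed(self, stage: str, *extra: int) -> int:
        s = derive_seed(self.config.seed, STAGE_ORDER.index(stage), *extra)
        self.manifest["seeds"][stage] = s
        return s

    # -- stages -------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config
        seed = self._seed("simulate")
        total = cfg.n_train_subjects + cfg.n_eval_subjects
        ds, hyps = make_subject_images(
            total, cfg.epochs_per_subject, seed, out_px=cfg.image_px,
            epochs_per_image=cfg.epochs_per_image, window_s_override=cfg.window_s,
        )
        self._images = ds
        self._hyps = hyps
        labels_dir = self.dir / "labels"
        labels_dir.mkdir(exist_ok=True)
        for sid, hyp in hyps.items():
            hyp.to_csv(labels_dir / f"{sid}.csv")
            self._record(labels_dir / f"{sid}.csv")
        log.info("simulate: %d subjects x %d epochs", total, cfg.epochs_per_subject)

    def images(self) -> None:
        cfg = self.config
        if not hasattr(self, "_images"):
            raise FileNotFoundError(
                "no simulated signals in memory; run the 'simulate' stage first"
            )
        sids = sorted(self._images.subject_ids)
        train_ids = set(sids[:cfg.n_train_subjects])
        eval_ids = set(sids[cfg.n_train_subjects:])
        train, evl = split_by_subject(self._images, train_ids, eval_ids)
        self._record(save_dataset(train, self.dir / "train_images"))
        self._record(save_dataset(evl, self.dir / "eval_images"))
        log.info("images: %d train / %d eval at %dpx",
                 len(train), len(evl), cfg.image_px)

    def _load_train_val(self) -> tuple[ImageDataset, ImageDataset]:
        ds = load_dataset(self._require(
            self.dir / "train_images" / "index.csv", "images"))
        sids = sorted(ds.subject_ids)
        if len(sids) < 2:
            raise ValueError("need >= 2 training subjects (one is held out as validation)")
        val_ids = {sids[-1]}
        return split_by_subject(ds, set(sids[:-1]), val_ids)

    def train(self, model_name: str = "model.npz",
              train_ds: ImageDataset | None = None) -> None:
        cfg = self.config
        seed = self._seed("train" if model_name == "model.npz" else "retrain")
        tr, va = self._load_train_val()
        if train_ds is not None:
            tr = train_ds
        model = SleepStageCNN(cfg.classifier_config(seed))
        model.fit(tr, va, seed=seed)
        model.save(self.dir / model_name)
        pd.DataFrame(model.history).to_csv(
            self.dir / f"{Path(model_name).stem}_history.csv", index=False)
        self._record(self.dir / model_name,
                     self.dir / f"{Path(model_name).stem}_history.csv")
        log.info("train: %s val_acc %.3f", model_name, model.history["val_acc"][-1])

    def gan(self) -> None:
        cfg = self.config
        seed = self._seed("gan")
        tr, _ = self._load_train_val()
        stage = Stage.from_label(cfg.gan_stage)
        real = tr.subset(stage=stage, provenance="real")
        gan = build_wgan_gp(GanConfig(resolution=cfg.gan_resolution, seed=seed))
        train_wgan(gan, real, steps=cfg.gan_steps, seed=seed)
        counts = tr.class_counts
        n_fakes = max(v for v in counts.values()) - counts[stage.name]
        fakes = sample_fake_images(gan, max(n_fakes, 1), stage, seed=seed)
        fdir = self.dir / "fakes"
        fdir.mkdir(exist_ok=True)
        for i, im in enumerate(fakes):
            save_png(im, fdir / f"fake_{stage.name}_{i:05d}.png")
        index = pd.DataFrame({
            "filename": [f"fake_{stage.name}_{i:05d}.png" for i in range(len(fakes))],
            "subject": "__generated__", "epoch_index": 0,
            "label": stage.name, "window_s": 20.0, "provenance": "generated",
        })
        index.to_csv(fdir / "index.csv", index=False)
        self._record(fdir / "index.csv")
        log.info("gan: trained %d steps, sampled %d fakes", cfg.gan_steps, len(fakes))

    def retrain(self) -> None:
        cfg = self.config
        tr, _ = self._load_train_val()
        fakes_ds = load_dataset(self._require(
            self.dir / "fakes" / "index.csv", "gan"))
        stage = Stage.from_label(cfg.gan_stage)
        augmented = balance_with_generated(tr, list(fakes_ds.images), stage,
                                           mode="equalize")
        self.train(model_name="model_gan.npz", train_ds=augmented)

    def predict(self) -> None:
        model_path = self.dir / "model_gan.npz"
        if not model_path.exists():
            model_path = self.dir / "model.npz"
        self._require(model_path, "train")
        model = SleepStageCNN.load(model_path)
        evl = load_dataset(self._require(
            self.dir / "eval_images" / "index.csv", "images"))
        hyp, probs = model.predict(evl)
        df = pd.DataFrame({
            "subject": [im.subject_id for im in evl],
            "epoch_index": [im.epoch_index for im in evl],
            "truth": [im.label.name for im in evl],
            "pred": hyp.labels,
        })
        df.to_csv(self.dir / "predictions.csv", index=False)
        np.savetxt(self.dir / "probabilities.csv", probs, delimiter=",",
                   header="p_WAKE,p_NREM,p_REM", comments="", fmt="%.6f")
        self._record(self.dir / "predictions.csv", self.dir / "probabilities.csv")
        log.info("predict: %d epochs with %s", len(df), model_path.name)

    def filter(self) -> None:
        cfg = self.config
        path = self._require(self.dir / "predictions.csv", "predict")
        df = pd.read_csv(path)
        out = []
        for sid, grp in df.groupby("subject", sort=False):
            h = Hypnogram.from_labels(grp["pred"].tolist())
            out.append(pd.Series(
                smooth_rem_in_wake(h, cfg.max_bout).labels, index=grp.index))
        df["pred_filtered"] = pd.concat(out).sort_index()
        df.to_csv(path, index=False)
        self._record(path)
        log.info("filter: max_bout=%d", cfg.max_bout)

    def score(self) -> None:
        df = pd.read_csv(self._require(self.dir / "predictions.csv", "predict"))
        pred_col = "pred_filtered" if "pred_filtered" in df.columns else "pred"
        truth = Hypnogram.from_labels(df["truth"].tolist())
        pred = Hypnogram.from_labels(df[pred_col].tolist())
        per_subject, agg = score_by_subject(truth, pred, df["subject"].to_numpy())
        payload = {
            "per_subject": {sid: r.to_dict() for sid, r in per_subject.items()},
            "mean_accuracy": agg["accuracy"],
            "mean_kappa": agg["kappa"],
            "mean_macro_f1": agg["macro_f1"],
            "mean_recall": agg["recall"],
            "pooled_accuracy": agg["pooled"].accuracy,
            "pooled_kappa": agg["pooled"].kappa,
        }
        (self.dir / "scores.json").write_text(json.dumps(payload, indent=2))
        self._record(self.dir / "scores.json")
        log.info("score: mean acc %.4f kappa %.4f",
                 agg["accuracy"], agg["kappa"])

    def run(self, stages: set[str] | None = None) -> dict:
        requested = set(stages) if stages else set(STAGE_ORDER)
        unknown = requested - set(STAGE_ORDER)
        if unknown:
            raise ValueError(
                f"unknown stages {sorted(unknown)}; valid: {list(STAGE_ORDER)}"
            )
        for name in STAGE_ORDER:
            if name in requested:
                getattr(self, name)()
        (self.dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return self.manifest


def run_pipeline(config: RunConfig, stages: set[str] | None = None) -> dict:
    """Execute the requested stages in workflow order; returns the manifest."""
    return PipelineRun(config).run(stages)
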