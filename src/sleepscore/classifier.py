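"""VGG-style convolutional sleep-stage classifier.

Five blocks of [conv3x3 -> conv3x3 -> maxpool2x2] extract image
features; the head is dense 128 -> dropout -> dense 96 -> dense 64 ->
dropout -> softmax over the three stages. The first (128-unit) and
last (64-unit) hidden dense layers can be read out as activation
matrices for embedding analyses. Training minimizes cross-entropy with
Adam and early-stops on validation loss, restoring the best epoch's
weights. Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn import tensor as T
from .nn.tensor import Tensor
from .dataset import ImageDataset
from .imaging import EpochImage
from .stages import Hypnogram, N_STAGES

__all__ = ["ClassifierConfig", "SleepStageCNN", "build_classifier"]


@dataclass
class ClassifierConfig:
    input_px: int = 180
    conv_blocks: int = 5
    filters_per_block: tuple[int, ...] = (16, 32, 64, 128, 128)
    dense_units: tuple[int, ...] = (128, 96, 64)
    dropout_rates: tuple[float, float] = (0.4, 0.4)
    n_classes: int = 3
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.conv_blocks < 1:
            raise ValueError("conv_blocks must be >= 1")
        if len(self.filters_per_block) != self.conv_blocks:
            raise ValueError(
                f"filters_per_block has {len(self.filters_per_block)} entries "
                f"for {self.conv_blocks} blocks"
            )
        if any(f < 1 for f in self.filters_per_block):
            raise ValueError("filter counts must be positive")
        units = list(self.dense_units)
        if any(u2 > u1 for u1, u2 in zip(units, units[1:])):
            raise ValueError("dense_units must be non-increasing")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.dropout_rates) != 2:
            raise ValueError("exactly two dropout rates are expected")
        side = self.input_px
        for _ in range(self.conv_blocks):
            side //= 2
        if side < 1:
            raise ValueError(
                f"input_px={self.input_px} too small for {self.conv_blocks} "
                f"pooling stages; minimum is {2 ** self.conv_blocks}"
            )

    def scaled_down(self, input_px: int = 64, **overrides) -> "ClassifierConfig":
        """Desk-scale profile: smaller input, halved filters."""
        d = asdict(self)
        d.update(
            input_px=input_px,
            filters_per_block=tuple(max(1, f // 2) for f in self.filters_per_block),
        )
        d.update(overrides)
        d["filters_per_block"] = tuple(d["filters_per_block"])
        d["dense_units"] = tuple(d["dense_units"])
        d["dropout_rates"] = tuple(d["dropout_rates"])
        return ClassifierConfig(**d)


def _as_batch(images, expected_px: int) -> np.ndarray:
    if isinstance(images, ImageDataset):
        X, _ = images.to_arrays()
    elif isinstance(images, np.ndarray):
        X = images
    else:
        images = list(images)
        if not images:
            return np.zeros((0, expected_px, expected_px, 1), np.float32)
        X = np.stack([im.pixels for im in images]).astype(np.float32)[..., None]
    if X.shape[0] and X.shape[1] != expected_px:
        raise ValueError(
            f"image size {X.shape[1]} does not match model input_px={expected_px}"
        )
    return X.astype(np.float32)


class SleepStageCNN:
    """The classifier model: parameters, forward pass, training loop."""

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.config.validate()
        self.trained = False
        self.history: dict[str, list[float]] = {}
        self._init_params(np.random.default_rng(self.config.seed))

    # -- parameters ---------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        self.params: list[Tensor] = []
        self._conv: list[tuple[Tensor, Tensor, Tensor, Tensor]] = []
        c_in = 1
        side = cfg.input_px
        for f in cfg.filters_per_block:
            w1 = Tensor(F.he_init(rng, 9 * c_in, (9 * c_in, f)), requires_grad=True)
            b1 = Tensor(np.zeros(f, np.float32), requires_grad=True)
            w2 = Tensor(F.he_init(rng, 9 * f, (9 * f, f)), requires_grad=True)
            b2 = Tensor(np.zeros(f, np.float32), requires_grad=True)
            self._conv.append((w1, b1, w2, b2))
            self.params += [w1, b1, w2, b2]
            c_in = f
            side //= 2
        self._flat_dim = side * side * c_in
        self._dense: list[tuple[Tensor, Tensor]] = []
        d_in = self._flat_dim
        for u in list(cfg.dense_units) + [cfg.n_classes]:
            w = Tensor(F.he_init(rng, d_in, (d_in, u)), requires_grad=True)
            b = Tensor(np.zeros(u, np.float32), requires_grad=True)
            self._dense.append((w, b))
            self.params += [w, b]
            d_in = u

    # -- forward ------------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None,
                 capture: dict | None = None) -> Tensor:
        h = Tensor(X)
        for w1, b1, w2, b2 in self._conv:
            h = T.relu(F.conv2d(h, w1, b1))
            h = T.relu(F.conv2d(h, w2, b2))
            _, H, W, _ = h.shape
            if H % 2 or W % 2:  # VGG-style floor pooling on odd sizes
                h = T.crop_hw(h, H - H % 2, W - W % 2)
            h = T.maxpool2(h)
        h = F.flatten(h)
        r1, r2 = self.config.dropout_rates
        n_hidden = len(self.config.dense_units)
        for i, (w, b) in enumerate(self._dense):
            h = F.dense(h, w, b)
            if i < n_hidden:
                h = T.relu(h)
                if capture is not None:
                    if i == 0:
                        capture["first_dense"] = h.data
                    if i == n_hidden - 1:
                        capture["last_dense"] = h.data
                if i == 0:
                    h = F.dropout(h, r1, rng, training)
                elif i == n_hidden - 1:
                    h = F.dropout(h, r2, rng, training)
        return h  # logits

    # -- training -----------------------------------------------------
    def fit(self, train: ImageDataset, val: ImageDataset,
            seed: int | None = None, verbose: bool = False) -> "SleepStageCNN":
        cfg = self.config
        Xtr, ytr = train.to_arrays()
        Xva, yva = val.to_arrays()
        if len(Xtr) == 0 or len(Xva) == 0:
            raise ValueError("training and validation sets must be non-empty")
        if Xtr.shape[1] != cfg.input_px or Xva.shape[1] != cfg.input_px:
            raise ValueError(
                f"image size {Xtr.shape[1]}/{Xva.shape[1]} does not match "
                f"config input_px={cfg.input_px}"
            )
        if len(np.unique(ytr)) < 2:
            raise ValueError("training set contains a single class; softmax is degenerate")

        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        opt = nn.Adam(self.params, lr=cfg.learning_rate)
        hist = {k: [] for k in ("train_loss", "train_acc", "val_loss", "val_acc")}
        best_val = np.inf
        best_weights = [p.data.copy() for p in self.params]
        stall = 0
        n = len(Xtr)
        for epoch in range(cfg.max_epochs):
            perm = rng.permutation(n)
            losses, hits = [], 0
            for s in range(0, n, cfg.batch_size):
                idx = perm[s:s + cfg.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                logits = self._forward(xb, training=True, rng=rng)
                loss = F.softmax_cross_entropy(logits, F.one_hot(yb, cfg.n_classes))
                grads = nn.grad(loss, self.params)
                opt.step(grads)
                losses.append(loss.item() * len(idx))
                hits += int((logits.data.argmax(1) == yb).sum())
            hist["train_loss"].append(float(np.sum(losses) / n))
            hist["train_acc"].append(hits / n)
            val_loss, val_acc = self._evaluate(Xva, yva)
            hist["val_loss"].append(val_loss)
            hist["val_acc"].append(val_acc)
            if verbose:
                print(f"epoch {epoch:3d}  loss {hist['train_loss'][-1]:.4f} "
                      f"acc {hist['train_acc'][-1]:.3f}  val_loss {val_loss:.4f} "
                      f"val_acc {val_acc:.3f}")
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = [p.data.copy() for p in self.params]
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        for p, w in zip(self.params, best_weights):
            p.data = w
        self.history = hist
        self.trained = True
        return self

    def _evaluate(self, X: np.ndarray, y: np.ndarray,
                  batch: int = 256) -> tuple[float, float]:
        losses, hits = 0.0, 0
        with nn.no_grad():
            for s in range(0, len(X), batch):
                xb, yb = X[s:s + batch], y[s:s + batch]
                logits = self._forward(xb)
                loss = F.softmax_cross_entropy(logits, F.one_hot(yb, self.config.n_classes))
                losses += loss.item() * len(xb)
                hits += int((logits.data.argmax(1) == yb).sum())
        return losses / len(X), hits / len(X)

    def evaluate(self, ds: ImageDataset) -> tuple[float, float]:
        """(mean cross-entropy, accuracy) on a dataset, no dropout."""
        X, y = ds.to_arrays()
        return self._evaluate(X, y)

    # -- inference ----------------------------------------------------
    def predict(self, images, epoch_length_s: float = 20.0,
                batch: int = 256) -> tuple[Hypnogram, np.ndarray]:
        """Per-image class probabilities and argmax stages.

        Argmax ties break toward the earlier class (WAKE < NREM < REM).
        """
        if not self.trained:
            raise RuntimeError("model is untrained; call fit() first")
        X = _as_batch(images, self.config.input_px)
        probs = np.zeros((len(X), self.config.n_classes), np.float32)
        with nn.no_grad():
            for s in range(0, len(X), batch):
                logits = self._forward(X[s:s + batch])
                probs[s:s + batch] = F.softmax(logits).data
        codes = probs.argmax(axis=1).astype(np.int8)
        return Hypnogram(codes, epoch_length_s), probs

    def extract_activations(self, images, layer: str = "first_dense",
                            batch: int = 256) -> np.ndarray:
        """Hidden dense-layer outputs, one row per image.

        ``first_dense`` is the 128-unit layer collecting the CNN
        features; ``last_dense`` is the 64-unit layer feeding the
        softmax.
        """
        if not self.trained:
            raise RuntimeError("model is untrained; call fit() first")
        if layer not in ("first_dense", "last_dense"):
            raise ValueError(
                f"unknown layer {layer!r}; valid names: 'first_dense', 'last_dense'"
            )
        X = _as_batch(images, self.config.input_px)
        rows = []
        with nn.no_grad():
            for s in range(0, len(X), batch):
                cap: dict = {}
                self._forward(X[s:s + batch], capture=cap)
                rows.append(cap[layer])
        if not rows:
            width = {"first_dense": self.config.dense_units[0],
                     "last_dense": self.config.dense_units[-1]}[layer]
            return np.zeros((0, width), np.float32)
        return np.concatenate(rows, axis=0)

    # -- persistence --------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        np.savez(
            path,
            config=json.dumps(cfg),
            trained=np.array(self.trained),
            history=json.dumps(self.history),
            **{f"p{i}": p.data for i, p in enumerate(self.params)},
        )

    @classmethod
    def load(cls, path: str | Path) -> "SleepStageCNN":
        with np.load(str(path), allow_pickle=False) as z:
            cfg = json.loads(str(z["config"]))
            for key in ("filters_per_block", "dense_units", "dropout_rates"):
                cfg[key] = tuple(cfg[key])
            model = cls(ClassifierConfig(**cfg))
            for i, p in enumerate(model.params):
                p.data = z[f"p{i}"]
            model.trained = bool(z["trained"])
            model.history = json.loads(str(z["history"]))
        return model


def build_classifier(config: ClassifierConfig | None = None) -> SleepStageCNN:
    """Construct an untrained classifier from a config (seeded init)."""
    return SleepStageCNN(config)
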