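"""CNN classifier: architecture contracts, training behaviour, inference."""

import numpy as np
import pytest

from sleepscore.classifier import ClassifierConfig, SleepStageCNN, build_classifier
from sleepscore.dataset import ImageDataset
from sleepscore.imaging import EpochImage
from sleepscore.stages import Stage
from sleepscore.workflow import make_subject_images

from conftest import desk_config


@pytest.fixture(scope="module")
def tiny_data():
    """4 small synthetic subjects at 32 px for fast training tests."""
    ds, _ = make_subject_images(4, 60, seed=100, out_px=32)
    return ds


def tiny_config(**overrides):
    base = dict(input_px=32, filters_per_block=(4, 8, 8, 16, 16),
                learning_rate=1e-3, batch_size=16, max_epochs=8,
                patience=3, seed=0)
    base.update(overrides)
    return ClassifierConfig(**base)


class TestArchitecture:
    def test_default_has_five_conv_blocks(self):
        model = build_classifier()
        assert len(model._conv) == 5

    def test_dense_head_starts_128_ends_64(self):
        cfg = ClassifierConfig()
        assert cfg.dense_units[0] == 128 and cfg.dense_units[-1] == 64
        model = build_classifier()
        widths = [w.shape[1] for w, _ in model._dense]
        assert widths == [128, 96, 64, 3]

    def test_five_class_head(self, tiny_data):
        model = SleepStageCNN(tiny_config(n_classes=5))
        X, _ = tiny_data.to_arrays()
        logits = model._forward(X[:4])
        assert logits.shape == (4, 5)

    def test_input_too_small_for_pooling_depth(self):
        with pytest.raises(ValueError, match="minimum"):
            ClassifierConfig(input_px=16).validate()

    def test_non_monotone_dense_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            ClassifierConfig(dense_units=(64, 96, 128)).validate()

    def test_scaled_down_halves_filters(self):
        cfg = ClassifierConfig().scaled_down(64)
        assert cfg.filters_per_block == (8, 16, 32, 64, 64)
        assert cfg.input_px == 64


class TestTraining:
    def test_overcapacity_memorization(self, tiny_data):
        """With no early stop, the CNN memorizes a 30-image subset."""
        sub = ImageDataset(tiny_data.images[:30])
        model = SleepStageCNN(tiny_config(max_epochs=60, patience=10_000,
                                          learning_rate=3e-3))
        model.fit(sub, sub, seed=0)
        _, acc = model.evaluate(sub)
        assert acc == 1.0

    def test_early_stopping_definition(self, tiny_data):
        """If training halts early, the last `patience` epochs did not improve."""
        tr = ImageDataset(tiny_data.images[:120])
        va = ImageDataset(tiny_data.images[120:180])
        model = SleepStageCNN(tiny_config(max_epochs=40, patience=2))
        model.fit(tr, va, seed=1)
        losses = model.history["val_loss"]
        if len(losses) < 40:  # stopped early
            best = min(losses[:-2])
            assert all(l >= best - 1e-6 for l in losses[-2:])

    def test_identical_seed_identical_history(self, tiny_data):
        tr = ImageDataset(tiny_data.images[:80])
        va = ImageDataset(tiny_data.images[80:120])
        runs = []
        for _ in range(2):
            m = SleepStageCNN(tiny_config(max_epochs=3, patience=99))
            m.fit(tr, va, seed=7)
            runs.append(m.history["train_loss"])
        assert runs[0] == runs[1]

    def test_single_class_training_rejected(self, tiny_data):
        wake_only = tiny_data.subset(stage=Stage.WAKE)
        model = SleepStageCNN(tiny_config())
        with pytest.raises(ValueError, match="single class"):
            model.fit(wake_only, wake_only, seed=0)

    def test_size_mismatch_rejected(self, tiny_data):
        model = SleepStageCNN(tiny_config(input_px=64))
        with pytest.raises(ValueError, match="input_px"):
            model.fit(tiny_data, tiny_data, seed=0)


@pytest.fixture(scope="module")
def fitted(tiny_data):
    tr = ImageDataset(tiny_data.images[:150])
    va = ImageDataset(tiny_data.images[150:200])
    model = SleepStageCNN(tiny_config(max_epochs=6))
    return model.fit(tr, va, seed=3), tiny_data


class TestInference:
    def test_probabilities_sum_to_one(self, fitted):
        model, data = fitted
        _, probs = model.predict(ImageDataset(data.images[:40]))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_input_empty_hypnogram(self, fitted):
        model, _ = fitted
        hyp, probs = model.predict([])
        assert len(hyp) == 0 and probs.shape == (0, 3)

    def test_untrained_predict_is_state_error(self):
        model = SleepStageCNN(tiny_config())
        with pytest.raises(RuntimeError, match="untrained"):
            model.predict([])

    def test_batch_permutation_equivariance(self, fitted):
        model, data = fitted
        imgs = data.images[:30]
        _, probs = model.predict(ImageDataset(imgs))
        perm = np.random.default_rng(0).permutation(30)
        _, probs_p = model.predict(ImageDataset([imgs[i] for i in perm]))
        assert np.allclose(probs_p, probs[perm], atol=1e-6)

    def test_activation_widths_and_rows(self, fitted):
        model, data = fitted
        imgs = ImageDataset(data.images[:17])
        first = model.extract_activations(imgs, "first_dense")
        last = model.extract_activations(imgs, "last_dense")
        assert first.shape == (17, 128)
        assert last.shape == (17, 64)

    def test_unknown_layer_lists_valid_names(self, fitted):
        model, data = fitted
        with pytest.raises(ValueError, match="first_dense.*last_dense"):
            model.extract_activations(ImageDataset(data.images[:2]), "conv3")

    def test_save_load_roundtrip(self, fitted, tmp_path):
        model, data = fitted
        model.save(tmp_path / "m.npz")
        back = SleepStageCNN.load(tmp_path / "m.npz")
        imgs = ImageDataset(data.images[:10])
        _, p1 = model.predict(imgs)
        _, p2 = back.predict(imgs)
        assert np.array_equal(p1, p2)


def test_two_epoch_context_not_worse_than_one_epoch():
    """Adding the preceding epoch never costs more than 2 accuracy points
    (mean over 3 seeds) on synthetic data."""
    accs = {1: [], 2: []}
    for mode in (1, 2):
        ds, _ = make_subject_images(4, 150, seed=55, out_px=32,
                                    epochs_per_image=mode)
        sids = sorted(ds.subject_ids)
        from sleepscore.dataset import split_by_subject
        tr, rest = split_by_subject(ds, set(sids[:2]), set(sids[2:]))
        va, ev = split_by_subject(rest, {sids[2]}, {sids[3]})
        for seed in (0, 1, 2):
            m = SleepStageCNN(tiny_config(max_epochs=5, patience=6, seed=seed))
            m.fit(tr, va, seed=seed)
            X, y = ev.to_arrays()
            hyp, _ = m.predict(ev)
            accs[mode].append(float((hyp.stages == y).mean()))
    assert np.mean(accs[2]) >= np.mean(accs[1]) - 0.02
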