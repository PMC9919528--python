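"""CNN construction, augmentation bookkeeping, and training behaviour.

Training tests run at reduced canvas resolution (block-mean downsample)
so the whole suite stays single-CPU friendly; the layer stack is the
same at every resolution.
"""

from __future__ import annotations

import numpy as np
import pytest

import swarmsense as ss
from swarmsense.pattern_classifier import _PATTERNS


def solid_color_dataset(n_per_class: int, seed: int = 0) -> ss.LabeledDataset:
    """Trivially separable stand-in canvases: one solid color per class."""
    rng = np.random.default_rng(seed)
    colors = np.array([[200, 30, 30], [30, 200, 30], [30, 30, 200], [180, 180, 30]])
    images, labels = [], []
    for idx, pattern in enumerate(ss.SwarmPattern):
        for _ in range(n_per_class):
            img = np.tile(colors[idx], (224, 224, 1)).astype(np.uint8)
            img = np.clip(img + rng.integers(-10, 11, img.shape), 0, 255).astype(np.uint8)
            images.append(img)
            labels.append(pattern)
    return ss.LabeledDataset(images=np.stack(images), labels=labels)


class TestBuildModel:
    def test_first_conv_kernel_shape(self):
        model = ss.build_model(ss.CNNConfig(downsample=8))
        conv1 = model.net.layers[0]
        assert conv1.W.shape == (3, 3, 3, 32)

    def test_layer_stack_shapes_consistent(self):
        cfg = ss.CNNConfig(downsample=8)  # 28x28x3 effective input
        model = ss.build_model(cfg)
        # conv(3x3 valid) -> 26 -> pool 13 -> conv 11 -> pool 5
        assert model.flatten_dim == 5 * 5 * 64
        dense1 = model.net.layers[7]
        assert dense1.W.shape == (model.flatten_dim, 1024)
        assert model.net.layers[9].W.shape == (1024, 4)

    def test_softmax_output_normalized(self, rng):
        model = ss.build_model(ss.CNNConfig(downsample=8))
        img = rng.integers(0, 255, (5, 224, 224, 3)).astype(np.uint8)
        probs, _ = ss.predict_batch(model, img)
        assert probs.shape == (5, 4)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_rectifier(self):
        from swarmsense._nn import ReLU

        out = ReLU().forward(np.array([-2.0, 0.0, 3.0]))
        np.testing.assert_array_equal(out, [0.0, 0.0, 3.0])

    def test_output_units_fixed_at_four(self):
        with pytest.raises(ValueError, match="output_units"):
            ss.CNNConfig(output_units=3)


class TestPredict:
    def test_wrong_shape_rejected(self):
        model = ss.build_model(ss.CNNConfig(downsample=8))
        with pytest.raises(ValueError, match="shape"):
            ss.predict(model, np.zeros((100, 100, 3), np.uint8))

    def test_tie_breaks_to_lowest_index(self):
        model = ss.build_model(ss.CNNConfig(downsample=8))
        final = model.net.layers[9]
        final.W[:] = 0.0  # all logits equal -> uniform probabilities
        final.b[:] = 0.0
        probs, label = ss.predict(model, np.zeros((224, 224, 3), np.uint8))
        np.testing.assert_allclose(probs, 0.25, atol=1e-6)
        assert label is ss.SwarmPattern.FOLLOWING  # pattern 1

    def test_argmax_label_mapping(self):
        assert _PATTERNS[int(np.argmax([0.1, 0.7, 0.1, 0.1]))] is ss.SwarmPattern.PARALLEL


class TestAugmentDataset:
    def test_inflation_1200_to_1620(self):
        base = ss.make_pattern_dataset(3, seed=0, sim_config=ss.SwarmSimConfig(steps=15))
        big = ss.LabeledDataset(
            images=np.tile(base.images, (100, 1, 1, 1)), labels=base.labels * 100
        )
        assert len(big) == 1200
        out = ss.augment_dataset(big, ss.AugmentationConfig(multiplier=1.35), seed=0)
        assert len(out) == 1620

    def test_identity_multiplier_unchanged(self):
        data = solid_color_dataset(2)
        cfg = ss.AugmentationConfig(
            multiplier=1.0, rotation_degrees=0, translation=0,
            flip_horizontal=False, flip_vertical=False, crop_fraction=1.0,
        )
        out = ss.augment_dataset(data, cfg, seed=0)
        np.testing.assert_array_equal(out.images, data.images)
        assert out.labels == data.labels

    def test_horizontal_flip_involution(self, rng):
        img = rng.integers(0, 255, (224, 224, 3)).astype(np.uint8)
        np.testing.assert_array_equal(img[:, ::-1][:, ::-1], img)

    def test_labels_preserved_and_reproducible(self):
        data = solid_color_dataset(3)
        cfg = ss.AugmentationConfig(multiplier=2.0)
        a = ss.augment_dataset(data, cfg, seed=5)
        b = ss.augment_dataset(data, cfg, seed=5)
        np.testing.assert_array_equal(a.images, b.images)
        assert a.labels == b.labels
        assert len(a) == 24
        assert set(a.labels) == set(ss.SwarmPattern)

    def test_empty_dataset_rejected(self):
        empty = ss.LabeledDataset(images=np.zeros((0, 224, 224, 3), np.uint8), labels=[])
        with pytest.raises(ValueError, match="empty"):
            ss.augment_dataset(empty, ss.AugmentationConfig(), seed=0)


class TestTrain:
    def test_loss_trace_length(self):
        data = solid_color_dataset(4)
        cfg = ss.CNNConfig(downsample=8, epochs=2, seed=0)
        _, trace = ss.train(ss.build_model(cfg), data, cfg)
        assert len(trace) == 2

    def test_single_class_warns(self):
        data = solid_color_dataset(4)
        only_one = data.subset(np.array([lab == ss.SwarmPattern.SHOAL for lab in data.labels]))
        cfg = ss.CNNConfig(downsample=8, epochs=1, seed=0)
        with pytest.warns(UserWarning, match="single class"):
            ss.train(ss.build_model(cfg), only_one, cfg)

    def test_loss_decreases_on_separable_data(self):
        wins = 0
        for seed in range(10):
            data = solid_color_dataset(4, seed=seed)
            cfg = ss.CNNConfig(downsample=8, epochs=5, seed=seed)
            _, trace = ss.train(ss.build_model(cfg), data, cfg)
            wins += trace[4] < trace[0]
        assert wins >= 9

    def test_seeded_determinism(self):
        data = solid_color_dataset(4)
        cfg = ss.CNNConfig(downsample=8, epochs=2, seed=3)
        _, t1 = ss.train(ss.build_model(cfg), data, cfg)
        _, t2 = ss.train(ss.build_model(cfg), data, cfg)
        assert t1 == t2

    def test_label_permutation_destroys_accuracy(self, pattern_dataset_400):
        """Scrambled training labels drop test accuracy to ~chance: the
        pipeline cannot leak the true labels."""
        data = pattern_dataset_400
        sub = data.subset(np.arange(len(data)) % 5 == 0)  # 80 images
        rng = np.random.default_rng(0)
        scrambled = ss.LabeledDataset(
            images=sub.images,
            labels=[sub.labels[i] for i in rng.permutation(len(sub))],
        )
        scrambled = ss.stratified_split(scrambled, 0.3, seed=0)
        cfg = ss.CNNConfig(downsample=8, epochs=5, seed=0)
        model, _ = ss.train(ss.build_model(cfg), scrambled, cfg)
        acc = ss.evaluate_accuracy(model, scrambled)
        assert acc <= 0.55  # near the 0.25 chance level, far from real runs
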