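"""Four-class CNN over trajectory-marker canvases.

Architecture (fixed by config): conv 32@3x3 -> ReLU -> maxpool 2x2 ->
conv 64@3x3 -> ReLU -> maxpool 2x2 -> flatten -> dense 1024 -> ReLU ->
dense 4 -> softmax, trained with Adam on categorical cross-entropy.
Convolutions are valid (no padding), stride 1.

Inputs are 224x224x3 canvases scaled to [0, 1].  ``CNNConfig.downsample``
optionally block-averages the canvas before the conv stack (a factor of
4 gives 56x56x3); the layer stack itself is unchanged.  This is how the
package runs its reduced-scale training protocol on one CPU.

Augmentation (rotation, translation, flipping, cropping) inflates a
labeled dataset to a target size while preserving labels, mirroring how
a 1200-image corpus is brought up to 1620.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi
from skimage.transform import resize as _resize
from skimage.transform import rotate as _rotate

from . import _nn
from .swarm_synth import SwarmPattern

__all__ = [
    "CNNConfig",
    "AugmentationConfig",
    "LabeledDataset",
    "PatternClassifier",
    "build_model",
    "augment_dataset",
    "stratified_split",
    "train",
    "predict",
    "predict_batch",
    "evaluate_accuracy",
]

_PATTERNS = list(SwarmPattern)  # index 0..3 <-> patterns 1..4


@dataclass
class CNNConfig:
    """Classifier hyperparameters.

    ``epochs=25`` and the layer sizes are the reference protocol; the
    Adam learning rate and batch size are conventional defaults (the
    reference names the optimizer but no hyperparameters).
    """

    input_shape: tuple[int, int, int] = (224, 224, 3)
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel_size: int = 3
    dense1_units: int = 1024
    output_units: int = 4
    learning_rate: float = 1e-3
    epochs: int = 25
    batch_size: int = 32
    downsample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_units != 4:
            raise ValueError("output_units must be 4 (the four-pattern corpus)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        h, w, c = self.input_shape
        if c != 3:
            raise ValueError("input must have 3 channels")
        if h % self.downsample or w % self.downsample:
            raise ValueError("downsample must divide the input height and width")

    @property
    def effective_input_shape(self) -> tuple[int, int, int]:
        h, w, c = self.input_shape
        return (h // self.downsample, w // self.downsample, c)


@dataclass
class AugmentationConfig:
    """Augmentation transforms and the dataset inflation factor.

    ``multiplier`` sets the output/input size ratio (1.35 takes 1200
    images to 1620); each synthesized image is a randomly transformed
    copy of a source image and keeps the source label.
    """

    rotation_degrees: float = 15.0
    translation: int = 10
    flip_horizontal: bool = True
    flip_vertical: bool = False
    crop_fraction: float = 0.9
    multiplier: float = 1.35

    def __post_init__(self) -> None:
        if not 0 < self.crop_fraction <= 1:
            raise ValueError("crop_fraction must be in (0, 1]")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.rotation_degrees < 0 or self.translation < 0:
            raise ValueError("transform ranges must be >= 0")

    @property
    def any_transform_enabled(self) -> bool:
        return bool(
            self.rotation_degrees > 0
            or self.translation > 0
            or self.flip_horizontal
            or self.flip_vertical
            or self.crop_fraction < 1
        )


@dataclass
class LabeledDataset:
    """Images (N, 224, 224, 3) uint8 with one SwarmPattern label each."""

    images: np.ndarray
    labels: list[SwarmPattern]
    split: np.ndarray | None = None  # per-sample "train"/"test" tags

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if self.split is not None and len(self.split) != len(self.labels):
            raise ValueError("split tags must match dataset length")

    def __len__(self) -> int:
        return len(self.labels)

    def label_indices(self) -> np.ndarray:
        return np.array([_PATTERNS.index(lab) for lab in self.labels])

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        idx = np.flatnonzero(mask)
        return LabeledDataset(
            images=self.images[idx],
            labels=[self.labels[i] for i in idx],
            split=None if self.split is None else self.split[idx],
        )


# ---------------------------------------------------------------------------
# model


class PatternClassifier:
    """The layer stack plus its preprocessing contract."""

    def __init__(self, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, w, c = config.effective_input_shape
        k = config.kernel_size
        h1, w1 = (h - k + 1) // 2, (w - k + 1) // 2  # after conv1 + pool
        h2, w2 = (h1 - k + 1) // 2, (w1 - k + 1) // 2  # after conv2 + pool
        if h2 < 1 or w2 < 1:
            raise ValueError("input too small for the layer stack")
        self.flatten_dim = h2 * w2 * config.conv2_filters
        self.net = _nn.Sequential([
            _nn.Conv2D(c, config.conv1_filters, k, rng),
            _nn.ReLU(),
            _nn.MaxPool2x2(),
            _nn.Conv2D(config.conv1_filters, config.conv2_filters, k, rng),
            _nn.ReLU(),
            _nn.MaxPool2x2(),
            _nn.Flatten(),
            _nn.Dense(self.flatten_dim, config.dense1_units, rng),
            _nn.ReLU(),
            _nn.Dense(config.dense1_units, config.output_units, rng),
        ])
        self.loss_trace: list[float] = []

    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """uint8 canvases -> float32 in [0, 1], block-averaged by ``downsample``."""
        x = np.asarray(images)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"expected images of shape {self.config.input_shape}, got {x.shape[1:]}"
            )
        x = x.astype(np.float32) / 255.0
        ds = self.config.downsample
        if ds > 1:
            n, h, w, c = x.shape
            x = x.reshape(n, h // ds, ds, w // ds, ds, c).mean(axis=(2, 4))
        return x

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"config": self.config, "net": self.net,
                         "loss_trace": self.loss_trace}, fh)

    @classmethod
    def load(cls, path) -> "PatternClassifier":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(blob["config"])
        model.net = blob["net"]
        model.loss_trace = blob["loss_trace"]
        return model


def build_model(config: CNNConfig | None = None) -> PatternClassifier:
    """Construct the untrained classifier for a config."""
    return PatternClassifier(config if config is not None else CNNConfig())


# ---------------------------------------------------------------------------
# augmentation


def _augment_one(img: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    out = img
    if cfg.flip_horizontal and rng.random() < 0.5:
        out = out[:, ::-1]
    if cfg.flip_vertical and rng.random() < 0.5:
        out = out[::-1, :]
    if cfg.rotation_degrees > 0:
        angle = rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees)
        # nearest-neighbour keeps marker colors exact
        out = _rotate(out, angle, order=0, preserve_range=True).astype(np.uint8)
    if cfg.translation > 0:
        ty = rng.integers(-cfg.translation, cfg.translation + 1)
        tx = rng.integers(-cfg.translation, cfg.translation + 1)
        out = _ndi.shift(out, (ty, tx, 0), order=0, mode="constant", cval=0)
    if cfg.crop_fraction < 1:
        h, w = out.shape[:2]
        ch, cw = int(round(h * cfg.crop_fraction)), int(round(w * cfg.crop_fraction))
        y0 = rng.integers(0, h - ch + 1)
        x0 = rng.integers(0, w - cw + 1)
        crop = out[y0 : y0 + ch, x0 : x0 + cw]
        out = _resize(crop, (h, w), order=0, preserve_range=True,
                      anti_aliasing=False).astype(np.uint8)
    return np.ascontiguousarray(out)


def augment_dataset(
    data: LabeledDataset, config: AugmentationConfig | None = None, seed: int = 0
) -> LabeledDataset:
    """Inflate a dataset to ``round(len(data) * multiplier)`` images.

    Originals are kept; the extras are randomly transformed copies with
    their source labels.  Reproducible given the seed.
    """
    if config is None:
        config = AugmentationConfig()
    if len(data) == 0:
        raise ValueError("cannot augment an empty dataset")
    target = int(round(len(data) * config.multiplier))
    n_extra = target - len(data)
    if n_extra == 0 or not config.any_transform_enabled:
        if n_extra > 0:
            raise ValueError(
                "multiplier > 1 requires at least one enabled transform"
            )
        return LabeledDataset(images=data.images.copy(), labels=list(data.labels))
    rng = np.random.default_rng(seed)
    sources = rng.integers(0, len(data), size=n_extra)
    extra_imgs = [_augment_one(data.images[i], config, rng) for i in sources]
    extra_labels = [data.labels[i] for i in sources]
    return LabeledDataset(
        images=np.concatenate([data.images, np.stack(extra_imgs)], axis=0),
        labels=list(data.labels) + extra_labels,
    )


# ---------------------------------------------------------------------------
# train / evaluate / predict


def stratified_split(
    data: LabeledDataset, test_fraction: float = 0.3, seed: int = 0
) -> LabeledDataset:
    """Tag samples "train"/"test", stratified by class, seeded."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = data.label_indices()
    split = np.full(len(data), "train", dtype=object)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_test = int(round(len(idx) * test_fraction))
        split[rng.permutation(idx)[:n_test]] = "test"
    return LabeledDataset(images=data.images, labels=data.labels,
                          split=np.asarray(split, dtype=object))


def train(
    model: PatternClassifier, data: LabeledDataset, config: CNNConfig | None = None
) -> tuple[PatternClassifier, list[float]]:
    """Fit on the dataset's train split (all samples when untagged).

    Returns the model and its per-epoch mean-loss trace.  The config
    seed fixes shuffling; initialization was fixed at build time.
    """
    if config is None:
        config = model.config
    if data.split is not None:
        data = data.subset(np.asarray(data.split) == "train")
    if len(data) == 0:
        raise ValueError("training split is empty")
    labels = data.label_indices()
    if len(np.unique(labels)) < 2:
        warnings.warn("training set contains a single class", stacklevel=2)
    x = model.preprocess(data.images)
    trace = model.net.fit(
        x, labels,
        epochs=config.epochs, batch_size=config.batch_size,
        lr=config.learning_rate, seed=config.seed,
    )
    model.loss_trace = trace
    return model, trace


def predict_batch(model: PatternClassifier, images: np.ndarray) -> tuple[np.ndarray, list[SwarmPattern]]:
    """Probabilities (N, 4) and argmax labels (lowest index wins ties)."""
    x = model.preprocess(images)
    probs = model.net.predict_proba(x)
    labels = [_PATTERNS[int(np.argmax(p))] for p in probs]
    return probs, labels


def predict(model: PatternClassifier, image: np.ndarray) -> tuple[np.ndarray, SwarmPattern]:
    """Classify one 224x224x3 canvas."""
    image = np.asarray(image)
    if image.shape != tuple(model.config.input_shape):
        raise ValueError(
            f"expected image of shape {model.config.input_shape}, got {image.shape}"
        )
    probs, labels = predict_batch(model, image[None])
    return probs[0], labels[0]


def evaluate_accuracy(model: PatternClassifier, data: LabeledDataset) -> float:
    """Accuracy on the dataset's test split (all samples when untagged)."""
    if data.split is not None:
        data = data.subset(np.asarray(data.split) == "test")
    if len(data) == 0:
        raise ValueError("evaluation split is empty")
    _, predicted = predict_batch(model, data.images)
    truth = data.label_indices()
    pred_idx = np.array([_PATTERNS.index(lab) for lab in predicted])
    return float((truth == pred_idx).mean())
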