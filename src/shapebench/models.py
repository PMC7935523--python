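"""Classifier contract, input-size presets, and the reference classifier.

The learning/transfer protocol only needs three behaviors from a model:
seedable construction, ``train_one_epoch`` over a labeled image batch, and
deterministic ``predict`` between training calls.  Anything honoring
:class:`Classifier` plugs into the protocol — the bundled reference model,
the trivial oracles used in tests, or adapters around external networks.

Input sizes for the four benchmark architectures (AlexNet 227, VGG-19 224,
ResNet-101 224, Inception-ResNet-v2 299) are exposed as presets next to
the 64 px ``reference`` size used for desk-scale runs.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .nn import SmallConvNet
from .raster import MODEL_INPUT_SIZES

__all__ = [
    "Classifier",
    "ReferenceCNNConfig",
    "ReferenceCNN",
    "build_reference_cnn",
    "ConstantClassifier",
    "FunctionClassifier",
    "evaluate",
    "input_preset",
]


def input_preset(name: str) -> tuple[int, int, int]:
    """(height, width, channels) expected by the named model."""
    if name not in MODEL_INPUT_SIZES:
        raise ValueError(f"unknown model name: {name!r}")
    s = MODEL_INPUT_SIZES[name]
    return (s, s, 3)


class Classifier(abc.ABC):
    """Behavioral contract consumed by the experiment protocol."""

    #: square input edge length in pixels (3 channels assumed)
    input_size: int

    @abc.abstractmethod
    def train_one_epoch(
        self, images: np.ndarray, labels: np.ndarray, rng: np.random.Generator
    ) -> None:
        """One pass over the labeled set; ``rng`` drives batch shuffling."""

    @abc.abstractmethod
    def predict(self, images: np.ndarray) -> np.ndarray:
        """Class labels for a stack of images; deterministic between updates."""


def evaluate(classifier: Classifier, images: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy percent: 100 x correct / total."""
    if len(images) == 0:
        raise ValueError("cannot evaluate on an empty set")
    pred = classifier.predict(images)
    return 100.0 * float(np.mean(pred == np.asarray(labels)))


@dataclass(frozen=True)
class ReferenceCNNConfig:
    """Hyperparameters of the bundled desk-scale classifier.

    Three 3x3 convolution blocks (16/32/64 channels, each ReLU + 2x max
    pool), one hidden dense layer of width 128, two-way output; SGD with
    learning rate 0.01 and momentum 0.9, batch size 32, 64x64x3 inputs.
    """

    input_size: int = 64
    widths: tuple[int, int, int] = (16, 32, 64)
    hidden: int = 128
    n_classes: int = 2
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32


class ReferenceCNN(Classifier):
    """Small from-scratch convolutional network trained on the CPU.

    Implemented directly on NumPy (see :mod:`shapebench.nn`); weights are
    initialized from the given seed, so two models built with the same
    seed make identical predictions before and after identical training.
    """

    def __init__(self, config: ReferenceCNNConfig | None = None, seed: int = 0):
        self.config = config or ReferenceCNNConfig()
        if self.config.input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8")
        self.input_size = self.config.input_size
        self.net = SmallConvNet(
            self.config.input_size,
            self.config.n_classes,
            seed,
            widths=self.config.widths,
            hidden=self.config.hidden,
            lr=self.config.learning_rate,
            momentum=self.config.momentum,
        )

    @staticmethod
    def _prepare(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images)
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError("expected (N, H, W, 3) images")
        return (x.astype(np.float32) / 255.0) - 0.5

    def train_one_epoch(
        self, images: np.ndarray, labels: np.ndarray, rng: np.random.Generator
    ) -> None:
        x = self._prepare(images)
        y = np.asarray(labels, dtype=np.int64)
        order = rng.permutation(len(x))
        bs = self.config.batch_size
        for start in range(0, len(x), bs):
            idx = order[start : start + bs]
            self.net.train_batch(x[idx], y[idx])

    def predict(self, images: np.ndarray) -> np.ndarray:
        x = self._prepare(images)
        out = []
        for start in range(0, len(x), 256):
            out.append(self.net.logits(x[start : start + 256]).argmax(axis=1))
        return np.concatenate(out)


def build_reference_cnn(
    config: ReferenceCNNConfig | None = None, seed: int = 0
) -> ReferenceCNN:
    return ReferenceCNN(config, seed)


class ConstantClassifier(Classifier):
    """Always predicts one class; on balanced data it scores exactly 50%."""

    input_size = 64

    def __init__(self, label: int = 0):
        self.label = label

    def train_one_epoch(self, images, labels, rng) -> None:
        pass

    def predict(self, images) -> np.ndarray:
        return np.full(len(images), self.label, dtype=np.int64)


class FunctionClassifier(Classifier):
    """Predicts with a fixed image -> label function (a test oracle).

    With a function that recovers the true class from the image (e.g., the
    hole count for disk-vs-ring), this realizes the perfect classifier:
    100% on learning and transfer sets alike.
    """

    input_size = 64

    def __init__(self, fn: Callable[[np.ndarray], int]):
        self.fn = fn

    def train_one_epoch(self, images, labels, rng) -> None:
        pass

    def predict(self, images) -> np.ndarray:
        return np.array([self.fn(img) for img in images], dtype=np.int64)
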