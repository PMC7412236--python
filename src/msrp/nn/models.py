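"""The three image classifiers: FCN, ResNet, and a pooled CNN baseline.

* **FCN** — three conv(5x5)-batchnorm-ReLU blocks with channel widths
  (128, 256, 128), no fully-connected layers, global average pooling and a
  softmax head.  Because it has no FC layers, it accepts any input side
  length >= 5 without structural change.
* **ResNet** — three residual blocks, each internally the FCN's three
  conv-BN(-ReLU) stages, with an additive shortcut (identity where channel
  counts match, 1x1 conv + batchnorm otherwise), then global average
  pooling and softmax.
* **CNNBaseline** — the traditional pooled CNN used as the image-encoding
  baseline: two 3x3 conv layers of 32 channels each followed by 2x2 max
  pooling, two fully-connected layers of 125 units, and a softmax output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    Add,
    BatchNorm2D,
    Conv2D,
    Dense,
    Flatten,
    GlobalAvgPool,
    Layer,
    MaxPool2x2,
    ReLU,
    softmax,
)

__all__ = ["NetworkSpec", "Network", "build_network"]

ARCHITECTURES = ("fcn", "resnet", "cnn")

FCN_CHANNELS = (128, 256, 128)
FCN_KERNEL = 5


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture choice, input side length, and number of classes."""

    kind: str
    input_size: int
    n_classes: int

    def __post_init__(self) -> None:
        kind = self.kind.lower()
        if kind not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.kind!r}; choose from {ARCHITECTURES}")
        object.__setattr__(self, "kind", kind)
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if kind == "cnn" and self.input_size < 4:
            raise ValueError(
                f"input size {self.input_size} too small for two 2x2 pooling stages (need >= 4)"
            )
        if self.input_size < 2:
            raise ValueError("input size must be >= 2")


class Network:
    """A feed-forward stack of layers with a softmax cross-entropy head."""

    def __init__(self, spec: NetworkSpec, layers: list[Layer]):
        self.spec = spec
        self.layers = layers

    def params(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for lay in self.layers for g in lay.grads()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits for a (N, 1, H, W) float32 batch."""
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for lay in reversed(self.layers):
            d = lay.backward(d)

    def conv_weight_count(self) -> int:
        """Total convolutional kernel weights (excluding biases, BN, head)."""

        def _count(layers: list[Layer]) -> int:
            total = 0
            for lay in layers:
                if isinstance(lay, Conv2D):
                    total += lay.W.size
                elif isinstance(lay, Add):
                    total += _count(lay.main) + _count(lay.shortcut)
            return total

        return _count(self.layers)


def _conv_bn_relu(c_in: int, c_out: int, k: int, rng) -> list[Layer]:
    return [Conv2D(c_in, c_out, k, rng), BatchNorm2D(c_out), ReLU()]


def _residual_block(c_in: int, rng) -> Add:
    c1, c2, c3 = FCN_CHANNELS
    main: list[Layer] = [
        *_conv_bn_relu(c_in, c1, FCN_KERNEL, rng),
        *_conv_bn_relu(c1, c2, FCN_KERNEL, rng),
        Conv2D(c2, c3, FCN_KERNEL, rng),
        BatchNorm2D(c3),
    ]
    shortcut: list[Layer] = []
    if c_in != c3:
        shortcut = [Conv2D(c_in, c3, 1, rng), BatchNorm2D(c3)]
    return Add(main, shortcut)


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Instantiate a trainable model with seeded weight initialization."""
    rng = np.random.Generator(np.random.PCG64(seed))
    c1, c2, c3 = FCN_CHANNELS
    if spec.kind == "fcn":
        layers: list[Layer] = [
            *_conv_bn_relu(1, c1, FCN_KERNEL, rng),
            *_conv_bn_relu(c1, c2, FCN_KERNEL, rng),
            *_conv_bn_relu(c2, c3, FCN_KERNEL, rng),
            GlobalAvgPool(),
            Dense(c3, spec.n_classes, rng),
        ]
    elif spec.kind == "resnet":
        layers = [
            _residual_block(1, rng),
            ReLU(),
            _residual_block(c3, rng),
            ReLU(),
            _residual_block(c3, rng),
            ReLU(),
            GlobalAvgPool(),
            Dense(c3, spec.n_classes, rng),
        ]
    else:  # cnn baseline
        side = spec.input_size // 2 // 2
        layers = [
            Conv2D(1, 32, 3, rng),
            ReLU(),
            MaxPool2x2(),
            Conv2D(32, 32, 3, rng),
            ReLU(),
            MaxPool2x2(),
            Flatten(),
            Dense(32 * side * side, 125, rng),
            ReLU(),
            Dense(125, 125, rng),
            ReLU(),
            Dense(125, spec.n_classes, rng),
        ]
    return Network(spec, layers)
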