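"""The reference-class classification network.

A five-block inverted-residual CNN: each block halves the spatial
resolution (output strides 2, 4, 8, 16, 32 on the input), block 5 ends with
a standard 3x3 convolution to a 1024-wide feature map, and global average
pooling feeds a linear head over the N reference classes with a softmax at
the output.  An inverted-residual layer expands channels with a 1x1
convolution, filters with a depthwise 3x3, and projects back with a linear
1x1, with an identity skip when the resolution and width are unchanged.

A ``width_multiplier`` scales every channel count (rounded to multiples of
8) so the same architecture runs from full scale (224 px input) down to a
CPU-friendly desk preset.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .layers import (
    BatchNorm2d,
    Conv2d,
    DepthwiseConv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    ReLU6,
    Sequential,
    softmax,
)

__all__ = ["NetworkConfig", "VolumeClassifier", "build_network", "preprocess_images"]

# (expansion channels, output channels, repeats) per inverted-residual stage;
# the first layer of each down-sampling stage carries stride 2
_STAGES = [
    ("block1", 96, 16, 1, 1),
    ("block2", 192, 32, 3, 2),
    ("block3", 384, 64, 3, 2),
    ("block4", 576, 96, 4, 2),
    ("block5", 960, 160, 3, 2),
]
_STEM_CHANNELS = 32
_HEAD_CHANNELS = 1024


def _scaled(channels: int, multiplier: float, divisor: int = 8) -> int:
    """Scale a channel count and round to the nearest multiple of ``divisor``."""
    v = channels * multiplier
    return max(divisor, int(v + divisor / 2) // divisor * divisor)


@dataclass(frozen=True)
class NetworkConfig:
    n_classes: int
    input_size: int = 224
    width_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be a multiple of 32 (five stride-2 stages)")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "input_size": self.input_size,
            "width_multiplier": self.width_multiplier,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            int(d["n_classes"]),
            int(d["input_size"]),
            float(d["width_multiplier"]),
            int(d.get("seed", 0)),
        )


class _SeedStream:
    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)

    def __call__(self) -> int:
        return int(self._rng.integers(2**31))


class InvertedResidual(Layer):
    """expand (1x1) -> depthwise 3x3 -> project (1x1), identity skip when possible."""

    def __init__(self, c_in: int, c_exp: int, c_out: int, stride: int, seeds: _SeedStream):
        self.use_skip = stride == 1 and c_in == c_out
        self.branch = Sequential(
            Conv2d(c_in, c_exp, k=1, seed=seeds()),
            BatchNorm2d(c_exp),
            ReLU6(),
            DepthwiseConv2d(c_exp, k=3, stride=stride, seed=seeds()),
            BatchNorm2d(c_exp),
            ReLU6(),
            Conv2d(c_exp, c_out, k=1, seed=seeds()),
            BatchNorm2d(c_out),
        )

    def forward(self, x, train=False):
        out = self.branch.forward(x, train=train)
        if self.use_skip:
            out = out + x
        return out

    def backward(self, dout):
        dx = self.branch.backward(dout)
        if self.use_skip:
            dx = dx + dout
        return dx

    def params(self):
        return self.branch.params()


class VolumeClassifier:
    """Table-style five-block network emitting reference-class probabilities."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        seeds = _SeedStream(config.seed)
        m = config.width_multiplier
        self.blocks: dict[str, Sequential] = {}

        c_stem = _scaled(_STEM_CHANNELS, m)
        stem_layers = [Conv2d(3, c_stem, k=3, stride=2, seed=seeds()), BatchNorm2d(c_stem), ReLU6()]
        c_in = c_stem
        for name, c_exp, c_out, repeats, stride in _STAGES:
            layers = [] if name != "block1" else stem_layers
            ce, co = _scaled(c_exp, m), _scaled(c_out, m)
            for r in range(repeats):
                layers.append(
                    InvertedResidual(c_in, ce, co, stride if r == 0 else 1, seeds)
                )
                c_in = co
            if name == "block5":
                c_head = _scaled(_HEAD_CHANNELS, m)
                layers += [Conv2d(c_in, c_head, k=3, stride=1, seed=seeds()), BatchNorm2d(c_head), ReLU6()]
                c_in = c_head
            self.blocks[name] = Sequential(*layers)

        self.n_features = c_in
        self.pool = GlobalAvgPool()
        self.head = Linear(c_in, config.n_classes, seed=seeds())
        self._trunk = Sequential(*self.blocks.values())

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a preprocessed (B, 3, H, W) float32 batch in [-1, 1]."""
        feats = self._trunk.forward(x, train=train)
        return self.head.forward(self.pool.forward(feats, train=train), train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self._trunk.backward(self.pool.backward(self.head.backward(dlogits)))

    def params(self):
        return self._trunk.params() + self.head.params()

    def block_output_shapes(self, input_size: int | None = None) -> dict[str, tuple]:
        """Per-block output shapes on a single input image (architecture audit)."""
        size = input_size or self.config.input_size
        x = np.zeros((1, 3, size, size), dtype=np.float32)
        shapes = {}
        for name, block in self.blocks.items():
            x = block.forward(x)
            shapes[name] = x.shape
        return shapes

    # ---- inference ----------------------------------------------------------

    def predict_probabilities(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch of RGB images.

        Accepts (B, H, W, 3) or (H, W, 3) uint8/float arrays; images are
        resized to the configured input size if needed, scaled to [-1, 1]
        and passed through the network in eval mode.  Rows are non-negative
        and sum to 1; order is preserved.
        """
        x = preprocess_images(images, self.config.input_size)
        return softmax(self.forward(x, train=False))

    # ---- serialization -------------------------------------------------------

    def _bn_layers(self):
        out = []

        def walk(layer):
            if isinstance(layer, Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, InvertedResidual):
                walk(layer.branch)
            elif isinstance(layer, BatchNorm2d):
                out.append(layer)

        walk(self._trunk)
        return out

    def save(self, path: str, sidecar: dict | None = None) -> None:
        """Write weights as ``<path>`` (npz) plus a JSON sidecar ``<path>.json``."""
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for j, bn in enumerate(self._bn_layers()):
            arrays[f"bn_{j}_mean"] = bn.running_mean
            arrays[f"bn_{j}_var"] = bn.running_var
        np.savez(path, **arrays)
        meta = {"network": self.config.to_dict()}
        meta.update(sidecar or {})
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=float)

    @classmethod
    def load(cls, path: str) -> tuple["VolumeClassifier", dict]:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        model = cls(NetworkConfig.from_dict(meta["network"]))
        if not str(path).endswith(".npz") and not os.path.exists(path):
            path = str(path) + ".npz"
        data = np.load(path)
        for i, p in enumerate(model.params()):
            p.value = data[f"param_{i}"].astype(np.float32)
        for j, bn in enumerate(model._bn_layers()):
            bn.running_mean = data[f"bn_{j}_mean"].astype(np.float32)
            bn.running_var = data[f"bn_{j}_var"].astype(np.float32)
        return model, meta


def build_network(config: NetworkConfig) -> VolumeClassifier:
    """Construct the classification network for a given configuration."""
    return VolumeClassifier(config)


def preprocess_images(images: np.ndarray, input_size: int) -> np.ndarray:
    """RGB rasters -> (B, 3, S, S) float32 batch scaled to [-1, 1]."""
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected (B, H, W, 3) images, got shape {arr.shape}")
    if arr.shape[1] != input_size or arr.shape[2] != input_size:
        resized = np.empty((arr.shape[0], input_size, input_size, 3), dtype=np.float32)
        for i, im in enumerate(arr):
            pil = Image.fromarray(np.asarray(np.clip(im, 0, 255), dtype=np.uint8))
            resized[i] = np.asarray(pil.resize((input_size, input_size), Image.BILINEAR))
        arr = resized
    x = arr.astype(np.float32) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))
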