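"""Training of the reference-class network.

Plain stochastic gradient descent (with heavy-ball momentum) against
softmax cross-entropy on one-hot class labels; the learning rate starts at
0.01 and is divided by 10 after every 5000 steps.  The only augmentation is
a random horizontal mirror — it changes pixels, never labels.  All
randomness flows from the policy seed, so a run is reproducible
step-for-step.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from ..reference import ReferenceScheme
from .layers import softmax_cross_entropy
from .network import VolumeClassifier, preprocess_images

__all__ = ["TrainingPolicy", "learning_rate", "train", "load_split_images"]


@dataclass(frozen=True)
class TrainingPolicy:
    """SGD schedule: lr(t) = initial_lr / decay_factor ** floor(t / decay_steps)."""

    initial_lr: float = 0.01
    lr_decay_steps: int = 5000
    lr_decay_factor: float = 10.0
    batch_size: int = 128
    total_steps: int = 15000
    momentum: float = 0.9
    augment_mirror: bool = True
    seed: int = 0
    log_every: int = 10

    def to_dict(self) -> dict:
        return {
            "initial_lr": self.initial_lr,
            "lr_decay_steps": self.lr_decay_steps,
            "lr_decay_factor": self.lr_decay_factor,
            "batch_size": self.batch_size,
            "total_steps": self.total_steps,
            "momentum": self.momentum,
            "augment_mirror": self.augment_mirror,
            "seed": self.seed,
        }


# the desk preset scales the run to a single CPU: small inputs, a thin
# network and a short schedule, same architecture and policy shape
DESK_POLICY = TrainingPolicy(batch_size=16, total_steps=900)


def learning_rate(policy: TrainingPolicy, step: int) -> float:
    """Learning rate in effect at 1-based ``step``."""
    return policy.initial_lr / policy.lr_decay_factor ** (step // policy.lr_decay_steps)


def load_split_images(
    manifest: pd.DataFrame, base_dir: str, split: str
) -> tuple[np.ndarray, np.ndarray]:
    """Load all images of a manifest split; returns (images NHWC uint8, labels 1..N)."""
    rows = manifest[manifest["split"] == split]
    if rows.empty:
        raise ValueError(f"manifest has no '{split}' split")
    images = np.stack(
        [
            np.asarray(Image.open(os.path.join(base_dir, p)).convert("RGB"))
            for p in rows["image_path"]
        ]
    )
    return images, rows["class"].to_numpy(dtype=np.int64)


def train(
    model: VolumeClassifier,
    manifest: pd.DataFrame,
    scheme: ReferenceScheme,
    policy: TrainingPolicy,
    images_dir: str = ".",
) -> pd.DataFrame:
    """Train in place; returns the log as a frame (step, lr, loss, train_top1)."""
    n = scheme.n_classes
    if model.config.n_classes != n:
        raise ValueError(
            f"model emits {model.config.n_classes} classes but scheme has {n}"
        )
    images, labels = load_split_images(manifest, images_dir, "train")
    if labels.min() < 1 or labels.max() > n:
        raise ValueError("train labels outside 1..N")
    x_all = preprocess_images(images, model.config.input_size)
    y_all = labels - 1

    rng = np.random.default_rng(policy.seed)
    params = model.params()
    velocity = [np.zeros_like(p.value) for p in params]
    order = rng.permutation(len(y_all))
    cursor = 0
    log = []
    for step in range(1, policy.total_steps + 1):
        if cursor + policy.batch_size > len(order):
            order = rng.permutation(len(y_all))
            cursor = 0
        idx = order[cursor : cursor + policy.batch_size]
        cursor += policy.batch_size
        xb = x_all[idx]
        if policy.augment_mirror:
            flip = rng.random(len(idx)) < 0.5
            xb = xb.copy()
            xb[flip] = xb[flip, :, :, ::-1]
        yb = y_all[idx]

        logits = model.forward(xb, train=True)
        loss, dlogits, probs = softmax_cross_entropy(logits, yb)
        for p in params:
            p.grad[...] = 0.0
        model.backward(dlogits)

        lr = learning_rate(policy, step)
        for p, v in zip(params, velocity):
            v *= policy.momentum
            v -= lr * p.grad
            p.value += v

        if step % policy.log_every == 0 or step == 1 or step == policy.total_steps:
            top1 = float((probs.argmax(axis=1) == yb).mean())
            log.append({"step": step, "lr": lr, "loss": loss, "train_top1": top1})
    return pd.DataFrame(log, columns=["step", "lr", "loss", "train_top1"])
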