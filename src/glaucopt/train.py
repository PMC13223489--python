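"""Training loop: seeded mini-batch gradient descent under mean BCE.

Supports selective fine-tuning: a :class:`~glaucopt.arch.FreezePlan` (or an
explicit list of layer names) pins the named units' parameters — frozen
parameters are bit-identical before and after training, while unfrozen
layers follow the chosen optimizer's update rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._rng import rng_for
from .arch import ArchitectureSpec, FreezePlan, OPTIMIZER_CHOICES
from .data import ImageManifest, load_and_normalize
from .evaluate import bce_loss
from .nn import compile_network, make_optimizer
from .nn.network import Network

__all__ = ["TrainConfig", "load_images", "train", "fit", "predict_proba", "accuracy"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Budget and optimizer of one training run.

    ``learning_rate=None`` uses the optimizer's own default (1e-3 adaptive,
    1e-2 SGD); fine-tuning runs conventionally pass 1e-4.
    """

    epochs: int = 16
    optimizer: str = "adam"
    learning_rate: float | None = None
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.epochs, int) and self.epochs >= 1):
            raise ValueError(f"epochs must be an integer >= 1, got {self.epochs!r}")
        if self.optimizer not in OPTIMIZER_CHOICES:
            raise ValueError(f"optimizer must be one of {OPTIMIZER_CHOICES}, got {self.optimizer!r}")
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def load_images(manifest: ImageManifest, image_size: int):
    """Stack a manifest's images into (X, y) arrays (glaucoma = 1)."""
    x = np.stack([load_and_normalize(r.path, image_size) for r in manifest])
    return x.astype(np.float32), manifest.labels().astype(np.float32)


def predict_proba(net: Network, x: np.ndarray) -> np.ndarray:
    return net.predict(x)


def accuracy(y, p, threshold: float = 0.5) -> float:
    """Fraction correct at a threshold (ties classified positive)."""
    pred = (np.asarray(p) >= threshold).astype(int)
    return float(np.mean(pred == np.asarray(y).astype(int)))


def fit(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    freeze=None,
):
    """Train a compiled network in place; returns the per-epoch history.

    ``freeze`` may be a FreezePlan (resolved through the spec's unit map) or
    an iterable of layer names.  Raises on a non-finite training loss.
    """
    if len(x_train) == 0:
        raise ValueError("empty training data")
    if freeze is not None:
        if isinstance(freeze, FreezePlan):
            net.apply_freeze_plan(freeze)
        else:
            net.freeze_layers(freeze)
    opt = make_optimizer(config.optimizer, lr=config.learning_rate)
    layers = net.trainable_layers()
    n = len(x_train)
    history = []
    for epoch in range(config.epochs):
        order = rng_for(config.seed, "shuffle", epoch).permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            p = net.forward(xb, training=True)
            loss = bce_loss(yb, p)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1} "
                    f"(optimizer={config.optimizer}, lr={config.learning_rate})"
                )
            net.backward_from_bce(yb)
            opt.step(layers)
            losses.append(loss)
        record = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if x_val is not None and len(x_val):
            pv = net.predict(x_val)
            record["val_loss"] = bce_loss(y_val, pv)
            record["val_acc"] = accuracy(y_val, pv)
        history.append(record)
        logger.debug("epoch %d: %s", epoch + 1, record)
    return history


def train(
    spec: ArchitectureSpec,
    freeze,
    config: TrainConfig,
    train_manifest: ImageManifest,
    val_manifest: ImageManifest | None = None,
):
    """Compile a spec, load the manifests and train.

    Returns (network, history).  Weight initialization, batch order and
    dropout are all keyed to ``config.seed``, so two identical calls give
    identical parameters and history.
    """
    image_size = spec.input_shape[0]
    x_train, y_train = load_images(train_manifest, image_size)
    if val_manifest is not None and len(val_manifest):
        x_val, y_val = load_images(val_manifest, image_size)
    else:
        x_val = y_val = None
    net = compile_network(spec, seed=config.seed)
    history = fit(net, x_train, y_train, config, x_val, y_val, freeze=freeze)
    return net, history
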