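"""Residual-CNN image enhancement: build, train, apply.

The network maps a reconstructed, envelope-normalized tracking image to
an enhanced image whose point-spread function approaches the Gaussian
ground-truth kernel it was trained with.  Training minimises the L1
loss between network output and ground truth on random 64x64 patches
with Adam; the full-image validation loss is evaluated every epoch and
the best-validation weights are kept.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import TrainingPair, extract_patches
from .nn import Adam, ResidualCNN, l1_loss
from .reconstruction import TrackingImage

__all__ = ["NetworkSpec", "TrainSpec", "TrainHistory", "build_network", "train", "enhance"]


@dataclass(frozen=True)
class NetworkSpec:
    """Residual network hyperparameters (defaults: 16 blocks of two
    64-channel 3x3 convolutions with ReLU between them)."""

    n_blocks: int = 16
    channels: int = 64
    conv_kernel: int = 3
    nonlinearity: str = "relu"

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.channels, self.conv_kernel) < 1:
            raise ValueError("all network counts must be >= 1")
        if self.nonlinearity != "relu":
            raise ValueError("only 'relu' nonlinearity is supported")


@dataclass(frozen=True)
class TrainSpec:
    """Training hyperparameters.

    ``steps_per_epoch`` defaults to ``ceil(n_pairs / batch_size)``:
    random patch extraction has no natural epoch boundary, so an epoch
    is defined as one batch per ``batch_size`` training pairs.
    """

    epochs: int = 80
    batch_size: int = 16
    patch_px: int = 64
    learning_rate: float = 1e-3
    loss: str = "L1"
    optimizer: str = "adam"
    seed: int = 0
    steps_per_epoch: int | None = None

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.patch_px) < 1:
            raise ValueError("epochs, batch_size and patch_px must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss.upper() != "L1":
            raise ValueError("only the L1 loss is supported")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class TrainHistory:
    """Per-epoch mean training loss and full-image validation loss."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss"])
            for e, (tr, va) in enumerate(zip(self.train_loss, self.val_loss)):
                w.writerow([e, tr, va])


def build_network(spec: NetworkSpec, seed: int = 0) -> ResidualCNN:
    """Instantiate the residual network with seeded fan-in-scaled
    random initialization."""
    return ResidualCNN(
        n_blocks=spec.n_blocks,
        channels=spec.channels,
        conv_kernel=spec.conv_kernel,
        seed=seed,
    )


def _validation_loss(model: ResidualCNN, pairs: Sequence[TrainingPair]) -> float:
    total = 0.0
    for p in pairs:
        pred = model.forward(p.input.pixels.astype(np.float32)[None])
        loss, _ = l1_loss(pred, p.target.pixels.astype(np.float32)[None])
        total += loss
    return total / len(pairs)


def train(
    model: ResidualCNN,
    train_pairs: Sequence[TrainingPair],
    val_pairs: Sequence[TrainingPair],
    spec: TrainSpec,
) -> tuple[ResidualCNN, TrainHistory]:
    """Train with Adam on L1 patch loss; returns the model loaded with
    the best-validation weights and the loss history.

    Deterministic given ``spec.seed`` (pure-numpy backend).  Raises
    ``RuntimeError`` if the loss diverges to a non-finite value.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be nonempty")
    steps = spec.steps_per_epoch or int(np.ceil(len(train_pairs) / spec.batch_size))
    opt = Adam(model.params, lr=spec.learning_rate)
    batches = extract_patches(
        train_pairs, patch_px=spec.patch_px, batch_size=spec.batch_size, seed=spec.seed
    )

    history = TrainHistory()
    best_val = np.inf
    best_params = model.copy_params()
    for epoch in range(spec.epochs):
        epoch_losses = []
        for _ in range(steps):
            xs, ys = next(batches)
            pred, cache = model.forward(xs, want_cache=True)
            loss, dpred = l1_loss(pred, ys)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
            grads = model.backward(dpred, cache)
            opt.step(model.params, grads)
            epoch_losses.append(loss)
        val = _validation_loss(model, val_pairs)
        if not np.isfinite(val):
            raise RuntimeError(f"validation loss non-finite at epoch {epoch}")
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_params = model.copy_params()
            history.best_epoch = epoch
    model.set_params(best_params)
    return model, history


def enhance(model: ResidualCNN, img: TrackingImage) -> TrackingImage:
    """Enhance a normalized tracking image with one full-image forward
    pass (no patching at inference).  The output lives on the same grid
    and is rescaled to unit peak so it remains a normalized image."""
    if not img.normalized:
        raise ValueError("enhance expects an envelope-normalized image in [0,1]")
    pred = model.forward(img.pixels.astype(np.float32)[None])[0]
    pred = np.clip(pred.astype(np.float64), 0.0, 1.0)
    peak = pred.max()
    if peak <= 0:
        raise RuntimeError("enhanced image is identically zero")
    pred /= peak
    pred[np.unravel_index(np.argmax(pred), pred.shape)] = 1.0
    return TrackingImage(pixels=pred, grid=img.grid, normalized=True)
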