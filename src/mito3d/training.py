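"""Patch-based training with Adam and the 16-transform augmentation regime.

Published setup reproduced at configurable scale: Adam with learning rate
1e-4, beta1 0.9, beta2 0.999, eps 1e-8, batch size 2, 30 epochs, plain binary
cross-entropy (no class weighting, no learning-rate schedule). Every base
patch may be expanded by all 16 rotation/flip transforms, and an epoch is a
full shuffled pass over the resulting sample set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .io_preprocess import AUGMENTATIONS, PatchSpec, extract_patches
from .network import (
    SegmentationModel,
    save_checkpoint,
    training_loss_tensors,
)
from .volume import LabelVolume, Volume

__all__ = ["TrainConfig", "TrainingSet", "make_training_set", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and loop settings (defaults follow the published setup)."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 2
    epochs: int = 30
    seed: int = 0
    checkpoint_every: int = 0  # epochs; 0 disables periodic checkpoints
    checkpoint_dir: str | None = None
    intensity_scale: float = 255.0  # raw gray levels mapped to [0, 1]

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


@dataclass
class TrainingSet:
    """Materialised (patch, label) samples with deterministic shuffling."""

    images: list[np.ndarray]
    labels: list[np.ndarray]
    seed: int
    n_base_patches: int
    augmented: bool

    def __len__(self) -> int:
        return len(self.images)

    def epoch_order(self, epoch: int) -> np.ndarray:
        rng = np.random.default_rng((self.seed, epoch))
        return rng.permutation(len(self.images))


def make_training_set(
    volume: Volume,
    labels: LabelVolume,
    patch_spec: PatchSpec,
    augment: bool = True,
    seed: int = 0,
) -> TrainingSet:
    """Tile the stack into patches, optionally expanded by all 16 transforms.

    With augmentation the sample count is exactly 16 x the base patch count.
    A training set without any foreground voxel is permitted but warned about
    (training would be degenerate).
    """
    imgs: list[np.ndarray] = []
    labs: list[np.ndarray] = []
    n_base = 0
    any_fg = False
    for img, lab in extract_patches(volume, labels, patch_spec):
        n_base += 1
        any_fg = any_fg or bool(lab.max() > 0)
        if augment:
            for t in AUGMENTATIONS:
                imgs.append(t.apply(img))
                labs.append(t.apply(lab))
        else:
            imgs.append(np.ascontiguousarray(img))
            labs.append(np.ascontiguousarray(lab))
    if not any_fg:
        import warnings

        warnings.warn("training set contains no foreground voxels", stacklevel=2)
    return TrainingSet(imgs, labs, seed=seed, n_base_patches=n_base, augmented=augment)


@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "mean_loss"])
            for i, loss in enumerate(self.epoch_loss):
                writer.writerow([i, f"{loss:.8f}"])


def train(
    model: SegmentationModel,
    dataset: TrainingSet,
    config: TrainConfig | None = None,
) -> tuple[SegmentationModel, TrainingHistory]:
    """Optimise the deep-supervision objective over shuffled epochs.

    Records the per-epoch mean loss; a NaN loss aborts immediately naming the
    offending batch. With a fixed seed and single-threaded numpy the loss
    trajectory is reproducible.
    """
    config = config or TrainConfig()
    opt = _nn.Adam(
        model.parameters(),
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        eps=config.eps,
    )
    history = TrainingHistory()
    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir is not None:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(config.epochs):
        order = dataset.epoch_order(epoch)
        losses: list[float] = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = np.stack([dataset.images[i] for i in idx]).astype(np.float64)
            batch = batch[:, None] / config.intensity_scale
            lab = np.stack([dataset.labels[i] for i in idx]).astype(np.intp)
            lab = (lab > 0).astype(np.intp)

            x = _nn.Tensor(batch)
            main, auxes = model.forward_tensors(x, train=True)
            loss = training_loss_tensors(model, main, auxes, lab)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting at sample {start}"
                )
            losses.append(value)
            if config.learning_rate != 0.0:
                opt.zero_grad()
                _nn.backward(loss)
                opt.step()
        history.epoch_loss.append(float(np.mean(losses)) if losses else float("nan"))
        if (
            ckpt_dir is not None
            and config.checkpoint_every > 0
            and (epoch + 1) % config.checkpoint_every == 0
        ):
            save_checkpoint(model, ckpt_dir / f"epoch_{epoch + 1:03d}.npz")

    return model, history
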