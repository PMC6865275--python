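"""End-to-end training of the attention model.

The recipe: MSRA initialization for convolutional filters, unit/zero
batch-norm parameters, Glorot initialization for fully connected
layers; random rotation and random isotropic scaling (factor 0.8-1.2)
as augmentation; Adam with initial learning rate 1e-3 decaying by 0.95
per epoch and reset to 1e-4 every 50 epochs (a cyclical schedule) over
200 epochs; mini-batch size 2.  Only the cross-entropy loss against the
tissue-level label is used — lesion boxes are never read on this path.

Variable grid sizes make tensor batching impossible, so a mini-batch is
assembled by per-image forward/backward passes with gradient
accumulation.  When augmentation is off, the activations of the frozen
backbone prefix are constant per tissue and are computed once and
cached, which makes desk-scale training take seconds rather than
minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import rescale as _sk_rescale

from .attention import AttentionModel
from .backbone import apply_freeze_policy
from .classes import class_index
from .nn import Adam, zero_grads
from .preprocessing import (
    ChannelStats,
    DEFAULT_CELL_PX,
    DEFAULT_OUT_PX,
    compute_normalization_stats,
    load_image,
    normalize_cells,
    tile_grid,
)

__all__ = [
    "TrainConfig",
    "TrainLog",
    "initialize_weights",
    "lr_schedule",
    "sample_augmentation",
    "augment",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the training recipe)."""

    lr0: float = 1e-3
    decay: float = 0.95
    cycle_reset_lr: float = 1e-4
    cycle_length: int = 50
    total_epochs: int = 200
    batch_size: int = 2
    scale_range: tuple[float, float] = (0.8, 1.2)
    rotation: bool = True
    continuous_rotation: bool = False  # default: right angles, no interpolation
    augment: bool = True
    decay_within_cycle: bool = True  # decay continues inside each 1e-4 cycle
    freeze_all_but_last: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.decay < 1:
            raise ValueError("decay must be in (0, 1)")
        if self.cycle_length < 1 or self.total_epochs % self.cycle_length != 0:
            raise ValueError("cycle_length must divide total_epochs")


@dataclass
class TrainLog:
    """One record per completed epoch plus the selected checkpoint."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")
    checkpoint_path: str | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def initialize_weights(model: AttentionModel, seed: int = 0) -> AttentionModel:
    """Re-initialize all parameters in place.

    Convolution weights are drawn zero-mean normal with variance
    2/fan_in (MSRA); batch-norm scale/shift are set to exactly 1/0;
    fully connected weights are zero-mean normal with variance
    2/(fan_in + fan_out) (Glorot); biases are zeroed.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    for p in model.params():
        if p.kind == "conv_weight":
            fan_in = int(np.prod(p.value.shape[1:]))
            p.value[...] = rng.normal(0.0, np.sqrt(2.0 / fan_in), p.value.shape)
        elif p.kind == "fc_weight":
            fan_out, fan_in = p.value.shape
            p.value[...] = rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), p.value.shape)
        elif p.kind == "bn_weight":
            p.value[...] = 1.0
        else:  # bn_bias and ordinary biases
            p.value[...] = 0.0
    return model


def lr_schedule(epoch: int, config: TrainConfig = TrainConfig()) -> float:
    """Learning rate for a 0-based epoch.

    ``lr0 * decay**epoch`` inside the first cycle; from epoch 50 on the
    rate restarts at ``cycle_reset_lr`` at each cycle boundary and (by
    default) decays within the cycle the same way.
    """
    if not 0 <= epoch < config.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.total_epochs})")
    if epoch < config.cycle_length:
        return config.lr0 * config.decay**epoch
    within = epoch % config.cycle_length
    if not config.decay_within_cycle:
        within = 0
    return config.cycle_reset_lr * config.decay**within


def sample_augmentation(rng: np.random.Generator, config: TrainConfig):
    """Draw one augmentation: (rotation, scale factor).

    Rotation is a multiple of 90 degrees by default (continuous mode
    draws a uniform angle); the scale factor is uniform in
    ``config.scale_range``.
    """
    if not config.rotation:
        rot = 0.0
    elif config.continuous_rotation:
        rot = float(rng.uniform(0.0, 360.0))
    else:
        rot = 90.0 * int(rng.integers(4))
    scale = float(rng.uniform(*config.scale_range))
    return rot, scale


def augment(image: np.ndarray, rng: np.random.Generator,
            config: TrainConfig = TrainConfig()) -> np.ndarray:
    """One random rotation + one random isotropic scale (training only).

    With ``config.augment`` false this is the identity, matching the
    evaluation path.
    """
    if not config.augment:
        return image
    rot, scale = sample_augmentation(rng, config)
    img = image
    if rot:
        if config.continuous_rotation:
            img = ndimage.rotate(img.astype(np.float32), rot, reshape=True,
                                 order=1, cval=250.0)
        else:
            img = np.rot90(img, k=int(round(rot / 90.0)) % 4, axes=(0, 1))
    if scale != 1.0:
        img = _sk_rescale(img.astype(np.float32), scale, channel_axis=2, order=1,
                          preserve_range=True, anti_aliasing=False)
    return np.clip(img, 0, 255).astype(image.dtype) if image.dtype == np.uint8 else img


def _as_image(sample) -> np.ndarray:
    return load_image(sample) if isinstance(sample, (str, Path)) else np.asarray(sample)


def _prepare(model, image, stats, cell_px, out_px):
    grid, cells = tile_grid(image, cell_px=cell_px, out_px=out_px)
    return grid, normalize_cells(cells, stats)


def _evaluate_cached(model, cached):
    correct = 0
    for grid, prefix, label in cached:
        probs, _, _ = model.forward_from_prefix(prefix, grid, train=False)
        if int(np.argmax(probs)) == label:
            correct += 1
    return correct / max(len(cached), 1)


def train(train_samples, model: AttentionModel, config: TrainConfig = TrainConfig(),
          val_samples=(), stats: ChannelStats | None = None,
          cell_px: int = DEFAULT_CELL_PX, out_px: int = DEFAULT_OUT_PX,
          checkpoint_path: str | Path | None = None,
          progress: bool = False) -> tuple[AttentionModel, TrainLog]:
    """Optimize the model on (image, label) pairs; returns the best model.

    ``train_samples`` / ``val_samples`` are sequences of ``(image,
    label)`` where ``image`` is an (H, W, 3) array or a path and
    ``label`` a class name.  Lesion boxes are never consumed here: the
    model trains from tissue-level labels alone.  Channel statistics
    are computed over the training tissues when not supplied.  The
    checkpoint with the best validation accuracy is selected (training
    loss breaks the tie when no validation set is given).
    """
    train_samples = list(train_samples)
    if not train_samples:
        raise ValueError("empty training manifest")
    for _, label in train_samples:
        class_index(label)

    if stats is None:
        stats = compute_normalization_stats(_as_image(img) for img, _ in train_samples)

    apply_freeze_policy(model.backbone, config.freeze_all_but_last)

    rng = np.random.default_rng(config.seed)
    model.dropout.rng = np.random.default_rng(rng.integers(2**31 - 1))
    aug_rng = np.random.default_rng(rng.integers(2**31 - 1))

    # With augmentation off, tissue tensors never change: cache the frozen
    # backbone prefix once per tissue and train only the suffix + head.
    cache_frozen = not config.augment
    cached_train = cached_val = None
    if cache_frozen:
        cached_train = []
        for img, label in train_samples:
            grid, cells = _prepare(model, _as_image(img), stats, cell_px, out_px)
            cached_train.append((grid, model.backbone.frozen_prefix(cells),
                                 class_index(label)))
        cached_val = []
        for img, label in val_samples:
            grid, cells = _prepare(model, _as_image(img), stats, cell_px, out_px)
            cached_val.append((grid, model.backbone.frozen_prefix(cells),
                               class_index(label)))

    params = model.params()
    opt = Adam(params, lr=config.lr0)
    log = TrainLog()
    best_state, best_score = None, -np.inf

    for epoch in range(config.total_epochs):
        opt.lr = lr_schedule(epoch, config)
        order = rng.permutation(len(train_samples))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            zero_grads(params)
            batch_loss = 0.0
            for idx in batch:
                if cache_frozen:
                    grid, prefix, label = cached_train[idx]
                    _, cls_logits, _ = model.forward_from_prefix(prefix, grid, train=True)
                    loss = model.backward(cls_logits, label)
                else:
                    img, label_name = train_samples[idx]
                    img = augment(_as_image(img), aug_rng, config)
                    grid, cells = _prepare(model, img, stats, cell_px, out_px)
                    loss = model.loss_and_grad(cells, grid, class_index(label_name))
                batch_loss += loss
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}; aborting")
            # mini-batch mean loss: scale accumulated gradients accordingly
            inv = 1.0 / len(batch)
            for p in params:
                p.grad *= inv
            opt.step()
            epoch_loss += batch_loss * inv
            n_batches += 1

        mean_loss = epoch_loss / n_batches
        if cache_frozen:
            val_acc = _evaluate_cached(model, cached_val) if cached_val else float("nan")
        elif val_samples:
            correct = 0
            for img, label_name in val_samples:
                grid, cells = _prepare(model, _as_image(img), stats, cell_px, out_px)
                probs, _ = model.forward(cells, grid, train=False)
                correct += int(np.argmax(probs)) == class_index(label_name)
            val_acc = correct / len(val_samples)
        else:
            val_acc = float("nan")

        log.records.append(dict(epoch=epoch, loss=mean_loss, lr=opt.lr,
                                val_accuracy=val_acc))
        if progress:  # pragma: no cover
            print(f"epoch {epoch:3d}  loss {mean_loss:.4f}  lr {opt.lr:.2e}  "
                  f"val_acc {val_acc:.3f}")

        score = val_acc if np.isfinite(val_acc) else -mean_loss
        if score > best_score:
            best_score, log.best_epoch = score, epoch
            log.best_val_accuracy = val_acc
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    if checkpoint_path is not None:
        model.save(checkpoint_path, extra=dict(best_epoch=log.best_epoch))
        log.checkpoint_path = str(checkpoint_path)
    return model, log
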