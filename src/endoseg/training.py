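"""Training contract: loss, Nadam schedule, stratified batches, folds, augmentation.

The learning rate decays geometrically, ``lr_i = lr0 * decay**i`` with decay
0.99 over 200 epochs for the edge task and 0.97 over 100 epochs for the
body/blob/roi tasks.  Batches hold 15 images of which six are drawn from the
guttae subgroups (two per complexity bin: low, medium, high); cross-validation
folds are formed at eye level so that no eye contributes to two folds.
Augmentation applies identical left-right/up-down flips and an elastic
deformation to image and target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from endoseg.nn import ModelGraph, Nadam, Network, softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "lr_schedule",
    "sample_batch",
    "make_folds",
    "augment",
    "train_model",
    "TASK_SCHEDULES",
]

log = logging.getLogger(__name__)

#: per-task (epochs, lr decay)
TASK_SCHEDULES = {"edge": (200, 0.99), "body": (100, 0.97), "blob": (100, 0.97), "roi": (100, 0.97)}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""

    task: str = "edge"
    batch_size: int = 15
    guttae_quota: int = 6          # two per complexity bin
    lr0: float = 0.001
    epochs: int | None = None      # default per task
    lr_decay: float | None = None  # default per task
    augment: bool = True
    elastic_grid: int = 8          # control points per axis
    elastic_sd: float = 10.0       # displacement SD in px

    def __post_init__(self) -> None:
        if self.task not in TASK_SCHEDULES:
            raise ValueError(f"unknown task: {self.task!r}")
        ep, dec = TASK_SCHEDULES[self.task]
        if self.epochs is None:
            object.__setattr__(self, "epochs", ep)
        if self.lr_decay is None:
            object.__setattr__(self, "lr_decay", dec)
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr decay must be in (0, 1]")
        if self.guttae_quota > self.batch_size:
            raise ValueError("guttae quota cannot exceed the batch size")


def lr_schedule(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate at a given epoch: lr0 * decay**epoch."""
    if epoch < 0:
        raise ValueError("epoch index must be >= 0")
    return cfg.lr0 * cfg.lr_decay**epoch


@dataclass(frozen=True)
class FoldAssignment:
    """Eye-level fold assignment: every image of an eye shares its fold."""

    eye_to_fold: dict
    k: int

    def fold_of(self, eye_id) -> int:
        return self.eye_to_fold[eye_id]

    def eyes_in_fold(self, fold: int) -> list:
        return [e for e, f in self.eye_to_fold.items() if f == fold]


def make_folds(eye_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Deal shuffled eyes round-robin into k folds (sizes differ by <= 1)."""
    eyes = list(dict.fromkeys(eye_ids))  # unique, order-preserving
    if len(eyes) < k:
        raise ValueError(f"need at least {k} eyes for {k} folds, got {len(eyes)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eyes))
    return FoldAssignment({eyes[j]: i % k for i, j in enumerate(order)}, k)


def sample_batch(index: pd.DataFrame, cfg: TrainConfig, seed: int = 0) -> list:
    """Draw one stratified training batch of image ids.

    ``index`` must have columns ``id`` and ``guttae_bin`` (one of none, low,
    medium, high).  Exactly two ids come from each of the low/medium/high
    guttae bins; the remaining slots are drawn uniformly without replacement
    from all images not already chosen.  A bin with fewer than two images
    falls back to sampling with replacement (logged).
    """
    rng = np.random.default_rng(seed)
    per_bin = cfg.guttae_quota // 3
    chosen: list = []
    for b in ("low", "medium", "high"):
        pool = index.loc[index["guttae_bin"] == b, "id"].to_numpy()
        if len(pool) == 0:
            raise ValueError(f"no images in guttae bin {b!r}")
        if len(pool) < per_bin:
            log.warning("guttae bin %r has %d image(s) < quota %d: sampling with replacement",
                        b, len(pool), per_bin)
            chosen.extend(rng.choice(pool, size=per_bin, replace=True).tolist())
        else:
            chosen.extend(rng.choice(pool, size=per_bin, replace=False).tolist())
    rest = index.loc[~index["id"].isin(chosen), "id"].to_numpy()
    n_rest = cfg.batch_size - len(chosen)
    if len(rest) < n_rest:
        log.warning("pool of %d remaining images < %d batch slots: sampling with replacement",
                    len(rest), n_rest)
        chosen.extend(rng.choice(rest, size=n_rest, replace=True).tolist())
    else:
        chosen.extend(rng.choice(rest, size=n_rest, replace=False).tolist())
    return chosen


def _elastic_field(shape, grid: int, sd: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Coarse random displacement grid, bilinearly upsampled to image size."""
    h, w = shape
    coarse = rng.normal(0.0, sd, size=(2, grid, grid))
    zoom = (h / grid, w / grid)
    dy = ndimage.zoom(coarse[0], zoom, order=1)
    dx = ndimage.zoom(coarse[1], zoom, order=1)
    return dy[:h, :w], dx[:h, :w]


def augment(image: np.ndarray, target: np.ndarray, seed: int = 0,
            elastic_grid: int = 8, elastic_sd: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Apply one identical random geometric transform to image and target.

    Left-right and up-down flips each occur with probability 1/2; an elastic
    deformation (coarse Gaussian displacement grid, bilinearly upsampled,
    applied by linear interpolation) follows.  Deterministic given the seed.
    """
    image = np.asarray(image, dtype=float)
    target = np.asarray(target, dtype=float)
    if image.shape != target.shape:
        raise ValueError(f"image and target shape mismatch: {image.shape} vs {target.shape}")
    rng = np.random.default_rng(seed)
    if rng.random() < 0.5:
        image, target = image[:, ::-1], target[:, ::-1]
    if rng.random() < 0.5:
        image, target = image[::-1, :], target[::-1, :]
    if elastic_sd > 0:
        dy, dx = _elastic_field(image.shape, elastic_grid, elastic_sd, rng)
        yy, xx = np.meshgrid(np.arange(image.shape[0], dtype=float),
                             np.arange(image.shape[1], dtype=float), indexing="ij")
        coords = np.stack([yy + dy, xx + dx])
        image = ndimage.map_coordinates(image, coords, order=1, mode="reflect")
        target = ndimage.map_coordinates(target, coords, order=1, mode="reflect")
    return np.clip(image, 0.0, 1.0), np.clip(target, 0.0, 1.0)


def _dice(pred: np.ndarray, truth: np.ndarray) -> float:
    a = pred >= 0.5
    b = truth >= 0.5
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * (a & b).sum() / denom


def train_model(graph: ModelGraph, images: np.ndarray, targets: np.ndarray,
                cfg: TrainConfig, seed: int = 0, batch_size: int | None = None,
                target_dice: float | None = None) -> tuple[Network, pd.DataFrame]:
    """Train a network on (images, targets) with the configured schedule.

    ``images`` is (N, H, W) in [0, 1]; ``targets`` is (N, H, W) of per-pixel
    foreground probabilities, internally encoded as the two softmax maps
    (p, 1-p).  There is no early stopping on the loss; ``target_dice``
    optionally ends the run once the training DICE of the thresholded
    foreground map reaches the given value (used by convergence smoke
    checks).  Returns the trained network and a per-epoch log with columns
    epoch, lr, loss, dice.  A NaN loss aborts with a diagnostic.
    """
    images = np.asarray(images, np.float32)
    targets = np.asarray(targets, np.float32)
    if images.shape != targets.shape:
        raise ValueError("images and targets must share shape (N, H, W)")
    n = images.shape[0]
    bs = min(batch_size or cfg.batch_size, n)
    net = Network(graph, seed=seed)
    opt = Nadam()
    rng = np.random.default_rng(seed)
    rows = []
    for epoch in range(cfg.epochs):
        lr = lr_schedule(cfg, epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        steps = 0
        inter = 0.0
        denom = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb = images[idx]
            tb = targets[idx]
            if cfg.augment:
                xb = xb.copy()
                tb = tb.copy()
                for j in range(len(idx)):
                    xb[j], tb[j] = augment(xb[j], tb[j], seed=int(rng.integers(2**31)),
                                           elastic_grid=cfg.elastic_grid,
                                           elastic_sd=cfg.elastic_sd)
            t2 = np.stack([tb, 1.0 - tb], axis=1)
            acts = net.forward(xb[:, None], training=True, dropout_rng=rng)
            loss, dlog = softmax_cross_entropy(acts["logits"], t2)
            if math.isnan(loss):
                raise FloatingPointError(
                    f"NaN loss at epoch {epoch}, lr {lr:.2e}: aborting (inspect inputs/lr)")
            pred_fg = acts["output"][:, 0]
            inter += float(((pred_fg >= 0.5) & (tb >= 0.5)).sum())
            denom += float((pred_fg >= 0.5).sum() + (tb >= 0.5).sum())
            grads = net.backward(dlog)
            opt.step(net.params, grads, lr)
            epoch_loss += loss
            steps += 1
        # training DICE of the thresholded foreground maps over the epoch's
        # own forward passes (batch statistics, as during optimization)
        dice = 1.0 if denom == 0 else 2.0 * inter / denom
        rows.append({"epoch": epoch, "lr": lr, "loss": epoch_loss / steps, "dice": dice})
        log.info("epoch %d lr %.3e loss %.4f dice %.3f", epoch, lr, epoch_loss / steps, dice)
        if target_dice is not None and dice >= target_dice:
            break
    return net, pd.DataFrame(rows)
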