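"""Training protocol: plan-level splits, five-fold CV, augmentation,
optimization with early stopping, and ensemble-mean inference.

Splitting is *plan-level*: all map stacks of all beams of one plan land on
the same side of the train/test divide (and in the same CV fold), so the
classifier is never evaluated on a plan it saw during training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform, rotate

from qaerr.nn.autograd import Tensor, cross_entropy
from qaerr.nn.optim import AdamW, CosineAnnealingLR
from qaerr.network import HybridNet, NetConfig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AugmentConfig:
    """Online augmentation switches; geometric transforms are applied
    identically to all channels, intensity jitter is a single global
    ``a*x + b`` map per sample (contrast/brightness only)."""

    erasure: bool = True
    affine: bool = True
    rotation: bool = True
    flip: bool = True
    jitter: bool = True
    max_rotation_deg: float = 15.0
    max_translate_frac: float = 0.05
    scale_range: tuple[float, float] = (0.9, 1.1)
    erasure_frac: tuple[float, float] = (0.05, 0.2)
    contrast_range: tuple[float, float] = (0.9, 1.1)
    brightness_range: tuple[float, float] = (-0.05, 0.05)

    @classmethod
    def none(cls) -> "AugmentConfig":
        return cls(erasure=False, affine=False, rotation=False, flip=False,
                   jitter=False)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: AdamW + cosine annealing + early stopping."""

    lr: float = 1e-5
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 50
    folds: int = 5
    test_fraction: float = 0.2
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


def desk_train_config(seed: int = 0) -> TrainConfig:
    """CPU-scale protocol: higher learning rate, short schedule, batch 16."""
    return TrainConfig(lr=1e-3, batch_size=16, max_epochs=20, patience=5,
                       seed=seed)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def split_plan_level(manifest: pd.DataFrame, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """80:20-style split over distinct plan_ids; no plan straddles sides."""
    plans = sorted(manifest["plan_id"].unique())
    if len(plans) < 2:
        raise ValueError("need >= 2 distinct plan_ids to split")
    rng = np.random.default_rng(seed)
    plans = list(rng.permutation(plans))
    n_test = int(round(test_fraction * len(plans)))
    n_test = min(max(n_test, 1), len(plans) - 1)
    test_plans = set(plans[:n_test])
    is_test = manifest["plan_id"].isin(test_plans)
    return manifest[~is_test].copy(), manifest[is_test].copy()


def kfold_by_plan(train_rows: pd.DataFrame, folds: int = 5,
                  seed: int = 0) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Plan-disjoint CV folds; every plan validates exactly once."""
    plans = sorted(train_rows["plan_id"].unique())
    if len(plans) < folds:
        raise ValueError(f"need >= {folds} plans for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    plans = list(rng.permutation(plans))
    parts = np.array_split(plans, folds)
    out = []
    for part in parts:
        val_mask = train_rows["plan_id"].isin(set(part))
        out.append((train_rows[~val_mask].copy(), train_rows[val_mask].copy()))
    return out


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment_channels(channels: np.ndarray, config: AugmentConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Augment one (H, W, C) stack; label-preserving, clipped to [-1, 1]."""
    x = channels.astype(np.float32).copy()
    size = x.shape[0]

    if config.flip:
        if rng.random() < 0.5:
            x = x[:, ::-1]
        if rng.random() < 0.5:
            x = x[::-1, :]

    if config.rotation:
        angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        x = rotate(x, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")

    if config.affine:
        s = rng.uniform(*config.scale_range)
        t = rng.uniform(-config.max_translate_frac, config.max_translate_frac,
                        size=2) * size
        center = (size - 1) / 2.0
        matrix = np.eye(2) / s
        offset = center - matrix @ (center + t)
        for c in range(x.shape[2]):
            x[:, :, c] = affine_transform(x[:, :, c], matrix, offset=offset,
                                          order=1, mode="nearest")

    if config.jitter:
        a = rng.uniform(*config.contrast_range)
        b = rng.uniform(*config.brightness_range)
        x = a * x + b

    if config.erasure:
        fh = rng.uniform(*config.erasure_frac)
        fw = rng.uniform(*config.erasure_frac)
        eh, ew = max(1, int(fh * size)), max(1, int(fw * size))
        r0 = rng.integers(0, size - eh + 1)
        c0 = rng.integers(0, size - ew + 1)
        x[r0:r0 + eh, c0:c0 + ew, :] = 0.0

    return np.clip(x, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Fold training
# ---------------------------------------------------------------------------

@dataclass
class FoldHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def _eval_loss(model: HybridNet, images: np.ndarray, labels: np.ndarray,
               batch_size: int) -> float:
    model.eval()
    losses, weights = [], []
    for i in range(0, images.shape[0], batch_size):
        xb = images[i:i + batch_size]
        yb = labels[i:i + batch_size]
        loss = cross_entropy(model(Tensor(xb)), yb)
        losses.append(float(loss.data))
        weights.append(len(yb))
    model.train()
    return float(np.average(losses, weights=weights))


def train_fold(train_images: np.ndarray, train_labels: np.ndarray,
               val_images: np.ndarray, val_labels: np.ndarray,
               net_config: NetConfig, train_config: TrainConfig,
               verbose: bool = False) -> tuple[HybridNet, FoldHistory]:
    """Train one CV fold; returns the best-validation-loss model.

    Images are NCHW float32.  Stops at ``max_epochs`` or once the
    validation loss has not improved for ``patience`` epochs.  Raises
    RuntimeError on divergence (non-finite loss).
    """
    model = HybridNet(net_config)
    opt = AdamW(model.parameters(), lr=train_config.lr,
                weight_decay=train_config.weight_decay)
    sched = CosineAnnealingLR(opt, t_max=train_config.max_epochs)
    history = FoldHistory()
    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0
    n = train_images.shape[0]
    bs = train_config.batch_size

    for epoch in range(train_config.max_epochs):
        rng = np.random.default_rng(train_config.seed * 10_000 + epoch)
        order = rng.permutation(n)
        epoch_losses = []
        history.lr.append(opt.lr)
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            xb = train_images[idx]
            if any([train_config.augment.erasure, train_config.augment.affine,
                    train_config.augment.rotation, train_config.augment.flip,
                    train_config.augment.jitter]):
                xb = np.stack([
                    augment_channels(im.transpose(1, 2, 0),
                                     train_config.augment, rng).transpose(2, 0, 1)
                    for im in xb
                ])
            loss = cross_entropy(model(Tensor(xb)), train_labels[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}, "
                    f"lr={opt.lr:.2e}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        sched.step()

        train_loss = float(np.mean(epoch_losses))
        val_loss = _eval_loss(model, val_images, val_labels, bs)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        if verbose:
            log.info("epoch %d: train %.4f val %.4f lr %.2e",
                     epoch, train_loss, val_loss, history.lr[-1])

        if val_loss < best_val - 1e-8:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > train_config.patience:
                history.stopped_epoch = epoch
                break

    model.load_state_dict(best_state)
    model.eval()
    return model, history


def ensemble_predict(models: list[HybridNet], images: np.ndarray,
                     batch_size: int = 32) -> np.ndarray:
    """Arithmetic mean of per-model class probabilities."""
    if not models:
        raise ValueError("need at least one model")
    n_cls = {m.config.n_classes for m in models}
    if len(n_cls) != 1:
        raise ValueError("inconsistent class counts across models")
    probs = [m.predict_proba(images, batch_size) for m in models]
    return np.mean(probs, axis=0)
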