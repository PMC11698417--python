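"""End-to-end training of the dual-branch model at configurable scale.

Recipe: Adam with cosine-annealed learning rate (5e-4 down to 5e-6 over
the run), weight decay 1e-5, batch size 8, random square crops plus
horizontal/vertical flips and brightness/contrast jitter (each with
probability 0.5), and five-fold cross-validation with selection by
validation mean Dice.

TSDF targets are computed once per image from the full-size mask and
cached; augmentation crops the cached stack instead of recomputing, so
the normalization (defined over the full image) is unchanged by cropping.
Validation images are evaluated uncropped at full size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nn import Adam
from .network import DualBranchNet, ModelSpec, build_model
from .losses import LossConfig, total_loss
from .evaluation import dice_iou
from .synthetic import LabeledImage
from . import tsdf as _tsdf

__all__ = ["TrainConfig", "Sample", "prepare_samples", "augment",
           "cosine_lr", "train", "cross_validate", "mean_validation_dice"]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    lr_start: float = 5e-4
    lr_end: float = 5e-6
    weight_decay: float = 1e-5
    crop: int = 256
    flip_prob: float = 0.5
    jitter_prob: float = 0.5
    jitter: float = 0.2          # max relative brightness/contrast change
    folds: int = 5
    seed: int = 0
    early_stop_dice: float | None = None   # stop once val mDice reaches this

    def __post_init__(self):
        if self.lr_end > self.lr_start:
            raise ValueError("lr_end must be <= lr_start")
        for p in (self.flip_prob, self.jitter_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class Sample:
    """One training example with its cached full-image TSDF stack."""

    image: np.ndarray        # (H, W) float32 in [0,1]
    mask: np.ndarray         # (H, W) integer labels
    tsdf: np.ndarray         # (K, H, W) normalized TSDF targets


def prepare_samples(labeled, K: int, tau: float = _tsdf.DEFAULT_TAU):
    """Attach cached TSDF stacks to a list of :class:`LabeledImage`."""
    out = []
    for li in labeled:
        stack = _tsdf.tsdf_stack(li.mask, K, tau).values.astype(np.float32)
        out.append(Sample(image=li.image.astype(np.float32),
                          mask=li.mask.astype(np.int64), tsdf=stack))
    return out


def augment(sample, config: TrainConfig, rng: np.random.Generator,
            tsdf_stack: np.ndarray | None = None):
    """Random crop + joint flips + intensity jitter.

    Crop and flips are applied jointly to image, mask (and the TSDF stack
    when given); brightness/contrast jitter touches the image only.
    Returns a :class:`LabeledImage`, or ``(LabeledImage, tsdf)`` when a
    stack is passed.
    """
    img, msk = sample.image, sample.mask
    h, w = img.shape
    c = min(config.crop, h, w)
    if config.crop > min(h, w):
        raise ValueError(f"crop {config.crop} exceeds image size {h}x{w}")
    r0 = int(rng.integers(0, h - c + 1))
    c0 = int(rng.integers(0, w - c + 1))
    img = img[r0:r0 + c, c0:c0 + c]
    msk = msk[r0:r0 + c, c0:c0 + c]
    std = tsdf_stack[:, r0:r0 + c, c0:c0 + c] if tsdf_stack is not None else None
    if rng.random() < config.flip_prob:        # horizontal
        img, msk = img[:, ::-1], msk[:, ::-1]
        std = std[:, :, ::-1] if std is not None else None
    if rng.random() < config.flip_prob:        # vertical
        img, msk = img[::-1, :], msk[::-1, :]
        std = std[:, ::-1, :] if std is not None else None
    jittered = False
    if rng.random() < config.jitter_prob:      # brightness
        img = img + rng.uniform(-config.jitter, config.jitter)
        jittered = True
    if rng.random() < config.jitter_prob:      # contrast
        m = img.mean()
        img = m + (1.0 + rng.uniform(-config.jitter, config.jitter)) * (img - m)
        jittered = True
    if jittered:
        img = np.clip(img, 0.0, 1.0)
    li = LabeledImage(image=np.ascontiguousarray(img),
                      mask=np.ascontiguousarray(msk))
    if tsdf_stack is None:
        return li
    return li, np.ascontiguousarray(std)


def cosine_lr(step: int, total_steps: int, lr_start: float,
              lr_end: float) -> float:
    """Cosine annealing from lr_start (step 0) to lr_end (final step)."""
    if total_steps < 1:
        raise ValueError("total_steps must be >= 1")
    t = min(max(step, 0), total_steps)
    return lr_end + 0.5 * (lr_start - lr_end) * (1 + np.cos(np.pi * t / total_steps))


def mean_validation_dice(model: DualBranchNet, samples) -> float:
    """Mean foreground Dice over full-size validation images."""
    model.eval()
    K = model.spec.n_classes
    vals = []
    for s in samples:
        probs, _ = model(s.image[None])
        pred = probs.data[0].argmax(axis=0)
        vals.append(dice_iou(pred, s.mask, K).mean_dice)
    return float(np.mean(vals))


def train(model: DualBranchNet, train_samples, val_samples,
          config: TrainConfig, loss_config: LossConfig | None = None):
    """Minimize the composite loss; returns (model, per-epoch log).

    The log has one row per epoch with the mean loss components and the
    validation mean Dice.  Deterministic given config.seed.
    """
    if not train_samples:
        raise ValueError("empty training set")
    if loss_config is None:
        loss_config = LossConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_shuffle, rng_aug = [np.random.default_rng(c) for c in ss.spawn(2)]
    opt = Adam(model.parameters(), lr=config.lr_start,
               weight_decay=config.weight_decay)
    n = len(train_samples)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = max(1, config.epochs * steps_per_epoch - 1)
    step = 0
    log_rows = []
    for epoch in range(config.epochs):
        model.train()
        order = rng_shuffle.permutation(n)
        comp_sums = {"ce": 0.0, "dice": 0.0, "bou": 0.0, "total": 0.0}
        for b0 in range(0, n, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            imgs, msks, stds = [], [], []
            for i in idx:
                s = train_samples[i]
                li, std = augment(s, config, rng_aug, tsdf_stack=s.tsdf)
                imgs.append(li.image)
                msks.append(li.mask)
                stds.append(std)
            x = np.stack(imgs, axis=0)
            masks = np.stack(msks, axis=0)
            targets = np.stack(stds, axis=0)
            opt.set_lr(cosine_lr(step, total_steps, config.lr_start,
                                 config.lr_end))
            seg, tsd = model(x)
            loss, parts = total_loss(seg, tsd, masks, loss_config,
                                     target_tsdf=targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1
            for key in comp_sums:
                comp_sums[key] += parts[key]
        row = {"epoch": epoch + 1,
               **{k: v / steps_per_epoch for k, v in comp_sums.items()}}
        row["val_mdice"] = (mean_validation_dice(model, val_samples)
                            if val_samples else np.nan)
        log_rows.append(row)
        if (config.early_stop_dice is not None
                and row["val_mdice"] >= config.early_stop_dice):
            break
    return model, pd.DataFrame(log_rows)


def cross_validate(samples, config: TrainConfig, model_spec: ModelSpec,
                   loss_config: LossConfig | None = None):
    """K-fold cross-validation; returns (best model, per-fold summary).

    Folds are a deterministic permutation of the dataset given
    config.seed; the model with the highest final validation mean Dice
    is selected.
    """
    n = len(samples)
    if n < config.folds:
        raise ValueError(f"need at least {config.folds} samples, got {n}")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    bounds = np.linspace(0, n, config.folds + 1).astype(int)
    models, rows = [], []
    for f in range(config.folds):
        val_idx = perm[bounds[f]:bounds[f + 1]]
        trn_idx = np.concatenate([perm[:bounds[f]], perm[bounds[f + 1]:]])
        model = build_model(model_spec, seed=config.seed + f)
        fold_cfg = replace(config, seed=config.seed * 1000 + f)
        model, log = train(model, [samples[i] for i in trn_idx],
                           [samples[i] for i in val_idx], fold_cfg,
                           loss_config)
        vd = float(log["val_mdice"].iloc[-1])
        models.append(model)
        rows.append({"fold": f, "val_mdice": vd,
                     "n_train": len(trn_idx), "n_val": len(val_idx)})
    summary = pd.DataFrame(rows)
    best = models[int(summary["val_mdice"].idxmax())]
    return best, summary
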