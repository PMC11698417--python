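"""Composite training objective: L = Lce + Ldice + lambda * Lbou.

The segmentation branch is trained with pixel-weighted cross-entropy plus
Dice loss; the boundary branch with pixel-weighted mean squared error
against the normalized TSDF targets.  The weight map w(x) is the
information-entropy weight of the top-two per-class TSDF values and is
treated as a constant during backpropagation (no gradient flows through
its computation); by default it is derived from the network's *predicted*
TSDF, so poorly learned regions are up-weighted on the fly, but it can be
switched to the ground-truth stack or turned off.

Shape convention: probability/TSDF tensors are (N, K, H, W); weight maps
are (N, H, W).  Cross-entropy and boundary MSE average over pixels and
images; the Dice term sums over classes and images as is conventional for
it, so its ceiling is N*K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, clip, log
from . import tsdf as _tsdf

__all__ = ["LossConfig", "weighted_cross_entropy", "dice_loss",
           "boundary_mse", "total_loss", "onehot_encode"]


@dataclass
class LossConfig:
    """Knobs of the composite objective.

    lambda_bou          : weight of the boundary regression term (>= 0)
    use_adaptive_weight : apply the entropy weight map to CE and MSE
    weight_source       : 'predicted' or 'ground_truth' TSDF stack
    epsilon             : stabilizer inside logs and Dice denominators
    tau                 : truncation radius for TSDF targets (pixels)
    """

    lambda_bou: float = 1.0
    use_adaptive_weight: bool = True
    weight_source: str = "predicted"
    epsilon: float = 1e-7
    tau: float = _tsdf.DEFAULT_TAU

    def __post_init__(self):
        if self.lambda_bou < 0:
            raise ValueError("lambda_bou must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.weight_source not in ("predicted", "ground_truth"):
            raise ValueError("weight_source must be 'predicted' or "
                             "'ground_truth'")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _check_nkhw(name, t):
    if t.ndim != 4:
        raise ValueError(f"{name} must be (N,K,H,W), got shape {t.shape}")


def onehot_encode(mask: np.ndarray, K: int) -> np.ndarray:
    """(N,H,W) or (H,W) integer mask -> float (N,K,H,W) one-hot."""
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    n, h, w = mask.shape
    out = np.zeros((n, K, h, w), dtype=np.float64)
    np.put_along_axis(out, mask[:, None].astype(np.int64), 1.0, axis=1)
    return out


def weighted_cross_entropy(probs, onehot, weights) -> Tensor:
    """- (1/N) sum_i sum_k (1/HW) sum_j w y log(p + eps).

    Equals the plain per-pixel-averaged cross entropy when w == 1.
    """
    probs = _as_tensor(probs)
    _check_nkhw("probs", probs)
    onehot = np.asarray(onehot)
    weights = np.asarray(weights)
    if onehot.shape != probs.shape or weights.shape != (
            probs.shape[0], probs.shape[2], probs.shape[3]):
        raise ValueError("shape mismatch between probs, onehot and weights")
    n, _, h, w = probs.shape
    eps = 1e-7
    wy = Tensor((weights[:, None] * onehot).astype(probs.data.dtype))
    per = wy * log(clip(probs, eps, 1.0))
    return -per.sum() * (1.0 / (n * h * w))


def dice_loss(probs, onehot, epsilon: float = 1e-7) -> Tensor:
    """sum_k sum_i (1 - 2 sum_j y p / (sum_j y + sum_j p + eps))."""
    probs = _as_tensor(probs)
    _check_nkhw("probs", probs)
    onehot = np.asarray(onehot)
    if onehot.shape != probs.shape:
        raise ValueError("shape mismatch between probs and onehot")
    n, k, _, _ = probs.shape
    y = Tensor(onehot.astype(probs.data.dtype))
    inter = (probs * y).sum(axis=(2, 3))          # (N, K)
    denom = (probs.sum(axis=(2, 3))
             + (onehot.sum(axis=(2, 3)) + epsilon).astype(probs.data.dtype))
    return (1.0 - (inter * 2.0) / denom).sum()


def boundary_mse(pred_tsdf, target_tsdf, weights) -> Tensor:
    """(1/N) sum_i sum_k (1/HW) sum_j w (s - d)^2."""
    pred = _as_tensor(pred_tsdf)
    _check_nkhw("pred_tsdf", pred)
    target = np.asarray(target_tsdf)
    weights = np.asarray(weights)
    if target.shape != pred.shape or weights.shape != (
            pred.shape[0], pred.shape[2], pred.shape[3]):
        raise ValueError("shape mismatch between pred, target and weights")
    n, _, h, w = pred.shape
    diff = (pred - Tensor(target.astype(pred.data.dtype))) ** 2
    wt = Tensor(np.ascontiguousarray(weights[:, None]).astype(pred.data.dtype))
    return (wt * diff).sum() * (1.0 / (n * h * w))


def _weight_map(pred_tsdf_data: np.ndarray, target: np.ndarray,
                config: LossConfig) -> np.ndarray:
    """(N,H,W) adaptive weight map, computed outside the autograd graph."""
    src = (pred_tsdf_data if config.weight_source == "predicted" else target)
    maps = []
    for i in range(src.shape[0]):
        d1, d2 = _tsdf.top2(src[i])
        maps.append(_tsdf.entropy_weight(d1, d2).values)
    return np.stack(maps, axis=0)


def total_loss(seg_probs, pred_tsdf, mask, config: LossConfig,
               target_tsdf=None):
    """Composite loss and its components.

    mask may be (H,W) or (N,H,W); ``target_tsdf`` is the (N,K,H,W)
    normalized TSDF stack of the mask and is computed here (per image,
    with config.tau) when not supplied.  Returns ``(loss, parts)`` where
    parts maps 'ce', 'dice', 'bou', 'total' to floats.
    """
    seg_probs = _as_tensor(seg_probs)
    pred_tsdf = _as_tensor(pred_tsdf)
    _check_nkhw("seg_probs", seg_probs)
    n, K, h, w = seg_probs.shape
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    onehot = onehot_encode(mask, K)
    if target_tsdf is None:
        target_tsdf = np.stack(
            [_tsdf.tsdf_stack(mask[i], K, config.tau).values
             for i in range(n)], axis=0)
    else:
        target_tsdf = np.asarray(target_tsdf)
    if config.use_adaptive_weight:
        weights = _weight_map(pred_tsdf.data, target_tsdf, config)
    else:
        weights = np.ones((n, h, w))
    ce = weighted_cross_entropy(seg_probs, onehot, weights)
    dc = dice_loss(seg_probs, onehot, config.epsilon)
    bou = boundary_mse(pred_tsdf, target_tsdf, weights)
    total = ce + dc + bou * config.lambda_bou
    parts = {"ce": ce.item(), "dice": dc.item(), "bou": bou.item(),
             "total": total.item()}
    return total, parts
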