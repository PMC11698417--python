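"""Canned desk-scale experiments on synthetic data.

These functions define the package's reference synthetic study: train the
small-width dual-branch model on easy layered scenes, measure held-out
segmentation quality, and check that one structured-pruning iteration
plus a short fine-tune preserves it.  The tests and the acceptance
script both run exactly these conditions.

Study conditions: 128x256 scenes with K = 5 layers, high contrast, low
noise, no weakened boundaries; 64 training + 16 held-out images; model
widths [8, 16, 32, 32, 32]; 8 training epochs (batch 4, full-height
128x128 crops, cosine LR fully annealed 1e-3 -> 1e-5, mild photometric
jitter).  The full anneal matters: boundary-pixel jitter — and with it
the column-topology violation rate — keeps dropping as the LR tail
flattens, well after mean Dice has converged.
"""

from __future__ import annotations

import numpy as np

from .evaluation import column_topology_violations, dice_iou
from .network import ModelSpec, build_model, count_parameters
from .pruning import accumulate_importance, apply_prune, plan_prune
from .synthetic import random_scene, render_scene
from .training import TrainConfig, prepare_samples, train

__all__ = ["RECOVERY_SPEC", "recovery_train_config", "make_recovery_dataset",
           "train_recovery_model", "evaluate_model", "prune_and_recover"]

RECOVERY_SPEC = ModelSpec(n_classes=5, channels=(8, 16, 32, 32, 32))

_SCENE_KW = dict(width=256, height=128, K=5, contrast=0.9,
                 noise_sigma=(0.01, 0.02), max_weak=0)


def recovery_train_config(seed: int, epochs: int = 8) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=4, crop=128,
                       lr_start=1e-3, lr_end=1e-5, jitter=0.05, seed=seed)


def make_recovery_dataset(seed: int, n_train: int = 64, n_heldout: int = 16):
    """Easy synthetic layered scenes; returns (train, heldout) samples."""
    base = np.random.SeedSequence(seed).generate_state(n_train + n_heldout)
    labeled = [render_scene(random_scene(seed=int(s % (2 ** 31)), **_SCENE_KW))
               for s in base]
    samples = prepare_samples(labeled, RECOVERY_SPEC.n_classes)
    return samples[:n_train], samples[n_train:]


def train_recovery_model(train_samples, val_samples, seed: int,
                         epochs: int = 8):
    """Train the small-width model under the study conditions."""
    model = build_model(RECOVERY_SPEC, seed=seed)
    cfg = recovery_train_config(seed, epochs=epochs)
    return train(model, train_samples, val_samples, cfg)


def evaluate_model(model, samples) -> dict:
    """Held-out mean foreground Dice/IoU and topology-violation rate."""
    model.eval()
    K = model.spec.n_classes
    dices, ious, topo = [], [], []
    for s in samples:
        probs, _ = model(s.image[None])
        pred = probs.data[0].argmax(axis=0)
        rep = dice_iou(pred, s.mask, K)
        dices.append(rep.mean_dice)
        ious.append(rep.mean_iou)
        topo.append(column_topology_violations(pred))
    return {"mean_dice": float(np.mean(dices)),
            "mean_iou": float(np.mean(ious)),
            "topology_violation_rate": float(np.mean(topo))}


def prune_and_recover(model, train_samples, val_samples, seed: int,
                      ratio: float = 0.2, finetune_epochs: int = 4):
    """One pruning iteration at ``ratio`` plus a short fine-tune.

    Returns the fine-tuned pruned model and a dict with parameter counts
    before/after.  Importance is scored on the training images in fixed
    order without augmentation.
    """
    images = np.stack([s.image for s in train_samples], axis=0)
    batches = [images[i:i + 8] for i in range(0, len(images), 8)]
    table = accumulate_importance(model, batches)
    plan = plan_prune(table, ratio, min_kept=4)
    pruned = apply_prune(model, plan)
    cfg = TrainConfig(epochs=finetune_epochs, batch_size=4, crop=128,
                      lr_start=1e-3, lr_end=1e-5, jitter=0.05,
                      early_stop_dice=0.96, seed=seed + 1)
    pruned, _ = train(pruned, train_samples, val_samples, cfg)
    return pruned, {"params_before": count_parameters(model),
                    "params_after": count_parameters(pruned)}
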