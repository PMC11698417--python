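"""Channel-attention-scored structured pruning with weight transfer.

Kernel importance is the channel-attention weight alpha of each output
channel, summed over all batches of a scoring pass (the attention is
data-driven, so a single batch would be noisy).  Kernels are grouped per
convolution layer (its depth group), sorted ascending by importance, and
the bottom r% of the *current* kernels of each group are removed, never
going below a minimum.  Surgery rebuilds the model at the reduced widths
and copies every surviving parameter from the unpruned network: the kept
convolution kernels, their BN statistics, the matching rows/columns of
the attention MLPs, and the matching input-channel slices of every
consumer (decoder skips, both fusion branches, attention gates, heads)
by walking the named channel-group graph.  Iterating prune + fine-tune
five times and keeping the best validation checkpoint is the default
schedule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import DualBranchNet, count_parameters

__all__ = ["ImportanceTable", "PrunePlan", "accumulate_importance",
           "plan_prune", "apply_prune", "mask_pruned_channels",
           "iterative_prune"]


@dataclass
class ImportanceTable:
    """Accumulated alpha per output kernel of every prunable convolution.

    scores : group name -> (n_current,) nonnegative array
    kept   : group name -> current original channel indices (score i
             belongs to original channel kept[g][i])
    """

    scores: dict
    kept: dict
    batches_seen: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "batches_seen": self.batches_seen,
            "scores": {g: list(map(float, s)) for g, s in self.scores.items()},
            "kept": {g: list(map(int, k)) for g, k in self.kept.items()},
        })


@dataclass
class PrunePlan:
    """Per-group sorted original channel indices that survive."""

    kept: dict
    prune_ratio: float = 0.0
    min_kept: int = 4

    def to_json(self) -> str:
        return json.dumps({"prune_ratio": self.prune_ratio,
                           "min_kept": self.min_kept,
                           "kept": {g: list(map(int, k))
                                    for g, k in self.kept.items()}})


def accumulate_importance(model: DualBranchNet, batches) -> ImportanceTable:
    """Sum channel-attention alphas over scoring batches (inference mode).

    ``batches`` iterates arrays shaped (N,H,W) or (N,1,H,W).  Pure
    summation, so the result is invariant to batch order.
    """
    model.eval()
    units = model.attention_units
    scores = {g: np.zeros(u.ca.fc2.weight.shape[0]) for g, u in units.items()}
    seen = 0
    for x in batches:
        model(np.asarray(x))
        for g, u in units.items():
            scores[g] += u.ca.last_alpha.sum(axis=0)
        seen += 1
    if seen == 0:
        raise ValueError("accumulate_importance needs a nonempty dataset")
    kept = {g: model.spec.kept_indices(g) for g in units}
    return ImportanceTable(scores=scores, kept=kept, batches_seen=seen)


def plan_prune(table: ImportanceTable, r_p: float,
               min_kept: int = 4) -> PrunePlan:
    """Drop the floor(r_p * n_current) lowest-scoring kernels per group.

    Ties are broken by removing the lower channel index first; no group
    goes below ``min_kept`` kernels.
    """
    if not (0.0 <= r_p < 1.0):
        raise ValueError(f"prune ratio must be in [0, 1), got {r_p}")
    kept = {}
    for g, scores in table.scores.items():
        n = len(scores)
        n_keep = max(min_kept, n - math.floor(r_p * n))
        n_keep = min(n_keep, n)
        order = np.lexsort((np.arange(n), scores))   # ascending, low idx first
        removed = set(order[:n - n_keep].tolist())
        current = table.kept[g]
        kept[g] = [current[i] for i in range(n) if i not in removed]
    return PrunePlan(kept=kept, prune_ratio=r_p, min_kept=min_kept)


def _positions(new_idx, old_idx, group) -> np.ndarray:
    pos = {c: i for i, c in enumerate(old_idx)}
    try:
        return np.array([pos[c] for c in new_idx], dtype=np.intp)
    except KeyError as e:
        raise ValueError(f"prune plan keeps channel {e} that group "
                         f"{group!r} does not have") from None


def apply_prune(model: DualBranchNet, plan: PrunePlan) -> DualBranchNet:
    """Rebuild the model at the plan's widths, copying surviving weights.

    Every parameter of the new model is initialized from the unpruned
    network; a plan inconsistent with the model's bookkeeping raises a
    ValueError naming the first mismatched layer.
    """
    old_spec = model.spec
    new_kept = {g: list(old_spec.kept_indices(g)) for g in old_spec.groups}
    for g, idx in plan.kept.items():
        if g not in new_kept:
            raise ValueError(f"plan refers to unknown group {g!r}")
        new_kept[g] = list(idx)
    new_model = DualBranchNet(old_spec.with_kept(new_kept), seed=0)
    new_reg = new_model.registry
    for name, old_u in model.registry.items():
        new_u = new_reg[name]
        # output rows
        if isinstance(old_u.out_group, int):
            rows = np.arange(old_u.conv.out_ch, dtype=np.intp)
        else:
            g = old_u.out_group
            rows = _positions(new_model.spec.kept_indices(g),
                              old_spec.kept_indices(g), f"{name}:{g}")
        # input columns (concatenated group order)
        cols = []
        off = 0
        for g in old_u.in_groups:
            if isinstance(g, int):
                cols.append(np.arange(g, dtype=np.intp) + off)
                off += g
            else:
                old_idx = old_spec.kept_indices(g)
                cols.append(_positions(new_model.spec.kept_indices(g),
                                       old_idx, f"{name}:{g}") + off)
                off += len(old_idx)
        cols = np.concatenate(cols)
        if off != old_u.conv.in_ch:
            raise ValueError(f"channel bookkeeping mismatch at layer {name!r}")
        new_u.conv.weight.data[...] = old_u.conv.weight.data[
            np.ix_(rows, cols)]
        if old_u.conv.bias is not None:
            new_u.conv.bias.data[...] = old_u.conv.bias.data[rows]
        if old_u.bn is not None:
            new_u.bn.gamma.data[...] = old_u.bn.gamma.data[rows]
            new_u.bn.beta.data[...] = old_u.bn.beta.data[rows]
            new_u.bn.running_mean[...] = old_u.bn.running_mean[rows]
            new_u.bn.running_var[...] = old_u.bn.running_var[rows]
        if old_u.ca is not None:
            ca_o, ca_n = old_u.ca, new_u.ca
            ca_n.fc1.weight.data[...] = ca_o.fc1.weight.data[:, rows]
            ca_n.fc1.bias.data[...] = ca_o.fc1.bias.data
            ca_n.fc2.weight.data[...] = ca_o.fc2.weight.data[rows]
            ca_n.fc2.bias.data[...] = ca_o.fc2.bias.data[rows]
    return new_model


def mask_pruned_channels(model: DualBranchNet, plan: PrunePlan) -> None:
    """Zero the would-be-pruned kernels in place (oracle for surgery).

    Zeroing a kernel's convolution weights/bias and its BN affine makes
    the channel identically zero downstream, which is exactly what
    removing it does; forward outputs of the masked original model and
    the surgically pruned model coincide.
    """
    spec = model.spec
    for name, u in model.registry.items():
        if isinstance(u.out_group, int):
            continue
        g = u.out_group
        if g not in plan.kept:
            continue
        current = spec.kept_indices(g)
        gone = [i for i, c in enumerate(current) if c not in set(plan.kept[g])]
        if not gone:
            continue
        u.conv.weight.data[gone] = 0.0
        if u.conv.bias is not None:
            u.conv.bias.data[gone] = 0.0
        if u.bn is not None:
            u.bn.gamma.data[gone] = 0.0
            u.bn.beta.data[gone] = 0.0


def iterative_prune(model: DualBranchNet, train_samples, val_samples,
                    r_p: float, n_iters: int = 5, finetune_epochs: int = 20,
                    train_config=None, loss_config=None, min_kept: int = 4,
                    batch_size: int = 8, seed: int = 0):
    """Prune/fine-tune loop: score -> plan -> surgery -> fine-tune, n times.

    Scoring runs with augmentation disabled and fixed data order.  Returns
    ``(best_model, history)`` where history is a DataFrame with one row
    per iteration (parameter count, validation mean Dice) and the best
    model is the fine-tuned checkpoint with the highest validation Dice.
    """
    from .training import TrainConfig, train, mean_validation_dice

    if train_config is None:
        train_config = TrainConfig(epochs=finetune_epochs, seed=seed)
    rows = []
    candidates = []
    current = model
    for it in range(n_iters):
        images = np.stack([s.image for s in train_samples], axis=0)
        batches = [images[i:i + batch_size]
                   for i in range(0, len(images), batch_size)]
        table = accumulate_importance(current, batches)
        plan = plan_prune(table, r_p, min_kept=min_kept)
        current = apply_prune(current, plan)
        cfg = TrainConfig(**{**vars(train_config),
                             "epochs": finetune_epochs,
                             "seed": train_config.seed + it + 1})
        current, _ = train(current, train_samples, val_samples, cfg,
                           loss_config=loss_config)
        vd = mean_validation_dice(current, val_samples)
        rows.append({"iteration": it + 1,
                     "params": count_parameters(current),
                     "val_dice": vd,
                     "spec": current.spec})
        candidates.append(current)
    history = pd.DataFrame(rows)
    best = candidates[int(history["val_dice"].idxmax())]
    return best, history
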