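"""File I/O: masks and images (PNG), TSDF stacks (TIFF), YAML config."""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = ["read_mask", "write_mask", "read_image", "write_image",
           "write_tsdf_tiff", "read_tsdf_tiff", "write_weight_png",
           "read_config", "KNOWN_CONFIG_KEYS"]


def read_mask(path: str) -> np.ndarray:
    """Read an integer label mask from a single-channel PNG (lossless)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(f"{path}: mask must be single-channel")
    return arr.astype(np.int64)


def write_mask(path: str, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.min(initial=0) < 0 or mask.max(initial=0) > 255:
        raise ValueError("mask values must fit in 8 bits")
    iio.imwrite(path, mask.astype(np.uint8))


def read_image(path: str) -> np.ndarray:
    """Read an 8- or 16-bit grayscale image, normalized to [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    return np.clip(arr, 0.0, 1.0)


def write_image(path: str, image: np.ndarray) -> None:
    """Write a [0,1] float image as 16-bit grayscale PNG."""
    image = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (image * 65535).round().astype(np.uint16))


def write_tsdf_tiff(path: str, stack: np.ndarray) -> None:
    """Export a (K,H,W) TSDF stack as a multi-page float32 TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_tsdf_tiff(path: str) -> np.ndarray:
    return tifffile.imread(path).astype(np.float64)


def write_weight_png(path: str, weights: np.ndarray) -> None:
    """Export a (0,1] weight map as an 8-bit heatmap-style PNG."""
    w = np.clip(np.asarray(weights, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (w * 255).round().astype(np.uint8))


KNOWN_CONFIG_KEYS = {
    # training
    "epochs", "batch_size", "lr_start", "lr_end", "weight_decay", "crop",
    "flip_prob", "jitter_prob", "jitter", "folds", "seed",
    # loss
    "lambda_bou", "use_adaptive_weight", "weight_source", "epsilon", "tau",
    # model
    "channels", "n_classes", "ca_reduction", "kernel_size",
    # pruning
    "prune_ratio", "n_iters", "finetune_epochs", "min_kept",
}


def read_config(path: str, warn=print) -> dict:
    """Load a flat YAML config; warn about unknown keys, listing the
    accepted ones."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = sorted(set(cfg) - KNOWN_CONFIG_KEYS)
    if unknown:
        warn(f"warning: unknown config keys {unknown}; accepted keys: "
             f"{sorted(KNOWN_CONFIG_KEYS)}")
    return cfg
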