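"""Truncated signed distance maps and the entropy-based pixel weights.

For each tissue class k the boundary-regression branch is supervised with a
truncated signed distance function (TSDF): the Euclidean distance from every
pixel to the nearest boundary pixel of the class region, negative inside the
region, positive outside, clipped at a truncation radius ``tau`` and
normalized to [-1, 1] per class and per image.

Near boundaries (and wherever a model has not learned the layer topology)
the largest and second-largest per-class TSDF values at a pixel are close;
an information-entropy weight w(x) in (0, 1] quantifies that closeness and
is used to up-weight such pixels in the training losses.

Boundary membership convention: a pixel belongs to the boundary of class k
when it carries label k and has at least one 4-neighbour (inside the image)
with a different label.  Image borders alone do not create boundary pixels,
so the zero level set is a one-pixel-thick curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

__all__ = [
    "TsdfStack", "WeightMap", "boundary_pixels", "signed_distance",
    "normalize", "tsdf_stack", "top2", "entropy_weight", "DEFAULT_TAU",
]

#: default truncation radius in pixels
DEFAULT_TAU = 5.0


@dataclass
class TsdfStack:
    """Per-class normalized truncated signed distance maps.

    values : (K, H, W) array in [-1, 1]
    tau    : truncation radius in pixels
    """

    values: np.ndarray
    tau: float

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]


@dataclass
class WeightMap:
    """Per-pixel adaptive weight in (0, 1]; 1 exactly where the top two
    per-class TSDF values tie."""

    values: np.ndarray


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be an integer label image")
    return mask


def boundary_pixels(mask: np.ndarray, k: int) -> np.ndarray:
    """Boolean H x W map of the boundary pixels of class ``k``.

    A class-k pixel is a boundary pixel iff one of its 4-neighbours inside
    the image has a different label.  An absent class yields an all-False
    map.
    """
    mask = _check_mask(mask)
    inside = mask == k
    diff = np.zeros_like(inside)
    diff[:-1, :] |= inside[:-1, :] & (mask[1:, :] != k)
    diff[1:, :] |= inside[1:, :] & (mask[:-1, :] != k)
    diff[:, :-1] |= inside[:, :-1] & (mask[:, 1:] != k)
    diff[:, 1:] |= inside[:, 1:] & (mask[:, :-1] != k)
    return diff


def signed_distance(mask: np.ndarray, k: int, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Truncated signed Euclidean distance to the boundary of class ``k``.

    Negative of magnitude min(dist, tau) inside the class region, positive
    outside.  If the class has no boundary pixels the map is the constant
    +tau (class absent) or -tau (class fills the image).
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    mask = _check_mask(mask)
    inside = mask == k
    bnd = boundary_pixels(mask, k)
    if not bnd.any():
        fill = -tau if inside.all() else tau
        return np.full(mask.shape, fill, dtype=np.float64)
    # distance from every pixel to the nearest boundary pixel
    dist = distance_transform_edt(~bnd)
    dist = np.minimum(dist, tau)
    sign = np.where(inside, -1.0, 1.0)
    return sign * dist


def normalize(sd: np.ndarray) -> np.ndarray:
    """Scale a signed-distance map by its maximum absolute value.

    An identically-zero map is returned unchanged (degenerate convention);
    otherwise the output attains magnitude 1 somewhere and lies in [-1, 1].
    """
    sd = np.asarray(sd, dtype=np.float64)
    m = np.abs(sd).max()
    if m == 0:
        return np.zeros_like(sd)
    return sd / m


def tsdf_stack(mask: np.ndarray, K: int, tau: float = DEFAULT_TAU) -> TsdfStack:
    """Normalized TSDF maps for classes 0..K-1 stacked as (K, H, W)."""
    mask = _check_mask(mask)
    if mask.max(initial=0) >= K:
        raise ValueError(f"mask contains labels >= K={K}")
    maps = [normalize(signed_distance(mask, k, tau)) for k in range(K)]
    return TsdfStack(values=np.stack(maps, axis=0), tau=tau)


def top2(stack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel largest and second-largest value across the class axis.

    Accepts a :class:`TsdfStack` or a raw (K, H, W) array (for example the
    network's predicted TSDF).  On ties the lowest class index is treated
    as the argmax, so the runner-up is the next value in the full sort.
    """
    values = stack.values if isinstance(stack, TsdfStack) else np.asarray(stack)
    if values.ndim != 3 or values.shape[0] < 2:
        raise ValueError("need a (K,H,W) stack with K >= 2")
    part = np.sort(values, axis=0)
    return part[-1], part[-2]


def entropy_weight(dmax1: np.ndarray, dmax2: np.ndarray) -> WeightMap:
    """Adaptive weight from the two largest per-class TSDF values.

    The pair is softmaxed into probabilities p1 = e^d1 / (e^d1 + e^d2),
    p2 = 1 - p1, and the weight is their binary entropy in bits:
    w = -(p1 log p1 + p2 log p2) / log 2.  w depends on the pair only
    through the gap d1 - d2; it equals 1 at a tie and decreases
    monotonically as the gap grows.
    """
    d1 = np.asarray(dmax1, dtype=np.float64)
    d2 = np.asarray(dmax2, dtype=np.float64)
    gap = d1 - d2
    p1 = 1.0 / (1.0 + np.exp(-gap))
    p2 = 1.0 - p1
    # x*log(x) -> 0 as x -> 0; guard the log only
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(p1 * np.log(np.maximum(p1, 1e-300))
                + p2 * np.log(np.maximum(p2, 1e-300)))
    return WeightMap(values=ent / np.log(2.0))
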