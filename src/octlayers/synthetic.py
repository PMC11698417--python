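"""Synthetic layered "retina-like" images with known topology.

Flattened OCT B-scans of the retina show a stack of horizontal tissue
bands (NFL ... RPE) separated by smooth, non-crossing interfaces, with
per-layer intensity contrast, noise, and occasional locally weakened
boundaries.  This module draws such scenes so that the TSDF targets, the
losses, the network and the pruning schedule can all be exercised at desk
scale without any external dataset.

Conventions
-----------
* Class 0 is background and occupies the band above the first interface.
* Tissue classes 1..K-1 are vertically ordered, span the full width, and
  the last class extends to the image bottom.
* Interface j is the row coordinate of the top of tissue layer j; curves
  are strictly ordered at every column with a minimum gap of one pixel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = ["LayerScene", "LabeledImage", "sample_boundaries", "render_scene",
           "make_dataset", "random_scene"]


@dataclass
class LayerScene:
    """Parameters of one synthetic layered scene."""

    width: int
    height: int
    n_classes: int
    boundaries: np.ndarray          # (K-1, width), interface row per column
    intensities: np.ndarray         # (K,) mean gray level per class, in [0,1]
    noise_sigma: float = 0.0
    weak_regions: list = field(default_factory=list)  # (col0, col1, scale)
    speckle: bool = False
    seed: int = 0

    def validate(self):
        b = self.boundaries
        if b.shape != (self.n_classes - 1, self.width):
            raise ValueError("boundaries must have shape (K-1, width)")
        if not (np.diff(b, axis=0) > 0).all():
            raise ValueError("boundary curves must be strictly ordered")
        if (b <= 0).any() or (b >= self.height).any():
            raise ValueError("boundary curves must lie inside (0, height)")


@dataclass
class LabeledImage:
    """A gray image in [0,1] and its integer class mask of equal shape."""

    image: np.ndarray
    mask: np.ndarray


def sample_boundaries(width: int, height: int, K: int, smoothness: float = 0.7,
                      seed: int = 0, min_gap: float = 1.0,
                      n_bumps: int = 0) -> np.ndarray:
    """Draw K-1 smooth, strictly ordered interface curves.

    Each curve is a sum of two or three low-frequency sinusoids plus
    Gaussian noise smoothed along the column axis; ``smoothness`` in (0,1]
    trades amplitude and noise for flatness.  ``n_bumps`` adds that many
    localized Gaussian bumps/depressions to randomly chosen curves.  The
    curves are then projected onto the ordered cone with a column-wise
    minimum gap of ``min_gap`` (never below 1 pixel) and kept inside
    (0, height).  Deterministic given ``seed``.
    """
    if K < 2:
        raise ValueError(f"need K >= 2 classes, got K={K}")
    if width < 16 or height < 16:
        raise ValueError(f"image too small: need width,height >= 16, "
                         f"got {width}x{height}")
    min_gap = max(float(min_gap), 1.0)
    n_curves = K - 1
    if height - 2 < n_curves * min_gap:
        raise ValueError(f"height={height} cannot fit {n_curves} ordered "
                         f"curves with gap {min_gap}")
    rng = np.random.default_rng(seed)
    x = np.arange(width) / width
    # evenly spaced bases leaving a thin top margin and no bottom margin
    base = np.linspace(0.12, 0.92, n_curves) * height
    amp = 0.05 * height * (1.2 - 0.7 * smoothness)
    curves = np.empty((n_curves, width))
    for j in range(n_curves):
        c = np.full(width, base[j])
        for _ in range(rng.integers(2, 4)):
            freq = rng.uniform(0.5, 3.0)
            phase = rng.uniform(0, 2 * np.pi)
            c = c + rng.uniform(0.3, 1.0) * amp * np.sin(2 * np.pi * freq * x + phase)
        noise = rng.normal(0.0, 0.015 * height * (1.05 - smoothness), width)
        c = c + gaussian_filter1d(noise, sigma=max(1.0, smoothness * width / 16))
        curves[j] = c
    for _ in range(n_bumps):
        j = int(rng.integers(0, n_curves))
        center = rng.uniform(0.1, 0.9) * width
        sig = rng.uniform(0.02, 0.08) * width
        depth = rng.uniform(-0.08, 0.08) * height
        curves[j] += depth * np.exp(-0.5 * ((np.arange(width) - center) / sig) ** 2)
    # project to the ordered cone: push down, then pull back from the bottom
    curves[0] = np.clip(curves[0], 1.0, None)
    for j in range(1, n_curves):
        curves[j] = np.maximum(curves[j], curves[j - 1] + min_gap)
    curves[-1] = np.clip(curves[-1], None, height - 1.0)
    for j in range(n_curves - 2, -1, -1):
        curves[j] = np.minimum(curves[j], curves[j + 1] - min_gap)
    return curves


def render_scene(scene: LayerScene) -> LabeledImage:
    """Rasterize a scene into an image/mask pair.

    Pixel (r, c) gets tissue class j iff boundary_j <= r < boundary_{j+1}
    (the last class runs to the bottom, background above the first curve).
    The image is the per-class mean intensity plus Gaussian noise; inside
    each weak region the per-class intensities are compressed toward their
    mean by the region's contrast scale, so a scale of 0 erases the
    contrast between adjacent layers there.
    """
    scene.validate()
    h, w, K = scene.height, scene.width, scene.n_classes
    rows = np.arange(h)[:, None]
    # mask[r, c] = number of curves at or below row r
    mask = (rows >= scene.boundaries[:, None, :]).sum(axis=0).astype(np.uint8)
    intensities = np.asarray(scene.intensities, dtype=np.float64)
    image = intensities[mask]
    for (c0, c1, scale) in scene.weak_regions:
        c0, c1 = max(int(c0), 0), min(int(c1), w)
        if c1 <= c0:
            continue
        mu = intensities.mean()
        weak = mu + scale * (intensities - mu)
        image[:, c0:c1] = weak[mask[:, c0:c1]]
    rng = np.random.default_rng(scene.seed)
    if scene.speckle:
        # simple multiplicative speckle: unit-mean gamma multiplier
        image = image * rng.gamma(16.0, 1.0 / 16.0, size=image.shape)
    if scene.noise_sigma > 0:
        image = image + rng.normal(0.0, scene.noise_sigma, size=image.shape)
    return LabeledImage(image=np.clip(image, 0.0, 1.0), mask=mask)


def class_intensities(K: int, contrast: float = 0.8) -> np.ndarray:
    """Canonical mean gray level per class.

    Background (class 0) is the darkest; tissue layers take evenly spaced
    levels assigned from alternating ends of the brightness range, so
    layers adjacent in depth differ strongly in brightness (mimicking the
    alternating hyper-/hypo-reflective retinal bands).
    """
    lo, hi = 0.5 - 0.45 * contrast, 0.5 + 0.45 * contrast
    levels = np.linspace(lo, hi, K)
    out = np.empty(K)
    out[0] = levels[0]
    rest = list(levels[1:])
    take_high = True
    for j in range(1, K):
        out[j] = rest.pop(-1) if take_high else rest.pop(0)
        take_high = not take_high
    return out


def random_scene(width: int = 256, height: int = 128, K: int = 5,
                 seed: int = 0, noise_sigma: tuple = (0.01, 0.05),
                 contrast: float = 0.8, smoothness: float = 0.7,
                 max_weak: int = 2, max_bumps: int = 2,
                 speckle: bool = False) -> LayerScene:
    """Draw a full random scene: curves, intensities, noise, weak regions.

    ``contrast`` in (0,1] sets how far apart the per-class mean gray
    levels are.  As in real OCT, each tissue layer has a characteristic
    brightness that is consistent across images (hyper-/hypo-reflective
    bands alternating with depth, dark background) up to a small
    per-image jitter, so class identity is learnable from intensity.
    """
    rng = np.random.default_rng(seed)
    curves = sample_boundaries(width, height, K, smoothness=smoothness,
                               seed=int(rng.integers(2 ** 31)),
                               n_bumps=int(rng.integers(0, max_bumps + 1)))
    intensities = class_intensities(K, contrast)
    intensities = np.clip(intensities + rng.normal(0.0, 0.02, K), 0.0, 1.0)
    weak = []
    for _ in range(int(rng.integers(0, max_weak + 1))):
        c0 = int(rng.integers(0, max(1, width - 16)))
        c1 = c0 + int(rng.integers(8, max(9, width // 4)))
        weak.append((c0, min(c1, width), float(rng.uniform(0.1, 0.6))))
    return LayerScene(width=width, height=height, n_classes=K,
                      boundaries=curves, intensities=intensities,
                      noise_sigma=float(rng.uniform(*noise_sigma)),
                      weak_regions=weak, speckle=speckle,
                      seed=int(rng.integers(2 ** 31)))


def make_dataset(n_images: int, out_dir: str, seed: int = 0,
                 **scene_kwargs) -> pd.DataFrame:
    """Write ``n_images`` image/mask PNG pairs plus a CSV manifest.

    Images are 16-bit grayscale PNG, masks 8-bit PNG with pixel value =
    class index.  The manifest (``manifest.csv``) lists path_image,
    path_mask, K and the per-image seed; regeneration from the same
    arguments is byte-identical.  Extra keyword arguments are forwarded to
    :func:`random_scene`.
    """
    os.makedirs(out_dir, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_images)
    rows = []
    for i in range(n_images):
        s = int(child_seeds[i] % (2 ** 31))
        scene = random_scene(seed=s, **scene_kwargs)
        sample = render_scene(scene)
        p_img = os.path.join(out_dir, f"img_{i:04d}.png")
        p_msk = os.path.join(out_dir, f"mask_{i:04d}.png")
        iio.imwrite(p_img, (sample.image * 65535).round().astype(np.uint16))
        iio.imwrite(p_msk, sample.mask.astype(np.uint8))
        rows.append({"path_image": p_img, "path_mask": p_msk,
                     "K": scene.n_classes, "seed": s})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
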