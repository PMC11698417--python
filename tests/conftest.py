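import numpy as np
import pytest

from octlayers.synthetic import random_scene, render_scene
from octlayers.training import prepare_samples


def make_labeled(n, seed0=100, **kw):
    kw.setdefault("width", 256)
    kw.setdefault("height", 128)
    kw.setdefault("K", 5)
    return [render_scene(random_scene(seed=seed0 + i, **kw)) for i in range(n)]


@pytest.fixture(scope="session")
def easy_dataset():
    """High-contrast, low-noise layered images: 64 train + 16 held out."""
    lab = make_labeled(80, seed0=100, contrast=0.9,
                       noise_sigma=(0.01, 0.03), max_weak=1)
    samples = prepare_samples(lab, 5)
    return samples[:64], samples[64:]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
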