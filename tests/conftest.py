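"""Shared fixtures: small deterministic images and phantoms."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from ad3ri.io import RetinalImage


@pytest.fixture
def flat_image() -> RetinalImage:
    """Uniform 128x128 image at grey 100, ROI disc of 100 px radius."""
    return RetinalImage(
        pixels=np.full((128, 128), 100.0),
        resolution_um=12.5,
        roi_center=(63.5, 63.5),
        roi_diameter_um=1500.0,
    )


@pytest.fixture
def smooth_random_image():
    """Factory for smooth plateau-free test images (Gaussian-filtered noise)."""

    def make(seed: int, shape=(64, 64), sigma=3.0, lo=85.0, hi=115.0):
        rng = np.random.default_rng(seed)
        img = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
        img = lo + (hi - lo) * (img - img.min()) / (img.max() - img.min())
        return img

    return make


@pytest.fixture
def two_peak_profile_image():
    """Factory: 1-D intensity profile tiled into rows (controlled saddles)."""

    def make(profile):
        return np.tile(np.asarray(profile, dtype=float), (7, 1))

    return make
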