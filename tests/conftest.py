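from __future__ import annotations

import numpy as np
import pytest

from plaquekit import ImageGrid, SceneSpec, ShapeLimits, ZStack, make_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def separated_scene():
    """25 fully separated two-plateau plaques at core SNR 19 (noise sd 10)."""
    spec = SceneSpec(
        width_um=500.0,
        height_um=500.0,
        pixel_size_um=1.0,
        n_plaques=25,
        min_center_distance_um=32.0,
        seed=11,
    )
    channels, truth = make_scene(spec)
    return spec, channels, truth


@pytest.fixture
def default_shape_limits():
    return ShapeLimits(solidity=0.5, roundness=0.2)


def disk_image(radius_px: int, pad: int = 4, value: float = 100.0, pixel_size_um: float = 1.0):
    """A single bright rasterized disk on a zero background."""
    n = 2 * (radius_px + pad) + 1
    c = n // 2
    rr, cc = np.ogrid[:n, :n]
    img = np.zeros((n, n))
    img[(rr - c) ** 2 + (cc - c) ** 2 <= radius_px**2] = value
    return ImageGrid(img, pixel_size_um)


def stack_of(arr, pixel_size_um: float = 1.0, spacing: float = 1.0) -> ZStack:
    return ZStack(np.asarray(arr, dtype=float), pixel_size_um, slice_spacing_um=spacing)
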