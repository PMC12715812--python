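import numpy as np
import pytest
from skimage.draw import disk


def rasterize_disks(centers, radius, shape=(64, 64)):
    """Binary union of disks (the fused/separate bending-loss fixtures)."""
    m = np.zeros(shape, dtype=np.uint8)
    for c in centers:
        rr, cc = disk(c, radius, shape=shape)
        m[rr, cc] = 1
    return m


@pytest.fixture
def fused_and_separate_disks():
    """Two disks fused with a waist vs the same disks well separated."""

    def build(jitter_seed=0, radius=11.0, shape=(64, 96)):
        # identical subpixel jitter in both renderings, and the second disk is
        # displaced by an integer pixel count in the separate rendering, so
        # the staircase rasterization of each disk is pixel-identical in both
        # maps: the only geometric difference is the waist
        rng = np.random.default_rng(jitter_seed)
        dy, dx = rng.uniform(-0.5, 0.5, 2)
        c1 = (32 + dy, 20 + dx)
        d = 1.8 * radius
        fused = rasterize_disks([c1, (32 + dy, 20 + dx + d)], radius, shape)
        separate = rasterize_disks([c1, (32 + dy, 20 + dx + d + 40)], radius, shape)
        return fused, separate

    return build


@pytest.fixture
def regular_polygon():
    def build(m, radius=1.0):
        theta = 2 * np.pi * np.arange(m) / m
        return np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])

    return build
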