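"""Shared fixtures: small rasterised shapes with known geometry."""

import numpy as np
import pytest

from clumpsplit.synthetic import _disc_pixels


def rasterise_disc(shape, center, r):
    mask = np.zeros(shape, dtype=np.uint8)
    px = _disc_pixels(center, r, shape)
    mask[px[:, 0], px[:, 1]] = 1
    return mask


def rasterise_chain(radii, d_factors, bends, shape=None, margin=8):
    """Chain of overlapping discs along +col with per-link bend (radians)."""
    centres = [(0.0, 0.0)]
    theta = 0.0
    for i in range(1, len(radii)):
        d = d_factors[i - 1] * (radii[i - 1] + radii[i]) / 2.0
        theta += bends[i - 1]
        centres.append(
            (centres[-1][0] + d * np.sin(theta), centres[-1][1] + d * np.cos(theta))
        )
    ys = [c[0] for c in centres]
    xs = [c[1] for c in centres]
    rmax = max(radii)
    if shape is None:
        h = int(max(ys) - min(ys) + 2 * rmax + 2 * margin) + 1
        w = int(max(xs) - min(xs) + 2 * rmax + 2 * margin) + 1
        shape = (h, w)
    oy = -min(ys) + rmax + margin
    ox = -min(xs) + rmax + margin
    mask = np.zeros(shape, dtype=np.uint8)
    for (cy, cx), r in zip(centres, radii):
        px = _disc_pixels((cy + oy, cx + ox), r, shape)
        mask[px[:, 0], px[:, 1]] = 1
    return mask


@pytest.fixture
def two_disc_mask():
    """Canonical clump: two radius-10 discs, centres 15 px apart."""
    from clumpsplit.synthetic import make_two_disc_clump

    return make_two_disc_clump(10, 1.5)


@pytest.fixture
def square_mask():
    mask = np.zeros((30, 30), dtype=np.uint8)
    mask[5:25, 5:25] = 1
    return mask
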