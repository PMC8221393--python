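"""Geometry helpers shared across test modules."""

import numpy as np


def ball_mask(shape, center, r):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ) <= r**2


def dumbbell(sphere_r=15, gap=44, neck_r=4, shape=(48, 96, 48)):
    """Two spheres joined by a cylindrical neck along y.

    Returns (mask, center_sphere_0, center_sphere_1). The analytic volume of
    each lobe is the sphere plus half the exposed neck.
    """
    c = shape[0] // 2
    y0 = (shape[1] - gap) // 2
    y1 = y0 + gap
    m = ball_mask(shape, (c, y0, c), sphere_r) | ball_mask(shape, (c, y1, c), sphere_r)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    neck = ((zz - c) ** 2 + (xx - c) ** 2 <= neck_r**2) & (yy >= y0) & (yy <= y1)
    return m | neck, (c, y0, c), (c, y1, c)
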