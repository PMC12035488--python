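"""Classical interpolation upscalers the network is compared against."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .synthesis import MetaboliteMap


def nearest_upscale(lr: MetaboliteMap, factor: int = 4) -> MetaboliteMap:
    """Nearest-neighbor upscaling: replicate each pixel into a factor^2 block."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return replace(lr, values=lr.values.copy())
    values = np.repeat(np.repeat(lr.values, factor, axis=0), factor, axis=1)
    return replace(lr, values=values)


def spline_upscale(lr: MetaboliteMap, factor: int = 4, order: int = 3) -> MetaboliteMap:
    """Spline upscaling (cubic by default) with reflect boundaries.

    Uses the half-pixel block-center alignment convention (each output
    sample sits at the center of its subdivided cell), so the operation is
    the geometric inverse of block-average downsampling.  Output is clipped
    to [0, 1] for normalized inputs, since splines overshoot at edges.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return replace(lr, values=lr.values.copy())
    values = ndimage.zoom(lr.values, factor, order=order,
                          mode="reflect", grid_mode=True)
    if lr.normalized:
        values = np.clip(values, 0.0, 1.0)
    return replace(lr, values=values)


UPSCALERS = {"nearest": nearest_upscale, "spline": spline_upscale}
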