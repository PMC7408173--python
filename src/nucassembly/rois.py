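"""Euclidean shrink/expand region geometry shared by segmentation and simulation.

All "px" distances are Euclidean (distance-transform thresholding), not
iterative pixel erosion, so diagonal directions are not biased and band areas
match their analytic annulus areas up to boundary discretisation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def inner_distance(mask: np.ndarray) -> np.ndarray:
    """Distance of each foreground pixel to the nearest background pixel."""
    return ndi.distance_transform_edt(mask)


def outer_distance(mask: np.ndarray) -> np.ndarray:
    """Distance of each background pixel to the nearest foreground pixel."""
    return ndi.distance_transform_edt(~mask)


def shrink(mask: np.ndarray, d: float) -> np.ndarray:
    """Foreground pixels deeper than ``d`` px from the boundary."""
    return inner_distance(mask) > d


def expand(mask: np.ndarray, d: float) -> np.ndarray:
    """Foreground plus background pixels within ``d`` px of it."""
    return mask | (outer_distance(mask) <= d)


def periphery_band(mask: np.ndarray, width: float) -> np.ndarray:
    """Annulus between the mask outline and its ``width``-px shrink.

    For masks too small to shrink the band degenerates to the whole mask
    (callers flag this case).
    """
    return mask & ~shrink(mask, width)


def ne_toroid(mask: np.ndarray, halfwidth: float) -> np.ndarray:
    """Toroid straddling the boundary: ``halfwidth`` px inward and outward."""
    din = inner_distance(mask)
    dout = outer_distance(mask)
    return (mask & (din <= halfwidth)) | (~mask & (dout <= halfwidth))


def cytoplasm_ring(mask: np.ndarray, inner: float, outer: float) -> np.ndarray:
    """Background annulus between the ``inner``- and ``outer``-px expansions."""
    dout = outer_distance(mask)
    return (~mask) & (dout > inner) & (dout <= outer)
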