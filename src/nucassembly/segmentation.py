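"""Nucleus segmentation from the chromatin channel and the three derived ROIs.

Nuclei are segmented from the H2B/DAPI chromatin signal with the classic
primary-object recipe (Gaussian smoothing, global Otsu, hole filling,
connected components, size filter).  From each nuclear mask three further
regions are derived by Euclidean shrink/expand:

* ``periphery_band`` — the 20-px-wide annulus inside the nuclear outline,
  used for radial/peripheral enrichment ratios;
* ``cytoplasm_ring`` — the 5-to-20-px expansion outside the nucleus, used as
  local background (pixels near *other* nuclei are excluded);
* ``ne_toroid`` — the +/-5-px toroid straddling the boundary, used for
  nuclear-envelope markers such as nuclear pore complexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation as skseg

from . import rois

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    smooth_sigma_px: float = 2.0
    min_area_px2: float = 500.0
    drop_border: bool = True

    def validate(self) -> None:
        if self.smooth_sigma_px < 0:
            raise ValueError("smooth_sigma_px must be >= 0")
        if self.min_area_px2 <= 0:
            raise ValueError("min_area_px2 must be > 0")


@dataclass
class RoiParams:
    """Pixel geometry of the three derived ROIs."""

    periphery_shrink_px: float = 20.0
    background_inner_px: float = 5.0
    background_outer_px: float = 20.0
    ne_halfwidth_px: float = 5.0

    def validate(self) -> None:
        if not 0 < self.background_inner_px < self.background_outer_px:
            raise ValueError("need 0 < background_inner_px < background_outer_px")
        if self.periphery_shrink_px <= 0:
            raise ValueError("periphery_shrink_px must be > 0")
        if self.ne_halfwidth_px <= 0:
            raise ValueError("ne_halfwidth_px must be > 0")


@dataclass
class NucleusRois:
    """Boolean region rasters for one nucleus."""

    nucleus_id: int
    nuclear_mask: np.ndarray
    periphery_band: np.ndarray
    cytoplasm_ring: np.ndarray
    ne_toroid: np.ndarray
    degenerate: bool = False  # nucleus too small for the periphery shrink


@dataclass
class RoiSet:
    """Per-nucleus ROI collection derived from one label map."""

    nuclei: dict[int, NucleusRois] = field(default_factory=dict)
    params: RoiParams = field(default_factory=RoiParams)

    def __iter__(self):
        return iter(self.nuclei.values())

    def __len__(self) -> int:
        return len(self.nuclei)

    def __getitem__(self, nucleus_id: int) -> NucleusRois:
        return self.nuclei[nucleus_id]


def segment_nuclei(chromatin: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment nuclei from a single chromatin channel.

    Returns a label map (0 background, consecutive positive integers, one
    4-connected component each).  An all-constant image yields an empty map
    with a warning rather than an error.
    """
    params = params or SegmentationParams()
    params.validate()
    img = np.asarray(chromatin, dtype=float)
    if img.ndim != 2:
        raise ValueError("chromatin channel must be 2D")
    if np.any(img < 0):
        raise ValueError("chromatin channel must be nonnegative")
    if np.ptp(img) == 0:
        logger.warning("chromatin channel is constant; returning empty label map")
        return np.zeros(img.shape, dtype=np.uint16)

    smooth = ndi.gaussian_filter(img, params.smooth_sigma_px) if params.smooth_sigma_px > 0 else img
    thr = filters.threshold_otsu(smooth)
    fg = smooth > thr
    fg = ndi.binary_fill_holes(fg)
    if params.drop_border:
        fg = skseg.clear_border(fg)
    labels = measure.label(fg, connectivity=1)
    ids, counts = np.unique(labels, return_counts=True)
    small = ids[(ids > 0) & (counts < params.min_area_px2)]
    if small.size:
        labels[np.isin(labels, small)] = 0
    labels, _, _ = skseg.relabel_sequential(labels)
    return labels.astype(np.uint16)


def _bbox_slices(mask: np.ndarray, pad: int, shape) -> tuple[slice, slice]:
    ys, xs = np.nonzero(mask)
    return (
        slice(max(ys.min() - pad, 0), min(ys.max() + pad + 1, shape[0])),
        slice(max(xs.min() - pad, 0), min(xs.max() + pad + 1, shape[1])),
    )


def derive_rois(labels: np.ndarray, roi_params: RoiParams | None = None) -> RoiSet:
    """Derive periphery band, cytoplasm ring and NE toroid for every nucleus.

    Cytoplasm-ring pixels within ``background_outer_px`` of any *other*
    nucleus are excluded so crowded neighbours cannot bleed into the local
    background estimate.  A nucleus whose ``periphery_shrink_px`` erosion is
    empty keeps the whole mask as its band and is flagged degenerate.
    """
    p = roi_params or RoiParams()
    p.validate()
    labels = np.asarray(labels)
    out = RoiSet(params=p)
    ids = [int(v) for v in np.unique(labels) if v != 0]
    if not ids:
        return out

    # pad far enough that neighbours within 2x the outer distance are visible
    pad = 2 * int(np.ceil(p.background_outer_px)) + 2

    for i in ids:
        mask = labels == i
        sl = _bbox_slices(mask, pad, labels.shape)
        m = mask[sl]
        din = rois.inner_distance(m)
        dout = rois.outer_distance(m)

        core = din > p.periphery_shrink_px
        degenerate = not core.any()
        band = m.copy() if degenerate else (m & ~core)

        ring = (~m) & (dout > p.background_inner_px) & (dout <= p.background_outer_px)
        # drop pixels inside or within the outer distance of any other nucleus
        other = (labels[sl] > 0) & ~m
        other_dist = ndi.distance_transform_edt(~other)
        ring &= other_dist > p.background_outer_px

        toroid = (m & (din <= p.ne_halfwidth_px)) | ((~m) & (dout <= p.ne_halfwidth_px))
        toroid &= ~other  # never claim another nucleus' pixels

        def full(local: np.ndarray) -> np.ndarray:
            arr = np.zeros(labels.shape, dtype=bool)
            arr[sl] = local
            return arr

        out.nuclei[i] = NucleusRois(
            nucleus_id=i,
            nuclear_mask=full(m),
            periphery_band=full(band),
            cytoplasm_ring=full(ring),
            ne_toroid=full(toroid),
            degenerate=degenerate,
        )
    return out
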