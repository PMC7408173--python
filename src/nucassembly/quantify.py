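"""Per-cell, per-marker intensity metrics on the derived ROIs.

Metric definitions (per nucleus and marker):

* ``nuclear_intensity``  = mean(nuclear ROI) - mean(cytoplasm ring)
* ``ne_intensity``       = mean(NE toroid)   - mean(cytoplasm ring)
* ``radial_distribution`` = mean(periphery band) / mean(nuclear ROI),
  computed on raw (non-background-subtracted) intensities
* ``peripheral_distribution`` — same periphery/nuclear mean ratio (the two
  names come from the same formula; both columns are emitted)
* ``area_px2`` — nuclear pixel count

Background subtraction applies only to the two "intensity" metrics; the
ratios are raw by definition.  Nuclei with an empty cytoplasm ring keep
their raw means but get NaN subtracted intensities and a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .field import ImageField
from .segmentation import RoiSet

MEASUREMENT_COLUMNS = [
    "nucleus_id", "marker", "area_px2", "nuclear_mean_raw", "cytoplasm_mean_raw",
    "nuclear_intensity", "ne_intensity", "radial_distribution",
    "peripheral_distribution", "degenerate_flag", "background_missing",
]


def _mean(img: np.ndarray, mask: np.ndarray) -> float:
    return float(img[mask].mean()) if mask.any() else float("nan")


def marker_intensities(
    field: ImageField,
    rois: RoiSet,
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """Measure every marker channel over every nucleus ROI set.

    Returns one row per nucleus x marker with the metric columns listed in
    :data:`MEASUREMENT_COLUMNS`.
    """
    if markers is None:
        markers = [c for c in field.channel_names if c != "chromatin"]
    if not markers:
        raise ValueError("no marker channels to quantify")
    if len(rois):
        roi_shape = next(iter(rois)).nuclear_mask.shape
        for m in markers:
            if field[m].shape != roi_shape:
                raise ValueError(f"marker {m!r} shape differs from ROI geometry")

    rows = []
    for nr in rois:
        for m in markers:
            img = np.asarray(field[m], dtype=float)
            nuc_mean = _mean(img, nr.nuclear_mask)
            band_mean = _mean(img, nr.periphery_band)
            ring_mean = _mean(img, nr.cytoplasm_ring)
            ne_mean = _mean(img, nr.ne_toroid)
            bg_missing = not nr.cytoplasm_ring.any()
            ratio = band_mean / nuc_mean if nuc_mean != 0 else float("nan")
            rows.append({
                "nucleus_id": nr.nucleus_id,
                "marker": m,
                "area_px2": int(nr.nuclear_mask.sum()),
                "nuclear_mean_raw": nuc_mean,
                "cytoplasm_mean_raw": ring_mean,
                "nuclear_intensity": float("nan") if bg_missing else nuc_mean - ring_mean,
                "ne_intensity": float("nan") if bg_missing else ne_mean - ring_mean,
                "radial_distribution": ratio,
                "peripheral_distribution": ratio,
                "degenerate_flag": nr.degenerate,
                "background_missing": bg_missing,
            })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def cross_sectional_area(labels: np.ndarray, pixel_size: float = 1.0) -> pd.DataFrame:
    """Per-nucleus cross-sectional area: pixel count x pixel_size^2.

    ``pixel_size`` is the pixel edge in micrometres (1.0 keeps areas in px^2).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    labels = np.asarray(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return pd.DataFrame({
        "nucleus_id": ids.astype(int),
        "area": counts * pixel_size**2,
    })


def haz_intensity(field: ImageField, rois: RoiSet, channel: str = "H2A.Z") -> pd.DataFrame:
    """Background-subtracted nuclear mean of the H2A.Z channel, per nucleus."""
    df = marker_intensities(field, rois, markers=[channel])
    return df[["nucleus_id", "nuclear_intensity", "degenerate_flag",
               "background_missing"]].rename(columns={"nuclear_intensity": "haz_intensity"})
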