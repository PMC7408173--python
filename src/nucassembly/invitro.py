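"""Cell-free assay phenotype scoring: DAPI-void "holes" and dextran penetration.

In envelope-reassembly extracts the two scored phenotypes are

* *holes* — interior regions of a chromatin substrate devoid of DAPI
  staining, flagged when a blurred interior region falls below a fraction of
  the substrate's median intensity;
* *dextran penetration* — a large labeled dextran entering the chromatin
  area, flagged when the mean dextran signal inside the structure reaches a
  fraction of the surrounding-extract level (an intact envelope and compact
  chromatin exclude it).

Both calls are relative-intensity rules, so they are invariant to global
intensity scaling; the thresholds are declared, tunable calibration
constants, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from . import rois


@dataclass
class HoleParams:
    void_intensity_fraction: float = 0.35  # of the nuclear median
    min_void_px2: float = 100.0
    blur_sigma_px: float = 1.5

    def validate(self) -> None:
        if not 0 < self.void_intensity_fraction < 1:
            raise ValueError("void_intensity_fraction must lie in (0, 1)")
        if self.min_void_px2 <= 0:
            raise ValueError("min_void_px2 must be > 0")
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be >= 0")


@dataclass
class PenetrationParams:
    positive_fraction_threshold: float = 0.5  # of the surrounding dextran mean
    annulus_inner_px: float = 5.0
    annulus_outer_px: float = 20.0

    def validate(self) -> None:
        if not 0 < self.positive_fraction_threshold <= 1:
            raise ValueError("positive_fraction_threshold must lie in (0, 1]")
        if not 0 < self.annulus_inner_px < self.annulus_outer_px:
            raise ValueError("need 0 < annulus_inner_px < annulus_outer_px")


def detect_holes(
    chromatin: np.ndarray,
    nucleus_mask: np.ndarray,
    params: HoleParams | None = None,
) -> tuple[bool, pd.DataFrame]:
    """Flag one nucleus for interior chromatin voids.

    The chromatin channel is blurred, and connected interior regions whose
    blurred intensity falls below ``void_intensity_fraction`` x the nuclear
    median and whose area reaches ``min_void_px2`` are recorded as voids.
    Returns (flag, per-void records).
    """
    params = params or HoleParams()
    params.validate()
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("nucleus mask is empty")
    img = np.asarray(chromatin, dtype=float)
    if img.shape != nucleus_mask.shape:
        raise ValueError("chromatin and mask shapes differ")

    blurred = ndi.gaussian_filter(img, params.blur_sigma_px) if params.blur_sigma_px > 0 else img
    median = float(np.median(img[nucleus_mask]))
    low = nucleus_mask & (blurred < params.void_intensity_fraction * median)
    interior = ndi.binary_erosion(nucleus_mask)
    lab = measure.label(low, connectivity=1)
    records = []
    for region in measure.regionprops(lab):
        if region.area < params.min_void_px2:
            continue
        pmask = lab == region.label
        if np.any(pmask & ~interior):  # touches the substrate boundary
            continue
        records.append({
            "area_px2": int(region.area),
            "centroid_y": float(region.centroid[0]),
            "centroid_x": float(region.centroid[1]),
        })
    df = pd.DataFrame(records, columns=["area_px2", "centroid_y", "centroid_x"])
    return bool(len(df)), df


def holes_prevalence(
    flags,
    experiment: "pd.Series | list | None" = None,
) -> dict:
    """Percentage of structures flagged as holes.

    Without grouping: the pooled percentage.  With per-experiment labels the
    replicate convention applies: the mean of per-experiment percentages and
    their SD are returned alongside the per-experiment values.
    """
    flags = np.asarray(list(flags), dtype=bool)
    if flags.size == 0:
        raise ValueError("no structures to summarize")
    if experiment is None:
        return {"percent": 100.0 * flags.mean(), "n": int(flags.size)}
    grp = pd.DataFrame({"flag": flags, "experiment": list(experiment)})
    per = grp.groupby("experiment")["flag"].mean() * 100.0
    return {
        "percent": float(per.mean()),
        "sd": float(per.std(ddof=1)) if len(per) > 1 else 0.0,
        "per_experiment": per.to_dict(),
        "n": int(flags.size),
    }


def dextran_penetration(
    dextran: np.ndarray,
    chromatin_mask: np.ndarray,
    params: PenetrationParams | None = None,
) -> dict:
    """Score one chromatin structure for dextran penetration.

    Positive iff mean dextran inside the structure >= threshold x mean
    dextran in the 5-20-px surrounding annulus.  The annulus stands in for
    the free-extract level around the structure.
    """
    params = params or PenetrationParams()
    params.validate()
    chromatin_mask = np.asarray(chromatin_mask, dtype=bool)
    if not chromatin_mask.any():
        raise ValueError("chromatin mask is empty")
    img = np.asarray(dextran, dtype=float)
    annulus = rois.cytoplasm_ring(chromatin_mask, params.annulus_inner_px, params.annulus_outer_px)
    if not annulus.any():
        return {"positive": None, "flagged": True, "inside_mean": float(img[chromatin_mask].mean())}
    inside = float(img[chromatin_mask].mean())
    outside = float(img[annulus].mean())
    positive = inside >= params.positive_fraction_threshold * outside
    return {"positive": bool(positive), "flagged": False,
            "inside_mean": inside, "outside_mean": outside}


def penetration_percentage(results: list[dict]) -> dict:
    """Population percentage of dextran-positive structures (flagged excluded)."""
    calls = [r["positive"] for r in results if not r.get("flagged")]
    if not calls:
        raise ValueError("no scoreable structures")
    arr = np.asarray(calls, dtype=bool)
    return {"percent": 100.0 * arr.mean(), "n": int(arr.size),
            "n_flagged": len(results) - len(calls)}
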