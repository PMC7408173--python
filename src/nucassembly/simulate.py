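"""Synthetic fluorescence-microscopy fields and mitotic-track tables with ground truth.

The generator emulates the structures the analysis modules quantify:

* adherent-cell fields — non-overlapping nuclei rendered as smoothed
  star-convex chromatin blobs over a dim cytoplasmic background, with marker
  channels whose nuclear / peripheral-band / nuclear-envelope-ring / nucleolar
  enrichments are configurable per marker;
* cell-free ("in vitro") nucleus fields — one chromatin substrate per field,
  optionally carrying an interior chromatin void (a "hole"), the phenotype
  scored in envelope-reassembly extracts;
* phase-annotated mitotic tracks — per-frame phase labels sampled at a fixed
  frame interval from continuous anaphase-onset-to-interphase exit durations.

Every generated object is recorded in a ground-truth structure (exact masks,
painted region means, continuous durations) so each downstream measurement can
be checked against an exact oracle.  All randomness flows from the config
seed: identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from . import rois
from .field import ImageField

CHROMATIN = "chromatin"

PHASES = ("inter", "pro", "prometa", "meta", "ana", "telo")

# ---------------------------------------------------------------------------
# small named-distribution helpers


def sample_value(rng: np.random.Generator, spec: dict, size=None):
    """Draw from a named scalar distribution spec.

    Supported: ``point`` (value), ``normal`` (mean, sd), ``uniform``
    (low, high), ``lognormal`` (median, sigma).
    """
    name = spec["name"]
    if name == "point":
        v = spec["value"]
        return v if size is None else np.full(size, float(v))
    if name == "normal":
        return rng.normal(spec["mean"], spec["sd"], size)
    if name == "uniform":
        return rng.uniform(spec["low"], spec["high"], size)
    if name == "lognormal":
        return rng.lognormal(math.log(spec["median"]), spec["sigma"], size)
    raise ValueError(f"unknown distribution {name!r}")


def distribution_median(spec: dict) -> float:
    """Closed-form median of a named scalar distribution."""
    name = spec["name"]
    if name == "point":
        return float(spec["value"])
    if name == "normal":
        return float(spec["mean"])
    if name == "uniform":
        return (spec["low"] + spec["high"]) / 2.0
    if name == "lognormal":
        return float(spec["median"])
    raise ValueError(f"unknown distribution {name!r}")


def sample_count(rng: np.random.Generator, spec: dict) -> int:
    name = spec["name"]
    if name == "point":
        return int(spec["value"])
    if name == "poisson":
        return int(rng.poisson(spec["lam"]))
    if name == "uniform_int":
        return int(rng.integers(spec["low"], spec["high"] + 1))
    raise ValueError(f"unknown count distribution {name!r}")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class MarkerSpec:
    """Region enrichment model for one marker channel.

    Emulates the marker classes quantified on real fields: pan-nuclear
    histone marks (H2A.Z), peripherally enriched heterochromatin marks
    (H3K9me3), nuclear-pore staining concentrated on the envelope (mAB414)
    and nucleolar markers (KI-67).
    """

    name: str
    nuclear_mean: float = 100.0
    cytoplasm_mean: float = 10.0
    periphery_enrichment: float = 1.0  # x on the periphery band
    ne_ring_enrichment: float = 1.0    # x on the boundary toroid
    nucleolar_factor: float = 1.0      # x inside nucleoli/voids; 0 = excluded

    def validate(self) -> None:
        if self.nuclear_mean < 0 or self.cytoplasm_mean < 0:
            raise ValueError(f"marker {self.name!r}: means must be >= 0")
        for attr in ("periphery_enrichment", "ne_ring_enrichment", "nucleolar_factor"):
            if getattr(self, attr) < 0:
                raise ValueError(f"marker {self.name!r}: {attr} must be >= 0")


@dataclass
class ImageSimConfig:
    """Parameters of a synthetic multi-channel nucleus field.

    Radii and the band geometry are in pixels; intensity levels are in the
    (pre-noise) units of the target bit depth.  ``nucleus_radius_px`` must
    keep the 20-px periphery band a strict subset of the nucleus.
    """

    field_size_px: tuple[int, int] = (512, 512)
    n_nuclei: int = 8
    nucleus_radius_px: tuple[float, float] = (50.0, 5.0)  # mean, sd
    shape_irregularity: float = 0.08
    chromatin_level: float = 180.0
    cytoplasm_level: float = 20.0
    camera_noise_sd: float = 8.0
    nucleoli_per_nucleus: dict = field(default_factory=lambda: {"name": "point", "value": 0})
    nucleolus_radius_px: dict = field(default_factory=lambda: {"name": "normal", "mean": 8.0, "sd": 1.0})
    hole_prevalence: float = 0.0
    hole_radius_px: dict = field(default_factory=lambda: {"name": "point", "value": 12.0})
    marker_specs: list[MarkerSpec] = field(default_factory=list)
    band_width_px: float = 20.0
    ne_halfwidth_px: float = 5.0
    border_margin_px: float = 25.0
    bit_depth: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        mean_r, sd_r = self.nucleus_radius_px
        if mean_r <= 25:
            raise ValueError(
                "nucleus_radius_px mean must exceed 25 px so the 20-px periphery "
                "band leaves a nonempty interior"
            )
        if sd_r < 0:
            raise ValueError("nucleus_radius_px sd must be >= 0")
        if not 0.0 <= self.hole_prevalence <= 1.0:
            raise ValueError("hole_prevalence must lie in [0, 1]")
        if not 0.0 <= self.shape_irregularity <= 1.0:
            raise ValueError("shape_irregularity must lie in [0, 1]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.camera_noise_sd < 0:
            raise ValueError("camera_noise_sd must be >= 0")
        names = [m.name for m in self.marker_specs]
        if len(names) != len(set(names)) or CHROMATIN in names:
            raise ValueError("marker names must be unique and not 'chromatin'")
        for m in self.marker_specs:
            m.validate()

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class TrackSimConfig:
    """Parameters of synthetic phase-annotated mitotic-exit tracks.

    ``exit_duration_model`` is the continuous distribution of the time from
    anaphase onset to the first interphase morphology, in minutes; the
    annotated track quantizes it at ``frame_interval_min`` (default the 3-min
    acquisition interval of the live-imaging protocol).
    """

    n_tracks: int = 100
    frame_interval_min: float = 3.0
    pre_anaphase_frames: int = 4
    exit_duration_model: dict = field(default_factory=lambda: {"name": "lognormal", "median": 19.5, "sigma": 0.25})
    ana_duration_model: dict = field(default_factory=lambda: {"name": "point", "value": 6.0})
    movie_length_min: float | None = None  # None = long enough, no censoring
    seed: int = 0

    def validate(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.pre_anaphase_frames < 1:
            raise ValueError("pre_anaphase_frames must be >= 1")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class FieldTruth:
    """Exact generative record for one field: masks, geometry, painted means."""

    label_map: np.ndarray        # uint16, 0 background, k>0 nucleus k
    void_label_map: np.ndarray   # uint16, global void/nucleolus labels
    nuclei: pd.DataFrame         # nucleus_id, center_y/x, radius_px, area_px2, n_voids, has_hole
    voids: pd.DataFrame          # void_id, nucleus_id, center_y/x, radius_px, area_px2
    region_means: pd.DataFrame   # nucleus_id, channel, region, mean (pre-noise)

    def nucleus_mask(self, nucleus_id: int) -> np.ndarray:
        return self.label_map == nucleus_id

    def void_masks(self, nucleus_id: int) -> list[np.ndarray]:
        ids = self.voids.loc[self.voids.nucleus_id == nucleus_id, "void_id"]
        return [self.void_label_map == v for v in ids]


@dataclass
class InvitroTruth:
    """Ground truth for a population of single-nucleus fields."""

    per_field: list[FieldTruth]
    table: pd.DataFrame  # field_index, has_hole, void_area_px2


# ---------------------------------------------------------------------------
# geometry


def _star_blob(shape, center, radius, irregularity, rng):
    """Rasterize a smoothed star-convex blob; returns a full-field bool mask.

    The boundary radius is perturbed by low-order angular harmonics (2..6)
    with total relative amplitude bounded by ``irregularity``.
    """
    cy, cx = center
    ks = np.arange(2, 7)
    amps = rng.uniform(-1.0, 1.0, ks.size)
    phases = rng.uniform(0.0, 2 * np.pi, ks.size)
    total = np.sum(np.abs(amps))
    if total > 0:
        amps = amps / total * irregularity

    rmax = radius * (1.0 + irregularity) + 2.0
    y0 = max(int(cy - rmax), 0)
    y1 = min(int(cy + rmax) + 2, shape[0])
    x0 = max(int(cx - rmax), 0)
    x1 = min(int(cx + rmax) + 2, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    bound = np.full(theta.shape, radius, dtype=float)
    for a, k, ph in zip(amps, ks, phases):
        bound += radius * a * np.cos(k * theta + ph)
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = rr <= bound
    return mask


def _place_nuclei(config: ImageSimConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping nucleus centers and radii."""
    h, w = config.field_size_px
    mean_r, sd_r = config.nucleus_radius_px
    irr = config.shape_irregularity
    gap = 8.0
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 2000 * config.n_nuclei
    while len(placed) < config.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_nuclei} non-overlapping nuclei of "
                f"radius ~{mean_r} px in a {h}x{w} field; reduce n_nuclei or "
                "nucleus_radius_px, or enlarge field_size_px"
            )
        r = max(float(sample_value(rng, {"name": "normal", "mean": mean_r, "sd": sd_r})), 26.0)
        margin = r * (1 + irr) + config.border_margin_px
        if 2 * margin >= min(h, w):
            raise ValueError(
                f"nucleus radius {r:.0f} px does not fit a {h}x{w} field with "
                f"border margin {config.border_margin_px} px; enlarge field_size_px"
            )
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        ok = True
        for py, px, pr in placed:
            if math.hypot(cy - py, cx - px) < (r + pr) * (1 + irr) + gap:
                ok = False
                break
        if ok:
            placed.append((cy, cx, r))
    return placed


def _place_voids(nucleus_mask, n, radius_spec, rng, min_clearance=4.0, min_spacing=6.0):
    """Place up to ``n`` disjoint circular voids strictly inside a nucleus.

    Clearance from the nuclear boundary and spacing between voids are kept
    generous enough that a ~1.5-px detection blur neither merges neighbouring
    voids nor pushes them against the boundary.
    """
    din = rois.inner_distance(nucleus_mask)
    out = []
    for _ in range(n):
        r = float(sample_value(rng, radius_spec))
        r = max(r, 1.0)
        candidates = np.argwhere(din > r + min_clearance)
        if candidates.size == 0:
            continue
        for _try in range(50):
            cy, cx = candidates[rng.integers(len(candidates))]
            if all(math.hypot(cy - oy, cx - ox) > r + orr + min_spacing
                   for oy, ox, orr in out):
                out.append((float(cy), float(cx), r))
                break
    masks = []
    yy, xx = np.mgrid[0 : nucleus_mask.shape[0], 0 : nucleus_mask.shape[1]]
    for cy, cx, r in out:
        masks.append(((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2) & nucleus_mask)
    return out, masks


# ---------------------------------------------------------------------------
# painting


def _paint_field(config: ImageSimConfig, nucleus_masks, void_masks_per_nucleus):
    """Paint pre-noise float channels from the exact geometry."""
    shape = config.field_size_px
    channels: dict[str, np.ndarray] = {}

    chrom = np.full(shape, float(config.cytoplasm_level))
    for mask, voids in zip(nucleus_masks, void_masks_per_nucleus):
        chrom[mask] = config.chromatin_level
        for v in voids:
            chrom[v] = config.cytoplasm_level
    channels[CHROMATIN] = chrom

    for spec in config.marker_specs:
        img = np.full(shape, float(spec.cytoplasm_mean))
        for mask, voids in zip(nucleus_masks, void_masks_per_nucleus):
            img[mask] = spec.nuclear_mean
            if spec.periphery_enrichment != 1.0:
                band = rois.periphery_band(mask, config.band_width_px)
                img[band] = spec.nuclear_mean * spec.periphery_enrichment
            for v in voids:
                img[v] = spec.nuclear_mean * spec.nucleolar_factor
            if spec.ne_ring_enrichment != 1.0:
                tor = rois.ne_toroid(mask, config.ne_halfwidth_px)
                img[tor] *= spec.ne_ring_enrichment
        channels[spec.name] = img
    return channels


def _region_means(config, channels, nucleus_masks, void_masks_per_nucleus):
    """Brute-force pre-noise means over the painted ground-truth regions."""
    rows = []
    for i, mask in enumerate(nucleus_masks, start=1):
        regions = {
            "nucleus": mask,
            "periphery_band": rois.periphery_band(mask, config.band_width_px),
            "ne_toroid": rois.ne_toroid(mask, config.ne_halfwidth_px),
            "cytoplasm_ring": rois.cytoplasm_ring(mask, 5.0, 20.0),
        }
        voids = void_masks_per_nucleus[i - 1]
        if voids:
            regions["voids"] = np.any(voids, axis=0)
        for cname, img in channels.items():
            for rname, rmask in regions.items():
                if rmask.any():
                    rows.append(
                        {"nucleus_id": i, "channel": cname, "region": rname,
                         "mean": float(img[rmask].mean())}
                    )
    return pd.DataFrame(rows)


def _finalize(config: ImageSimConfig, channels, rng) -> ImageField:
    """Add Gaussian camera noise and quantize to the configured bit depth."""
    out = {}
    for name, img in channels.items():
        arr = img
        if config.camera_noise_sd > 0:
            arr = arr + rng.normal(0.0, config.camera_noise_sd, img.shape)
        out[name] = np.clip(np.rint(arr), 0, config.max_value).astype(config.dtype)
    return ImageField(out)


# ---------------------------------------------------------------------------
# public generators


def generate_cell_field(config: ImageSimConfig) -> tuple[ImageField, FieldTruth]:
    """Generate one multi-nucleus, multi-channel field with exact ground truth.

    Nuclei are pairwise disjoint by construction (rejection sampling); each
    carries ``nucleoli_per_nucleus`` chromatin voids and, with probability
    ``hole_prevalence``, one larger hole void.  Marker channels follow their
    :class:`MarkerSpec` region means exactly before noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    placed = _place_nuclei(config, rng)

    shape = config.field_size_px
    label_map = np.zeros(shape, dtype=np.uint16)
    void_label_map = np.zeros(shape, dtype=np.uint16)
    nucleus_masks: list[np.ndarray] = []
    void_masks_per_nucleus: list[list[np.ndarray]] = []
    nuclei_rows, void_rows = [], []
    next_void = 1

    for i, (cy, cx, r) in enumerate(placed, start=1):
        mask = _star_blob(shape, (cy, cx), r, config.shape_irregularity, rng)
        nucleus_masks.append(mask)
        label_map[mask] = i

        n_nucleoli = sample_count(rng, config.nucleoli_per_nucleus)
        geo, masks = _place_voids(mask, n_nucleoli, config.nucleolus_radius_px, rng)
        has_hole = bool(rng.random() < config.hole_prevalence)
        if has_hole:
            hgeo, hmasks = _place_voids(mask, 1, config.hole_radius_px, rng)
            has_hole = bool(hmasks)  # placement can fail in a crowded nucleus
            geo, masks = geo + hgeo, masks + hmasks
        for (vy, vx, vr), vmask in zip(geo, masks):
            void_label_map[vmask] = next_void
            void_rows.append(
                {"void_id": next_void, "nucleus_id": i, "center_y": vy,
                 "center_x": vx, "radius_px": vr, "area_px2": int(vmask.sum())}
            )
            next_void += 1
        void_masks_per_nucleus.append(masks)
        nuclei_rows.append(
            {"nucleus_id": i, "center_y": cy, "center_x": cx, "radius_px": r,
             "area_px2": int(mask.sum()), "n_voids": len(masks), "has_hole": has_hole}
        )

    channels = _paint_field(config, nucleus_masks, void_masks_per_nucleus)
    means = _region_means(config, channels, nucleus_masks, void_masks_per_nucleus)
    fld = _finalize(config, channels, rng)
    truth = FieldTruth(
        label_map=label_map,
        void_label_map=void_label_map,
        nuclei=pd.DataFrame(nuclei_rows),
        voids=pd.DataFrame(void_rows, columns=["void_id", "nucleus_id", "center_y",
                                               "center_x", "radius_px", "area_px2"]),
        region_means=means,
    )
    return fld, truth


def generate_invitro_nuclei(config: ImageSimConfig) -> tuple[list[ImageField], InvitroTruth]:
    """Generate ``n_nuclei`` single-nucleus fields (cell-free assay substrates).

    Each field holds one chromatin structure which carries an interior void
    ("hole") with probability ``hole_prevalence``; the true hole indicator and
    void geometry are recorded per field.
    """
    config.validate()
    fields, truths, rows = [], [], []
    # one spawned child seed per field keeps fields independent yet reproducible
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_nuclei) % (2**31)
    for idx in range(config.n_nuclei):
        sub = replace(config, n_nuclei=1, seed=int(seeds[idx]))
        fld, truth = generate_cell_field(sub)
        fields.append(fld)
        truths.append(truth)
        rec = truth.nuclei.iloc[0]
        varea = int(truth.voids.area_px2.sum()) if len(truth.voids) else 0
        rows.append({"field_index": idx, "has_hole": bool(rec.has_hole),
                     "void_area_px2": varea})
    return fields, InvitroTruth(per_field=truths, table=pd.DataFrame(rows))


@dataclass
class TrackTruth:
    """Continuous per-track ground truth behind the quantized annotations."""

    table: pd.DataFrame  # track_id, duration_true_min, ana_duration_min, censored


def generate_tracks(config: TrackSimConfig) -> tuple[pd.DataFrame, TrackTruth]:
    """Sample phase-annotated tracks quantizing continuous exit durations.

    Each track runs interphase -> prophase -> prometaphase -> metaphase ->
    anaphase -> telophase -> interphase on a fixed frame grid.  The first
    interphase frame after anaphase onset sits at the smallest frame time
    greater than or equal to the true continuous exit duration (ceiling
    quantization), which is the resolution limit of the live-imaging assay.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_min
    durations = np.atleast_1d(sample_value(rng, config.exit_duration_model, config.n_tracks))
    durations = np.maximum(durations, 1e-9)
    ana_durations = np.atleast_1d(sample_value(rng, config.ana_duration_model, config.n_tracks))
    ana_durations = np.clip(ana_durations, 0.0, None)

    pre = config.pre_anaphase_frames
    pre_phases = ["inter"] * max(pre - 3, 0) + ["pro", "prometa", "meta"][-min(pre, 3):]

    rows = []
    truth_rows = []
    for t_id in range(config.n_tracks):
        d = float(durations[t_id])
        ana_d = float(ana_durations[t_id])
        onset = pre * dt
        n_exit_frames = math.ceil(d / dt)  # frames strictly within [onset, exit)
        total_time = onset + n_exit_frames * dt  # time of first interphase frame
        censored = False
        if config.movie_length_min is not None and total_time > config.movie_length_min:
            censored = True
        frame = 0
        t = 0.0
        for ph in pre_phases:
            rows.append({"track_id": t_id, "frame": frame, "time_min": t, "phase": ph})
            frame += 1
            t += dt
        while True:
            if config.movie_length_min is not None and t > config.movie_length_min:
                break
            u = t - onset
            if u >= d:
                rows.append({"track_id": t_id, "frame": frame, "time_min": t, "phase": "inter"})
                break
            phase = "ana" if u < min(ana_d, d) else "telo"
            rows.append({"track_id": t_id, "frame": frame, "time_min": t, "phase": phase})
            frame += 1
            t += dt
        truth_rows.append(
            {"track_id": t_id, "duration_true_min": d,
             "ana_duration_min": min(ana_d, d), "censored": censored}
        )
    table = pd.DataFrame(rows, columns=["track_id", "frame", "time_min", "phase"])
    return table, TrackTruth(table=pd.DataFrame(truth_rows))


def generate_nc_series(
    n_tracks: int,
    plateau: float = 3.0,
    tau_min: float = 12.0,
    n_frames: int = 30,
    frame_interval_min: float = 3.0,
    base_cytoplasm: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired per-frame nuclear/cytoplasmic mean-intensity series.

    Emulates nuclear import of a fluorescent substrate after anaphase onset:
    the true nuclear-to-cytoplasmic ratio rises as
    ``1 + (plateau - 1) * (1 - exp(-t / tau_min))`` from ratio 1 at onset.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval_min
    rows = []
    for k in range(n_tracks):
        ratio = 1.0 + (plateau - 1.0) * (1.0 - np.exp(-t / tau_min))
        cyto = base_cytoplasm + rng.normal(0, noise_sd, n_frames)
        nuc = base_cytoplasm * ratio + rng.normal(0, noise_sd, n_frames)
        for f in range(n_frames):
            rows.append(
                {"track_id": k, "frame": f, "time_min": float(t[f]),
                 "nuclear_mean": float(nuc[f]), "cytoplasm_mean": float(cyto[f])}
            )
    return pd.DataFrame(rows)
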