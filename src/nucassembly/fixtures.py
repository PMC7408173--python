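"""Condition presets calibrated to the reported phenotypes.

The live-imaging medians are frame-quantized observations: a track's measured
exit duration is the smallest frame time >= its continuous duration.  Each
continuous fixture median is therefore placed at the midpoint of the reported
value's 3-min quantization bin, so that ceiling quantization at the 3-min
acquisition interval reproduces the reported median (control: continuous
19.5 min -> quantized 21 min) and the control/H2A.Z-oligo-C offset stays
10 min at finer sampling.  sigma = 0.25 (lognormal, ~25% CV) is a realistic
cell-to-cell spread for mitotic-exit timing.
"""

from __future__ import annotations

from .simulate import ImageSimConfig, TrackSimConfig

# continuous anaphase-onset -> interphase duration models, minutes
EXIT_DURATION_MODELS: dict[str, dict] = {
    # reported quantized medians: control 21; pontin 30; reptin 39; double 36;
    # H2A.Z oligo C = control + 10
    "control": {"name": "lognormal", "median": 19.5, "sigma": 0.25},
    "pontin_kd": {"name": "lognormal", "median": 28.5, "sigma": 0.25},
    "reptin_kd": {"name": "lognormal", "median": 37.5, "sigma": 0.25},
    "pontin_reptin_kd": {"name": "lognormal", "median": 34.5, "sigma": 0.25},
    "h2az_oligo_c": {"name": "lognormal", "median": 29.5, "sigma": 0.25},
}

# fraction of cell-free chromatin substrates showing DAPI-void "holes"
HOLE_PREVALENCE: dict[str, float] = {
    "mock": 0.0,
    "vps72_depleted": 0.50,
}


def track_config(condition: str, n_tracks: int, frame_interval_min: float = 3.0,
                 seed: int = 0) -> TrackSimConfig:
    """Track-generator config for a named knockdown condition."""
    try:
        model = EXIT_DURATION_MODELS[condition]
    except KeyError:
        raise KeyError(
            f"unknown condition {condition!r}; known: {sorted(EXIT_DURATION_MODELS)}"
        ) from None
    return TrackSimConfig(
        n_tracks=n_tracks,
        frame_interval_min=frame_interval_min,
        exit_duration_model=dict(model),
        seed=seed,
    )


def invitro_config(condition: str, n_nuclei: int, seed: int = 0,
                   hole_radius_px: float = 12.0) -> ImageSimConfig:
    """Cell-free-assay generator config for a named extract condition.

    Single-nucleus 256-px fields, radius 45 +/- 4 px, default camera noise;
    the hole prevalence is the condition's reported phenotype rate.
    """
    try:
        prevalence = HOLE_PREVALENCE[condition]
    except KeyError:
        raise KeyError(
            f"unknown condition {condition!r}; known: {sorted(HOLE_PREVALENCE)}"
        ) from None
    return ImageSimConfig(
        field_size_px=(256, 256),
        n_nuclei=n_nuclei,
        nucleus_radius_px=(45.0, 4.0),
        hole_prevalence=prevalence,
        hole_radius_px={"name": "point", "value": float(hole_radius_px)},
        seed=seed,
    )
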