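"""Mitotic-exit dwell times, cumulative interphase curves and N/C ratio series.

The central readout of the live-imaging assay is the time a cell spends
between anaphase onset (the first frame annotated ``ana``) and the end of
telophase, operationalized as the first frame annotated ``inter`` after the
last ``telo`` frame.  Tracks that never reach interphase before the movie
ends are censored: they are excluded from medians and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHASES = ("inter", "pro", "prometa", "meta", "ana", "telo")


@dataclass
class TrackAnnotation:
    """Ordered per-frame phase labels for one tracked cell lineage."""

    track_id: int
    frames: pd.DataFrame  # columns: time_min, phase (sorted by time)

    def __post_init__(self) -> None:
        t = self.frames["time_min"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError(f"track {self.track_id}: times must strictly increase")
        bad = set(self.frames["phase"]) - set(PHASES)
        if bad:
            raise ValueError(f"track {self.track_id}: unknown phase labels {sorted(bad)}")

    @property
    def frame_interval_min(self) -> float:
        t = self.frames["time_min"].to_numpy()
        return float(np.median(np.diff(t))) if len(t) > 1 else float("nan")


@dataclass
class DwellResult:
    track_id: int
    duration_min: float | None  # None when censored
    ana_min: float
    telo_min: float
    censored: bool


@dataclass
class DwellSummary:
    condition: str
    n: int
    n_censored: int
    median_min: float
    iqr_min: float
    q1_min: float
    q3_min: float
    median_ana_min: float
    median_telo_min: float


def _majority_smooth(phases: list[str]) -> list[str]:
    """Width-1 majority filter for single-frame annotation flickers."""
    out = list(phases)
    for k in range(1, len(phases) - 1):
        if phases[k - 1] == phases[k + 1] != phases[k]:
            out[k] = phases[k - 1]
    return out


def annotations_from_table(table: pd.DataFrame) -> list[TrackAnnotation]:
    """Group a track table (track_id, time_min, phase) into annotations."""
    out = []
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("time_min").reset_index(drop=True)
        out.append(TrackAnnotation(track_id=int(tid), frames=grp[["time_min", "phase"]]))
    return out


def mitotic_exit_dwell(track: TrackAnnotation, smooth: bool = False) -> DwellResult:
    """Time from anaphase onset to the first interphase frame ending mitosis.

    Duration = time of the first ``inter`` frame following the last ``telo``
    (or, for tracks without telophase frames, the last ``ana``) minus the
    time of the first ``ana`` frame.  Also reports the per-phase split as
    annotated frames x frame interval.
    """
    phases = list(track.frames["phase"])
    if smooth:
        phases = _majority_smooth(phases)
    times = track.frames["time_min"].to_numpy(dtype=float)
    dt = track.frame_interval_min

    ana_idx = [k for k, p in enumerate(phases) if p == "ana"]
    if not ana_idx:
        raise ValueError(f"track {track.track_id}: no anaphase frame")
    onset = ana_idx[0]
    telo_idx = [k for k, p in enumerate(phases[onset:], start=onset) if p == "telo"]
    last_mitotic = telo_idx[-1] if telo_idx else ana_idx[-1]
    exit_idx = next(
        (k for k, p in enumerate(phases[last_mitotic + 1 :], start=last_mitotic + 1) if p == "inter"),
        None,
    )
    n_ana = sum(1 for p in phases[onset:last_mitotic + 1] if p == "ana")
    n_telo = len(telo_idx)
    if exit_idx is None:
        return DwellResult(track.track_id, None, n_ana * dt, n_telo * dt, censored=True)
    return DwellResult(
        track.track_id,
        float(times[exit_idx] - times[onset]),
        n_ana * dt,
        n_telo * dt,
        censored=False,
    )


def dwell_table(tracks: list[TrackAnnotation], smooth: bool = False) -> pd.DataFrame:
    rows = [mitotic_exit_dwell(t, smooth=smooth).__dict__ for t in tracks]
    return pd.DataFrame(rows)


def dwell_summary(
    durations: pd.DataFrame | list[TrackAnnotation],
    condition: str = "all",
) -> DwellSummary | None:
    """Median and interquartile range of uncensored exit durations.

    Accepts either a dwell table (from :func:`dwell_table`) or annotations.
    Tracks are pooled across replicates, matching the reporting convention
    of merging mitotic events from independent experiments.  Returns None
    (with a warning) when every track is censored.
    """
    if not isinstance(durations, pd.DataFrame):
        durations = dwell_table(durations)
    ok = durations[~durations["censored"]]
    n_censored = int(durations["censored"].sum())
    if ok.empty:
        import logging

        logging.getLogger(__name__).warning(
            "all %d tracks censored for condition %r", len(durations), condition
        )
        return None
    d = ok["duration_min"].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return DwellSummary(
        condition=condition,
        n=int(len(d)),
        n_censored=n_censored,
        median_min=float(med),
        iqr_min=float(q3 - q1),
        q1_min=float(q1),
        q3_min=float(q3),
        median_ana_min=float(np.median(ok["ana_min"])),
        median_telo_min=float(np.median(ok["telo_min"])),
    )


def dwell_summaries(table: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """One :class:`DwellSummary` row per condition of a combined dwell table."""
    rows = []
    for cond, grp in table.groupby(by, sort=True):
        s = dwell_summary(grp, condition=str(cond))
        if s is not None:
            rows.append(s.__dict__)
    return pd.DataFrame(rows)


def cumulative_interphase_curve(durations: pd.DataFrame | list[TrackAnnotation]) -> pd.DataFrame:
    """Cumulative percentage of cells in interphase vs time since anaphase onset.

    The curve is the empirical CDF of the exit-duration multiset scaled to
    percent of *all* tracks: it starts at 0, is nondecreasing, and plateaus
    at 100 x (uncensored / total).
    """
    if not isinstance(durations, pd.DataFrame):
        durations = dwell_table(durations)
    total = len(durations)
    if total == 0:
        raise ValueError("no tracks")
    d = np.sort(durations.loc[~durations["censored"], "duration_min"].to_numpy(dtype=float))
    times, counts = np.unique(d, return_counts=True)
    cum = np.cumsum(counts) / total * 100.0
    return pd.DataFrame({
        "time_min": np.concatenate([[0.0], times]),
        "percent_interphase": np.concatenate([[0.0], cum]),
    })


def nc_ratio_series(
    series: pd.DataFrame,
    onset_time_min: float,
    nuclear_col: str = "nuclear_mean",
    cytoplasm_col: str = "cytoplasm_mean",
) -> pd.DataFrame:
    """Per-frame nuclear-to-cytoplasmic ratio, time-normalized to anaphase onset.

    Frames with a nonpositive cytoplasmic mean have no defined ratio; they
    are dropped from the output and counted in ``attrs['n_dropped']``.
    """
    req = {"time_min", nuclear_col, cytoplasm_col}
    missing = req - set(series.columns)
    if missing:
        raise ValueError(f"series missing columns: {sorted(missing)}")
    out = series.copy()
    out["time_since_onset_min"] = out["time_min"] - onset_time_min
    valid = out[cytoplasm_col] > 0
    dropped = int((~valid).sum())
    out = out[valid].copy()
    out["nc_ratio"] = out[nuclear_col] / out[cytoplasm_col]
    cols = ["time_since_onset_min", nuclear_col, cytoplasm_col, "nc_ratio"]
    if "track_id" in series.columns:
        cols = ["track_id"] + cols
    out = out[cols].reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    return out


def fit_import_kinetics(nc: pd.DataFrame) -> dict:
    """Fit ratio(t) = 1 + (plateau - 1) * (1 - exp(-t / tau)) to an N/C series.

    Returns the fitted plateau and time constant (minutes); a convenience
    cross-check for synthetic import kinetics, not a mechanistic claim.
    """
    from scipy.optimize import curve_fit

    t = nc["time_since_onset_min"].to_numpy(dtype=float)
    y = nc["nc_ratio"].to_numpy(dtype=float)
    keep = t >= 0
    t, y = t[keep], y[keep]

    def model(t, plateau, tau):
        return 1.0 + (plateau - 1.0) * (1.0 - np.exp(-t / tau))

    (plateau, tau), _ = curve_fit(model, t, y, p0=(max(y.max(), 1.5), max(t.max() / 3, 1.0)))
    return {"plateau": float(plateau), "tau_min": float(tau)}
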