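"""Readers and writers: multi-page TIFF fields, label maps, track CSVs, config.

Conventions: pixel indices are 0-based row-major; areas are px^2 unless a
pixel size is supplied; every CSV written here carries a leading ``#``
provenance comment (tool version and config hash) and a header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .field import ImageField
from .timing import PHASES, TrackAnnotation, annotations_from_table

TRACK_COLUMNS = ["track_id", "frame", "time_min", "phase"]


def write_image_field(field: ImageField, path: "str | Path") -> None:
    """Write one page per channel plus a ``<stem>.channels.csv`` sidecar."""
    path = Path(path)
    stack = np.stack([field[c] for c in field.channel_names])
    tifffile.imwrite(path, stack)
    sidecar = path.with_suffix("").with_suffix(".channels.csv")
    pd.DataFrame({"page": range(len(field.channel_names)),
                  "channel": field.channel_names}).to_csv(sidecar, index=False)


def read_image_field(path: "str | Path", channel_names: list[str] | None = None) -> ImageField:
    """Read a multi-page TIFF as named channels, preserving dtype.

    Channel names come from the argument, else from the sidecar written by
    :func:`write_image_field`, else default to ``ch0..chN``.  Inputs with
    more than one non-channel dimension (Z stacks, time series) are rejected
    with guidance to max-project upstream.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path.name}: {arr.ndim}D data; only 2D fields (pages = channels) are "
            "supported — max-project Z stacks before analysis"
        )
    n = arr.shape[0]
    if channel_names is None:
        sidecar = path.with_suffix("").with_suffix(".channels.csv")
        if sidecar.exists():
            channel_names = pd.read_csv(sidecar)["channel"].tolist()
        else:
            channel_names = [f"ch{i}" for i in range(n)]
    if len(channel_names) != n:
        raise ValueError(f"{path.name}: {n} pages but {len(channel_names)} channel names")
    if len(set(channel_names)) != n:
        raise ValueError("channel names must be unique")
    return ImageField({name: arr[i] for i, name in enumerate(channel_names)})


def write_label_map(labels: np.ndarray, path: "str | Path") -> None:
    tifffile.imwrite(Path(path), np.asarray(labels, dtype=np.uint16))


def read_label_map(path: "str | Path") -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError("label map must be a single 2D page")
    return arr


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: "str | Path", config: dict | None = None) -> None:
    """CSV with a provenance comment line (version + config hash)."""
    path = Path(path)
    h = config_hash(config or {})
    with open(path, "w") as fh:
        fh.write(f"# nucassembly {__version__} config={h}\n")
        df.to_csv(fh, index=False)


def read_table(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_tracks(table: pd.DataFrame, path: "str | Path", config: dict | None = None) -> None:
    write_table(table[TRACK_COLUMNS], path, config)


def read_tracks(path: "str | Path") -> list[TrackAnnotation]:
    """Read a track CSV into per-track annotations.

    Rows are grouped by ``track_id`` and sorted by time; unknown phase
    tokens raise an error naming the offending row, and nonuniform frame
    intervals only warn (the per-track interval is kept).
    """
    df = read_table(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {sorted(missing)}")
    bad = ~df["phase"].isin(PHASES)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(
            f"{Path(path).name}: unknown phase {df.loc[row, 'phase']!r} at row {row}"
        )
    tracks = annotations_from_table(df)
    for t in tracks:
        dt = np.diff(t.frames["time_min"].to_numpy())
        if len(dt) and not np.allclose(dt, dt[0]):
            import logging

            logging.getLogger(__name__).warning(
                "track %s: nonuniform frame interval", t.track_id
            )
    return tracks


def read_config(path: "str | Path") -> dict:
    """Parse a plain-text ``key = value`` configuration file.

    Values are JSON-decoded when possible (numbers, lists, booleans),
    otherwise kept as strings; ``#`` starts a comment.
    """
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{Path(path).name}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        val = val.strip()
        try:
            out[key.strip()] = json.loads(val)
        except json.JSONDecodeError:
            out[key.strip()] = val
    return out
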