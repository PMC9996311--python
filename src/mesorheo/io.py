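"""File formats: trajectory tables, TIFF movies with metadata sidecars, result tables.

All analysis tables use μm and seconds; pixels appear only inside the
tracking stage.  Every writer emits a format-versioned header line and
readers reject unknown major versions, so stale files fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import SchemaError

FORMAT_VERSION = "1.0"
_FORMAT_MAJOR = 1

TRAJECTORY_COLUMNS = ["trajectory_id", "frame", "x_um", "y_um", "intensity"]

#: default column mapping for tables exported by the Mosaic particle tracker
#: (coordinates in pixels; exact names vary by version, hence configurable)
MOSAIC_COLUMN_MAP = {
    "trajectory_id": "Trajectory",
    "frame": "Frame",
    "x_px": "x",
    "y_px": "y",
}


@dataclasses.dataclass
class Movie:
    """Ordered stack of 2D intensity frames with acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width)
    pixel_size_um: float = 0.18
    frame_interval_s: float = 0.5

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("movie frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _header_line(kind: str) -> str:
    return f"# mesorheo {kind} v{FORMAT_VERSION}"


def _check_header(line: str, kind: str, path: Path) -> None:
    m = re.match(rf"#\s*mesorheo\s+{re.escape(kind)}\s+v(\d+)\.(\d+)", line)
    if m is None:
        raise SchemaError(
            f"{path}: missing or unrecognized '{kind}' format header: {line!r}"
        )
    if int(m.group(1)) != _FORMAT_MAJOR:
        raise SchemaError(
            f"{path}: unsupported major format version {m.group(1)} "
            f"(this reader handles v{_FORMAT_MAJOR}.x)"
        )


def validate_trajectories(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    """Validate a trajectory table: schema, frame ordering, duplicates."""
    missing = [c for c in TRAJECTORY_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")
    if "intensity" not in df.columns:
        df = df.assign(intensity=np.nan)
    frames = df["frame"].to_numpy()
    if len(df) and not np.all(frames == np.floor(frames)):
        bad = int(np.flatnonzero(frames != np.floor(frames))[0])
        raise SchemaError(f"{source}: non-integer frame index at row {bad}")
    df = df.astype(
        {"frame": np.int64, "x_um": float, "y_um": float, "intensity": float}
    )
    dup = df.duplicated(subset=["trajectory_id", "frame"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = df.iloc[row][["trajectory_id", "frame"]].tolist()
        raise SchemaError(f"{source}: duplicate (trajectory_id, frame)={key} at row {row}")
    # frames must be strictly increasing within each trajectory as stored
    for tid, sub in df.groupby("trajectory_id", sort=False):
        d = np.diff(sub["frame"].to_numpy())
        if len(d) and d.min() <= 0:
            row = int(sub.index[int(np.argmax(d <= 0)) + 1])
            raise SchemaError(
                f"{source}: non-monotone frames in trajectory {tid!r} at row {row}"
            )
    return df[TRAJECTORY_COLUMNS]


def write_trajectories(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory table as versioned CSV (μm coordinates)."""
    path = Path(path)
    df = validate_trajectories(df, source=str(path))
    with open(path, "w") as fh:
        fh.write(_header_line("trajectory-table") + "\n")
        df.to_csv(fh, index=False)


def read_trajectories(
    path: str | Path,
    dialect: str = "native",
    pixel_size_um: float = 0.18,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a trajectory table.

    ``dialect='native'`` expects the package's own versioned CSV in μm.
    ``dialect='mosaic'`` reads a Mosaic-style export with pixel coordinates,
    mapping columns via ``column_map`` and converting to μm with
    ``pixel_size_um``.
    """
    path = Path(path)
    if dialect == "native":
        with open(path) as fh:
            _check_header(fh.readline().strip(), "trajectory-table", path)
            df = pd.read_csv(fh)
        return validate_trajectories(df, source=str(path))
    if dialect == "mosaic":
        cmap = dict(MOSAIC_COLUMN_MAP)
        if column_map:
            cmap.update(column_map)
        raw = pd.read_csv(path)
        missing = [v for v in cmap.values() if v not in raw.columns]
        if missing:
            raise SchemaError(f"{path}: mosaic export lacks column(s) {missing}")
        df = pd.DataFrame(
            {
                "trajectory_id": raw[cmap["trajectory_id"]],
                "frame": raw[cmap["frame"]],
                "x_um": raw[cmap["x_px"]].astype(float) * pixel_size_um,
                "y_um": raw[cmap["y_px"]].astype(float) * pixel_size_um,
            }
        )
        if "intensity" in cmap and cmap["intensity"] in raw.columns:
            df["intensity"] = raw[cmap["intensity"]].astype(float)
        return validate_trajectories(df, source=str(path))
    raise ValueError(f"unknown dialect {dialect!r} (expected 'native' or 'mosaic')")


def write_movie(movie: Movie, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write a movie as multi-page 16-bit TIFF plus a YAML metadata sidecar."""
    tiff_path = Path(tiff_path)
    frames = movie.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(tiff_path, frames)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".yaml")
    meta = {
        "format": f"mesorheo movie-metadata v{FORMAT_VERSION}",
        "pixel_size_um": float(movie.pixel_size_um),
        "frame_interval_s": float(movie.frame_interval_s),
        "n_frames": int(movie.n_frames),
        "shape": [int(s) for s in movie.shape],
    }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_movie(tiff_path: str | Path, sidecar_path: str | Path | None = None) -> Movie:
    """Read a TIFF stack and its YAML sidecar back into a :class:`Movie`."""
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".yaml")
    pixel_size_um, frame_interval_s = 0.18, 0.5
    sidecar_path = Path(sidecar_path)
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
        fmt = str(meta.get("format", ""))
        _check_header("# " + fmt if not fmt.startswith("#") else fmt, "movie-metadata", sidecar_path)
        pixel_size_um = float(meta["pixel_size_um"])
        frame_interval_s = float(meta["frame_interval_s"])
    return Movie(frames, pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s)


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write an analysis table as versioned TSV (``kind`` names the format)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_line(kind) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        _check_header(fh.readline().strip(), kind, path)
        return pd.read_csv(fh, sep="\t")


def config_hash(config: dict) -> str:
    """Stable content hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, config: dict, extra: dict | None = None) -> None:
    """Record everything needed to re-execute a run: config, hash, versions."""
    from . import __version__

    record = {
        "format": f"mesorheo provenance v{FORMAT_VERSION}",
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": config_hash(config),
        "config": config,
    }
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)
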