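"""Spot detection, frame-to-frame linking, and particle intensity measurement.

A deliberately simple re-implementation of the classic percentile-threshold
particle tracker: candidate spots are local intensity maxima above a
per-frame brightness quantile, refined to subpixel precision by an
intensity-weighted centroid over a pixel disk; linking assigns detections
between consecutive frames by minimizing summed squared displacement under a
maximum-displacement gate (Brownian cost), with no gap closing.  The
moment-based non-particle discrimination of the original tool is not
reproduced; a ``cutoff`` of 0 — the value used throughout here — disables it
there as well.

Conventions: pixel-centered, 0-based coordinates; ``x`` is the column index,
``y`` the row index; μm = pixels × pixel size.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter
from scipy.optimize import linear_sum_assignment

from .exceptions import ConfigError
from .io import Movie

__all__ = [
    "TrackingParams",
    "detect_spots",
    "link_spots",
    "track_movie",
    "measure_intensity",
]


@dataclasses.dataclass
class TrackingParams:
    """Detection and linking parameters.

    ``percentile`` is the percentage of brightest pixels retained as spot
    candidates (a local maximum must exceed the ``100 - percentile`` intensity
    quantile of its frame); it is acquisition-dependent and has no universal
    default, so it must be set deliberately.  ``cutoff=0`` keeps every
    candidate (no non-particle discrimination).  ``link_range`` must be 1:
    unmatched particles terminate and gaps are never closed.
    """

    radius_px: int = 2
    cutoff: float = 0.0
    percentile: float = 0.5
    link_range: int = 1
    max_disp_px: float = 5.0
    assignment: str = "greedy"  # greedy | hungarian

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ConfigError("radius_px must be >= 1")
        if not 0.0 < self.percentile <= 100.0:
            raise ConfigError("percentile must lie in (0, 100]")
        if self.link_range != 1:
            raise ConfigError(
                "only link_range=1 is supported (gap closing is out of scope)"
            )
        if self.max_disp_px <= 0:
            raise ConfigError("max_disp_px must be > 0")
        if self.assignment not in ("greedy", "hungarian"):
            raise ConfigError(f"unknown assignment {self.assignment!r}")


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    mask = dy**2 + dx**2 <= r**2
    return dy[mask], dx[mask]


def detect_spots(frame: np.ndarray, params: TrackingParams) -> pd.DataFrame:
    """Detect bright spots in a single frame.

    Returns a table with subpixel positions (``x_px``, ``y_px``), integrated
    intensity (``mass``) and mean intensity over the radius-r disk.  The
    centroid uses intensities above the local (disk-minimum) pedestal: a flat
    background is symmetric about the window center and would otherwise bias
    the centroid toward it.  ``mass`` and ``mean_intensity`` are raw sums.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2D frame, got ndim={frame.ndim}")
    r = params.radius_px
    if min(frame.shape) < 2 * r + 1:
        raise ValueError("frame smaller than the detection neighborhood")
    threshold = np.percentile(frame, 100.0 - params.percentile)
    local_max = frame >= maximum_filter(frame, size=2 * r + 1, mode="nearest")
    candidates = np.argwhere(local_max & (frame > threshold))

    dy, dx = _disk_offsets(r)
    h, w = frame.shape
    rows = []
    for cy, cx in candidates:
        yy = cy + dy
        xx = cx + dx
        keep = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        yy, xx = yy[keep], xx[keep]
        values = frame[yy, xx]
        mass = float(values.sum())
        if mass <= 0:
            continue
        weights = values - values.min()
        wsum = float(weights.sum())
        if wsum > 0:
            x_sub = float((weights * xx).sum() / wsum)
            y_sub = float((weights * yy).sum() / wsum)
        else:  # flat disk: no subpixel information
            x_sub, y_sub = float(cx), float(cy)
        rows.append(
            {
                "x_px": x_sub,
                "y_px": y_sub,
                "mass": mass,
                "mean_intensity": mass / len(values),
            }
        )
    return pd.DataFrame(rows, columns=["x_px", "y_px", "mass", "mean_intensity"])


def _match_frames(
    prev_xy: np.ndarray, cur_xy: np.ndarray, params: TrackingParams
) -> list[tuple[int, int]]:
    """Pairs (prev_index, cur_index) linking consecutive frames."""
    if len(prev_xy) == 0 or len(cur_xy) == 0:
        return []
    d2 = ((prev_xy[:, None, :] - cur_xy[None, :, :]) ** 2).sum(axis=2)
    gate = params.max_disp_px**2
    if params.assignment == "hungarian":
        big = 1e12
        cost = np.where(d2 <= gate, d2, big)
        rows, cols = linear_sum_assignment(cost)
        return [(int(i), int(j)) for i, j in zip(rows, cols) if d2[i, j] <= gate]
    # greedy: ascending squared distance, ties by (prev index, cur index)
    ii, jj = np.nonzero(d2 <= gate)
    order = np.lexsort((jj, ii, d2[ii, jj]))
    used_prev: set[int] = set()
    used_cur: set[int] = set()
    pairs = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_prev or j in used_cur:
            continue
        used_prev.add(i)
        used_cur.add(j)
        pairs.append((i, j))
    return pairs


def link_spots(detections: pd.DataFrame, params: TrackingParams) -> pd.DataFrame:
    """Link per-frame detections into trajectories.

    ``detections`` needs columns ``frame, x_px, y_px`` (extra columns are
    carried through).  Returns the same rows with a ``trajectory_id`` column;
    ids are assigned in order of trajectory birth and are stable for a given
    input.  Detections in non-adjacent frames are never linked.
    """
    if len(detections) == 0:
        out = detections.copy()
        out["trajectory_id"] = pd.Series(dtype=np.int64)
        return out
    detections = detections.sort_values(["frame"], kind="stable").reset_index(drop=True)
    traj_id = np.full(len(detections), -1, dtype=np.int64)
    next_id = 0
    by_frame = {int(f): sub.index.to_numpy() for f, sub in detections.groupby("frame")}
    frames_present = sorted(by_frame)
    xy = detections[["x_px", "y_px"]].to_numpy()

    prev_frame = None
    prev_idx = np.empty(0, dtype=np.int64)
    for f in frames_present:
        cur_idx = by_frame[f]
        if prev_frame is not None and f - prev_frame == 1:
            pairs = _match_frames(xy[prev_idx], xy[cur_idx], params)
            for i, j in pairs:
                traj_id[cur_idx[j]] = traj_id[prev_idx[i]]
        for k in cur_idx:
            if traj_id[k] < 0:
                traj_id[k] = next_id
                next_id += 1
        prev_frame, prev_idx = f, cur_idx

    out = detections.copy()
    out["trajectory_id"] = traj_id
    return out.sort_values(["trajectory_id", "frame"], kind="stable").reset_index(drop=True)


def track_movie(
    movie: Movie, params: TrackingParams, intensity_radius_px: int = 3
) -> pd.DataFrame:
    """Detect, link, and measure a whole movie; returns a trajectory table in μm.

    The ``intensity`` column holds the per-frame disk mean (fixed radius
    ``intensity_radius_px``) at each tracked position.
    """
    per_frame = []
    for f in range(movie.n_frames):
        det = detect_spots(movie.frames[f], params)
        det.insert(0, "frame", np.int64(f))
        per_frame.append(det)
    detections = pd.concat(per_frame, ignore_index=True)
    linked = link_spots(detections, params)
    if len(linked) == 0:
        from .io import TRAJECTORY_COLUMNS

        return pd.DataFrame(
            {c: pd.Series(dtype=(np.int64 if c in ("trajectory_id", "frame") else float))
             for c in TRAJECTORY_COLUMNS}
        )
    out = pd.DataFrame(
        {
            "trajectory_id": linked["trajectory_id"].to_numpy(),
            "frame": linked["frame"].to_numpy(dtype=np.int64),
            "x_um": linked["x_px"].to_numpy() * movie.pixel_size_um,
            "y_um": linked["y_px"].to_numpy() * movie.pixel_size_um,
            "intensity": np.nan,
        }
    )
    for tid, sub in out.groupby("trajectory_id"):
        per_frame_means, _, _ = measure_intensity(movie, sub, radius_px=intensity_radius_px)
        out.loc[sub.index, "intensity"] = per_frame_means
    return out


def measure_intensity(
    movie: Movie, trajectory: pd.DataFrame, radius_px: int = 3
) -> tuple[np.ndarray, float, bool]:
    """Mean pixel intensity in a fixed disk around a particle, per tracked frame.

    The disk (radius ``radius_px``, center pixel included, distances between
    pixel centers) is placed at the rounded particle position in every tracked
    frame; the scalar summary is the unweighted mean of the per-frame disk
    means — the particle's *average mean intensity*.

    Returns ``(per_frame_means, average_mean_intensity, edge_flag)``;
    ``edge_flag`` is True if any frame's disk was truncated by the field edge
    (the in-field portion is used).
    """
    frames_idx = trajectory["frame"].to_numpy(dtype=np.int64)
    if len(frames_idx) == 0:
        raise ValueError("trajectory has no localizations")
    if frames_idx.min() < 0 or frames_idx.max() >= movie.n_frames:
        raise ValueError("trajectory frames outside the movie range")
    x_px = np.round(trajectory["x_um"].to_numpy() / movie.pixel_size_um).astype(int)
    y_px = np.round(trajectory["y_um"].to_numpy() / movie.pixel_size_um).astype(int)
    dy, dx = _disk_offsets(radius_px)
    h, w = movie.shape
    means = np.empty(len(frames_idx))
    edge_flag = False
    for k, (f, cx, cy) in enumerate(zip(frames_idx, x_px, y_px)):
        yy = cy + dy
        xx = cx + dx
        in_field = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        if not in_field.all():
            edge_flag = True
            yy, xx = yy[in_field], xx[in_field]
        if len(yy) == 0:
            means[k] = np.nan
            continue
        means[k] = float(movie.frames[f][yy, xx].mean())
    return means, float(np.nanmean(means)), edge_flag
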