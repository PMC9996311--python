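"""Synthetic single-particle-tracking data.

Emulates cytoplasmic microrheology acquisitions in budding yeast: point-like
fluorescent tracers (exogenous μNS-like nanoparticles or mRNP granules)
imaged at 500 ms intervals for ~2 min at 0.18 μm/pixel, moving subdiffusively
(MSD = 4 D τ^α with α ≤ 1) with static localization noise, and rendered as
Gaussian spots of heterogeneous brightness on a noisy camera background.

Ground truth is exact: each coordinate is an independent fractional Brownian
motion with ``Var[x(t)] = 2 D t^α`` (Hurst H = α/2), so the noise-free 2D MSD
is ``4 D τ^α`` and parameter-recovery tests have a meaningful target.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .fbm import sample_fbm
from .io import TRAJECTORY_COLUMNS, Movie

__all__ = [
    "SimulationConfig",
    "RenderConfig",
    "simulate_trajectory",
    "simulate_condition",
    "draw_peak_intensities",
    "render_movie",
]


@dataclasses.dataclass
class SimulationConfig:
    """Ground-truth motion and acquisition parameters for one condition.

    Defaults mirror a typical spinning-disc yeast acquisition: 500 ms frame
    interval, 2 min movies (240 frames), 0.18 μm pixels.  ``D_true`` is the
    generalized diffusion coefficient in μm²/s^α; ``alpha_true`` the anomalous
    exponent (1 = Brownian, <1 subdiffusive); ``loc_error_um`` the static
    localization noise std per coordinate.
    """

    n_trajectories: int = 800
    n_frames: int = 240
    frame_interval_s: float = 0.5
    pixel_size_um: float = 0.18
    D_true: float = 0.01
    alpha_true: float = 1.0
    loc_error_um: float = 0.0
    fov_px: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_true < 2.0:
            raise ConfigError(f"alpha_true must lie in (0, 2), got {self.alpha_true}")
        if self.D_true < 0:
            raise ConfigError(f"D_true must be >= 0, got {self.D_true}")
        if self.loc_error_um < 0:
            raise ConfigError("loc_error_um must be >= 0")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be > 0")
        if self.n_trajectories < 0:
            raise ConfigError("n_trajectories must be >= 0")
        if self.fov_px < 1:
            raise ConfigError("fov_px must be >= 1")

    @property
    def fov_um(self) -> float:
        return self.fov_px * self.pixel_size_um

    @property
    def hurst(self) -> float:
        return self.alpha_true / 2.0


@dataclasses.dataclass
class RenderConfig:
    """How trajectories are painted into camera frames.

    Each in-field particle is a 2D Gaussian of width ``psf_sigma_px`` at its
    subpixel position.  Per-particle peak intensities are drawn log-normally
    (median ``peak_intensity``, log-std ``peak_sigma_log``) to emulate the
    size/brightness heterogeneity of self-assembling tracer particles;
    ``peak_sigma_log=0`` gives identical particles.
    """

    psf_sigma_px: float = 1.2
    peak_intensity: float = 2000.0
    peak_sigma_log: float = 0.0
    background: float = 100.0
    noise_model: str = "poisson"  # none | poisson | gaussian
    gaussian_sigma: float = 10.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ConfigError("psf_sigma_px must be > 0")
        if self.background < 0:
            raise ConfigError("background must be >= 0")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if not 1 <= self.bit_depth <= 16:
            raise ConfigError("bit_depth must be in [1, 16]")


def _simulate_positions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """One particle's observed (x, y) in μm, shape (n_frames, 2)."""
    n_steps = cfg.n_frames - 1
    scale = np.sqrt(2.0 * cfg.D_true)
    pos = np.empty((cfg.n_frames, 2))
    start = rng.uniform(0.0, cfg.fov_um, size=2)
    for axis in range(2):
        if cfg.D_true == 0.0:
            path = np.zeros(cfg.n_frames)
        else:
            path = sample_fbm(n_steps, cfg.hurst, cfg.frame_interval_s, rng, scale=scale)
        pos[:, axis] = start[axis] + path
    if cfg.loc_error_um > 0:
        pos += rng.normal(0.0, cfg.loc_error_um, size=pos.shape)
    return pos


def simulate_trajectory(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a single trajectory as a tidy table (frame, x_um, y_um)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pos = _simulate_positions(cfg, rng)
    return pd.DataFrame(
        {
            "trajectory_id": np.zeros(cfg.n_frames, dtype=np.int64),
            "frame": np.arange(cfg.n_frames, dtype=np.int64),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "intensity": np.full(cfg.n_frames, np.nan),
        }
    )


def simulate_condition(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate ``cfg.n_trajectories`` independent trajectories.

    Deterministic given ``cfg.seed`` (or a caller-supplied generator): one
    generator stream drives every draw in a fixed order.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, t = cfg.n_trajectories, cfg.n_frames
    if n == 0:
        return pd.DataFrame(
            {c: pd.Series(dtype=(np.int64 if c in ("trajectory_id", "frame") else float))
             for c in TRAJECTORY_COLUMNS}
        )
    xs = np.empty((n, t))
    ys = np.empty((n, t))
    for i in range(n):
        pos = _simulate_positions(cfg, rng)
        xs[i] = pos[:, 0]
        ys[i] = pos[:, 1]
    return pd.DataFrame(
        {
            "trajectory_id": np.repeat(np.arange(n, dtype=np.int64), t),
            "frame": np.tile(np.arange(t, dtype=np.int64), n),
            "x_um": xs.ravel(),
            "y_um": ys.ravel(),
            "intensity": np.full(n * t, np.nan),
        }
    )


def draw_peak_intensities(
    n: int, render: RenderConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-particle peak brightness: log-normal around ``peak_intensity``."""
    if render.peak_sigma_log == 0.0:
        return np.full(n, float(render.peak_intensity))
    return render.peak_intensity * np.exp(
        rng.normal(0.0, render.peak_sigma_log, size=n)
    )


def render_movie(
    trajectories: pd.DataFrame,
    render: RenderConfig,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    peak_intensities: np.ndarray | None = None,
) -> Movie:
    """Render trajectories into a synthetic camera movie.

    One frame per time point 0..n_frames-1; particles outside the field are
    clipped (not wrapped).  Returns a 16-bit :class:`~mesorheo.io.Movie` with
    the acquisition metadata from ``cfg``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    fov = cfg.fov_px
    frames = np.full((cfg.n_frames, fov, fov), float(render.background))
    if len(trajectories) == 0:
        warnings.warn("rendering an empty trajectory set: movie is pure background")
    else:
        ids = trajectories["trajectory_id"].to_numpy()
        uniq, inv = np.unique(ids, return_inverse=True)
        if peak_intensities is None:
            peak_intensities = draw_peak_intensities(len(uniq), render, rng)
        elif len(peak_intensities) != len(uniq):
            raise ConfigError("peak_intensities length must match trajectory count")
        sigma = render.psf_sigma_px
        half = max(1, int(np.ceil(4.0 * sigma)))
        frame_idx = trajectories["frame"].to_numpy(dtype=np.int64)
        x_px = trajectories["x_um"].to_numpy() / cfg.pixel_size_um
        y_px = trajectories["y_um"].to_numpy() / cfg.pixel_size_um
        for k in range(len(trajectories)):
            f = frame_idx[k]
            if not 0 <= f < cfg.n_frames:
                continue
            x, y = x_px[k], y_px[k]
            if not (-half <= x < fov + half and -half <= y < fov + half):
                continue  # fully out of field: clipped
            cx, cy = int(np.round(x)), int(np.round(y))
            x0, x1 = max(cx - half, 0), min(cx + half + 1, fov)
            y0, y1 = max(cy - half, 0), min(cy + half + 1, fov)
            if x0 >= x1 or y0 >= y1:
                continue
            gx = np.exp(-0.5 * ((np.arange(x0, x1) - x) / sigma) ** 2)
            gy = np.exp(-0.5 * ((np.arange(y0, y1) - y) / sigma) ** 2)
            frames[f, y0:y1, x0:x1] += peak_intensities[inv[k]] * np.outer(gy, gx)
    if render.noise_model == "poisson":
        frames = rng.poisson(frames).astype(float)
    elif render.noise_model == "gaussian":
        frames = frames + rng.normal(0.0, render.gaussian_sigma, size=frames.shape)
    max_val = float(2**render.bit_depth - 1)
    frames = np.clip(np.rint(frames), 0, max_val).astype(np.uint16)
    return Movie(frames, pixel_size_um=cfg.pixel_size_um, frame_interval_s=cfg.frame_interval_s)
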