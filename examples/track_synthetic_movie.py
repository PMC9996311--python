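"""Render a synthetic particle movie, re-track it, and close the loop on D.

Simulates 20 Brownian particles, paints them into a 16-bit TIFF-style movie
(Gaussian PSF, Poisson camera noise), then runs the detector and linker and
checks that the recovered median D_eff matches the ground truth.
"""

import numpy as np
import pandas as pd

from mesorheo import (
    RenderConfig,
    SimulationConfig,
    TrackingParams,
    analyze_trajectories,
    render_movie,
    simulate_condition,
    track_movie,
)

D_TRUE = 0.01  # μm²/s
cfg = SimulationConfig(
    n_trajectories=20, n_frames=150, D_true=D_TRUE, alpha_true=1.0,
    loc_error_um=0.0, fov_px=220, seed=607,
)
trajs = simulate_condition(cfg)

# anchor starts on a grid so spots stay separable (MSD ignores absolute position)
grid = np.stack(np.meshgrid(*[np.linspace(35, 185, 5) * cfg.pixel_size_um] * 2), -1)
parts = []
for (tid, sub), anchor in zip(trajs.groupby("trajectory_id"), grid.reshape(-1, 2)):
    sub = sub.copy()
    sub["x_um"] += anchor[0] - sub["x_um"].iloc[0]
    sub["y_um"] += anchor[1] - sub["y_um"].iloc[0]
    parts.append(sub)
trajs = pd.concat(parts, ignore_index=True)

render = RenderConfig(peak_intensity=5000.0, background=100.0, noise_model="poisson")
movie = render_movie(trajs, render, cfg, rng=np.random.default_rng(608))
print(f"rendered movie: {movie.n_frames} frames of {movie.shape}, "
      f"{movie.pixel_size_um} μm/px")

tracked = track_movie(movie, TrackingParams(radius_px=2, percentile=0.3, max_disp_px=5.0))
records = analyze_trajectories(tracked, frame_interval_s=0.5)
median_d = records["D_eff_um2_per_s"].median()
print(f"tracked {tracked['trajectory_id'].nunique()} trajectories; "
      f"{len(records)} pass the >10-point filter")
print(f"median D_eff = {median_d:.4f} μm²/s vs ground truth {D_TRUE} "
      f"({100 * (median_d / D_TRUE - 1):+.1f}%; centroid pixel-locking biases "
      f"displacements slightly low)")
print(f"median particle brightness (radius-3 disk mean) = "
      f"{records['mean_intensity'].median():.0f} counts")
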