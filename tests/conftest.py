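import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mesorheo import SimulationConfig, simulate_condition

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_trajectory(positions, trajectory_id=0, intensity=np.nan):
    """Trajectory table from an (n, 2) array of μm positions at frames 0..n-1."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return pd.DataFrame(
        {
            "trajectory_id": np.full(n, trajectory_id, dtype=np.int64),
            "frame": np.arange(n, dtype=np.int64),
            "x_um": positions[:, 0],
            "y_um": positions[:, 1],
            "intensity": np.full(n, intensity, dtype=float),
        }
    )


def well_separated_condition(
    n_particles=20, n_frames=200, D_true=0.01, fov_px=220, seed=42, margin_px=35
):
    """Simulated condition with starts laid out on a grid (no particle crossings).

    MSD analysis is translation-invariant, so re-anchoring each trajectory's
    start changes nothing downstream while keeping rendered spots separable.
    """
    cfg = SimulationConfig(
        n_trajectories=n_particles,
        n_frames=n_frames,
        D_true=D_true,
        alpha_true=1.0,
        loc_error_um=0.0,
        fov_px=fov_px,
        seed=seed,
    )
    trajs = simulate_condition(cfg)
    cols = int(np.ceil(np.sqrt(n_particles)))
    lin = np.linspace(margin_px, fov_px - margin_px, cols) * cfg.pixel_size_um
    grid = np.stack(np.meshgrid(lin, lin), axis=-1).reshape(-1, 2)[:n_particles]
    parts = []
    for (tid, sub), anchor in zip(trajs.groupby("trajectory_id"), grid):
        sub = sub.copy()
        sub["x_um"] += anchor[0] - sub["x_um"].iloc[0]
        sub["y_um"] += anchor[1] - sub["y_um"].iloc[0]
        parts.append(sub)
    return pd.concat(parts, ignore_index=True), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
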