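"""Mean-squared-displacement quantification and diffusivity fits.

The pipeline's core observables, per trajectory and per condition:

* the time-averaged MSD (TA-MSD) over all overlapping displacement pairs,
  ``MSD(kΔt) = <|r(t+kΔt) - r(t)|²>_t``;
* the ensemble-time-averaged MSD, the unweighted mean of per-trajectory
  TA-MSDs at each lag;
* the effective diffusion coefficient ``D_eff`` from a through-origin linear
  fit ``MSD(τ) = 4 D_eff τ`` over the first ten lags (the 5-second timescale
  at a 500 ms frame interval);
* the anomalous exponent ``α`` from an ordinary least-squares line in
  log10-log10 space, ``MSD(τ) = 4 D τ^α``.

Trajectories enter the analysis only if they have more than ten time points,
the conventional filter against short, tracking-error-dominated tracks.
Static localization noise of std σ per coordinate offsets the observed MSD
by ≈ 4σ², which biases the through-origin D_eff fit upward at short lags;
a free-intercept variant is available when that matters.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MSDCurve",
    "RheologyFit",
    "filter_trajectories",
    "compute_tamsd",
    "compute_ensemble_msd",
    "fit_deff",
    "fit_alpha",
    "analyze_trajectories",
]


@dataclasses.dataclass
class MSDCurve:
    """MSD values on a grid of time delays, with per-lag pair/track counts."""

    tau_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray
    kind: str  # time_averaged | ensemble

    def __post_init__(self) -> None:
        self.tau_s = np.asarray(self.tau_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if not (len(self.tau_s) == len(self.msd_um2) == len(self.n_pairs)):
            raise ValueError("tau_s, msd_um2, n_pairs must have equal length")
        if len(self.tau_s) and np.any(np.diff(self.tau_s) <= 0):
            raise ValueError("tau_s must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise ValueError("msd_um2 must be non-negative")


@dataclasses.dataclass
class RheologyFit:
    """A fitted diffusivity law for one trajectory or one ensemble curve.

    For the linear model ``alpha`` is fixed at 1 by construction; for the
    power-law model ``D_eff_um2_per_s`` is the generalized coefficient
    (units μm²/s^α).
    """

    D_eff_um2_per_s: float
    alpha: float
    n_lags_used: int
    r_squared: float
    scope: str = "trajectory"  # trajectory | ensemble
    model: str = "linear"  # linear | power_law


def _positions(trajectory: pd.DataFrame) -> np.ndarray:
    frames = trajectory["frame"].to_numpy()
    if len(frames) >= 2 and np.any(np.diff(frames) != 1):
        raise ValueError("trajectory has frame gaps; TA-MSD requires consecutive frames")
    return trajectory[["x_um", "y_um"]].to_numpy()


def filter_trajectories(
    trajectories: pd.DataFrame, min_points: int = 11
) -> pd.DataFrame:
    """Keep trajectories with at least ``min_points`` localizations.

    The default, 11, implements the 'more than ten time points' selection.
    Kept/dropped counts are logged at INFO level.
    """
    if len(trajectories) == 0:
        return trajectories.copy()
    sizes = trajectories.groupby("trajectory_id")["frame"].size()
    keep = sizes.index[sizes >= min_points]
    out = trajectories[trajectories["trajectory_id"].isin(keep)].copy()
    logger.info(
        "trajectory length filter (>= %d points): kept %d, dropped %d",
        min_points, len(keep), len(sizes) - len(keep),
    )
    return out


def compute_tamsd(
    trajectory: pd.DataFrame, max_lag: int, frame_interval_s: float = 0.5
) -> MSDCurve:
    """Time-averaged MSD of one trajectory over all overlapping pairs.

    At lag k the estimate averages the N-k squared displacements between
    points i and i+k.  Requires gapless, uniformly sampled frames and at
    least ``max_lag + 1`` points.
    """
    pos = _positions(trajectory)
    n = len(pos)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if n < max_lag + 1:
        raise ValueError(f"trajectory has {n} points; need >= {max_lag + 1} for max_lag={max_lag}")
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=np.int64)
    for k in range(1, max_lag + 1):
        disp = pos[k:] - pos[:-k]
        msd[k - 1] = np.mean(np.einsum("ij,ij->i", disp, disp))
        n_pairs[k - 1] = n - k
    tau = frame_interval_s * np.arange(1, max_lag + 1)
    return MSDCurve(tau, msd, n_pairs, kind="time_averaged")


def compute_ensemble_msd(
    trajectories: pd.DataFrame, max_lag: int, frame_interval_s: float = 0.5
) -> MSDCurve:
    """Ensemble-time-averaged MSD: mean of per-trajectory TA-MSDs per lag.

    Trajectories too short for a given lag simply do not contribute there;
    ``n_pairs`` records the number of contributing trajectories per lag.
    The input should already be length-filtered.
    """
    if len(trajectories) == 0:
        raise ValueError("cannot compute an ensemble MSD from an empty trajectory set")
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for _, sub in trajectories.groupby("trajectory_id", sort=True):
        n = len(sub)
        lags_here = min(max_lag, n - 1)
        if lags_here < 1:
            continue
        curve = compute_tamsd(sub, lags_here, frame_interval_s)
        sums[:lags_here] += curve.msd_um2
        counts[:lags_here] += 1
    if counts[0] == 0:
        raise ValueError("no trajectory long enough to contribute any lag")
    valid = counts > 0
    tau = frame_interval_s * np.arange(1, max_lag + 1)
    return MSDCurve(
        tau[valid], sums[valid] / counts[valid], counts[valid], kind="ensemble"
    )


def fit_deff(
    msd: MSDCurve, n_lags: int = 10, intercept: bool = False, scope: str | None = None
) -> RheologyFit:
    """Effective diffusion coefficient from ``MSD(τ) = 4 D_eff τ``.

    Least squares over the first ``n_lags`` lags, through the origin by
    default (the model has no intercept term); ``intercept=True`` adds a free
    offset to absorb the localization-noise plateau.  At a 0.5 s frame
    interval and ``n_lags=10`` this is the 5-second-timescale D_eff.
    """
    if len(msd.tau_s) < n_lags:
        raise ValueError(f"MSD curve has {len(msd.tau_s)} lags; need >= {n_lags}")
    tau = msd.tau_s[:n_lags]
    y = msd.msd_um2[:n_lags]
    if intercept:
        design = np.column_stack([tau, np.ones_like(tau)])
    else:
        design = tau[:, None]
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    d_eff = float(coef[0]) / 4.0
    fitted = design @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else np.nan)
    if scope is None:
        scope = "ensemble" if msd.kind == "ensemble" else "trajectory"
    return RheologyFit(d_eff, 1.0, n_lags, r2, scope=scope, model="linear")


def fit_alpha(msd: MSDCurve, n_lags: int = 10, scope: str | None = None) -> RheologyFit:
    """Anomalous exponent from an OLS line in log10(MSD) vs log10(τ).

    ``α`` is the slope; the generalized coefficient is ``10^intercept / 4``
    from ``MSD(τ) = 4 D τ^α``.  Any non-positive MSD value among the fitted
    lags makes the log undefined and raises; callers exclude (and count)
    such trajectories.
    """
    if len(msd.tau_s) < n_lags:
        raise ValueError(f"MSD curve has {len(msd.tau_s)} lags; need >= {n_lags}")
    tau = msd.tau_s[:n_lags]
    y = msd.msd_um2[:n_lags]
    if np.any(y <= 0):
        raise ValueError("non-positive MSD value in the fit range; alpha undefined")
    lx, ly = np.log10(tau), np.log10(y)
    slope, log_intercept = np.polyfit(lx, ly, 1)
    fitted = slope * lx + log_intercept
    ss_res = float(np.sum((ly - fitted) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else np.nan)
    if scope is None:
        scope = "ensemble" if msd.kind == "ensemble" else "trajectory"
    return RheologyFit(
        float(10.0**log_intercept) / 4.0, float(slope), n_lags, r2,
        scope=scope, model="power_law",
    )


def analyze_trajectories(
    trajectories: pd.DataFrame,
    frame_interval_s: float = 0.5,
    n_fit_lags: int = 10,
    min_points: int = 11,
    deff_intercept: bool = False,
) -> pd.DataFrame:
    """Per-trajectory D_eff and α for every trajectory passing the length filter.

    Returns one row per trajectory: ``trajectory_id, n_points,
    D_eff_um2_per_s, alpha, r_squared_D, r_squared_alpha, mean_intensity``.
    Trajectories with a zero MSD at a fitted lag keep their D_eff but get
    ``alpha = NaN`` (excluded from α analysis; exclusions are logged).
    """
    filtered = filter_trajectories(trajectories, min_points=min_points)
    rows = []
    n_alpha_excluded = 0
    for tid, sub in filtered.groupby("trajectory_id", sort=True):
        curve = compute_tamsd(sub, n_fit_lags, frame_interval_s)
        d_fit = fit_deff(curve, n_fit_lags, intercept=deff_intercept)
        try:
            a_fit = fit_alpha(curve, n_fit_lags)
            alpha, r2_a = a_fit.alpha, a_fit.r_squared
        except ValueError:
            n_alpha_excluded += 1
            alpha, r2_a = np.nan, np.nan
        if "intensity" in sub:
            inten = sub["intensity"].to_numpy()
            mean_intensity = float(np.nanmean(inten)) if np.any(~np.isnan(inten)) else np.nan
        else:
            mean_intensity = np.nan
        rows.append(
            {
                "trajectory_id": tid,
                "n_points": len(sub),
                "D_eff_um2_per_s": d_fit.D_eff_um2_per_s,
                "alpha": alpha,
                "r_squared_D": d_fit.r_squared,
                "r_squared_alpha": r2_a,
                "mean_intensity": mean_intensity,
            }
        )
    if n_alpha_excluded:
        logger.info("alpha fit excluded %d trajectories (zero MSD in range)", n_alpha_excluded)
    return pd.DataFrame(
        rows,
        columns=[
            "trajectory_id", "n_points", "D_eff_um2_per_s", "alpha",
            "r_squared_D", "r_squared_alpha", "mean_intensity",
        ],
    )
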