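"""TA-MSD estimator, ensemble averaging, and the D_eff / α fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mesorheo import (
    MSDCurve,
    SimulationConfig,
    analyze_trajectories,
    compute_ensemble_msd,
    compute_tamsd,
    filter_trajectories,
    fit_alpha,
    fit_deff,
    simulate_condition,
)
from conftest import make_trajectory


def brute_force_tamsd(positions, max_lag):
    """Independent oracle: explicit double loop over all overlapping pairs."""
    n = len(positions)
    out = []
    for k in range(1, max_lag + 1):
        acc = [
            (positions[i + k][0] - positions[i][0]) ** 2
            + (positions[i + k][1] - positions[i][1]) ** 2
            for i in range(n - k)
        ]
        out.append(sum(acc) / len(acc))
    return np.array(out)


class TestTamsd:
    def test_stationary_particle_zero_msd(self):
        traj = make_trajectory(np.tile([1.0, 2.0], (20, 1)))
        curve = compute_tamsd(traj, max_lag=5, frame_interval_s=0.5)
        assert np.allclose(curve.msd_um2, 0.0)
        assert np.array_equal(curve.n_pairs, [19, 18, 17, 16, 15])

    def test_hand_computed_ballistic_example(self):
        """Positions (0,0),(1,0),(2,0),(3,0) μm at 1 s: MSD = 1, 4, 9 μm²."""
        traj = make_trajectory([[0, 0], [1, 0], [2, 0], [3, 0]])
        curve = compute_tamsd(traj, max_lag=3, frame_interval_s=1.0)
        assert np.allclose(curve.msd_um2, [1.0, 4.0, 9.0])
        assert np.allclose(curve.tau_s, [1.0, 2.0, 3.0])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(12, 40))
            pos = rng.normal(size=(n, 2))
            traj = make_trajectory(pos)
            curve = compute_tamsd(traj, max_lag=10, frame_interval_s=0.5)
            assert np.allclose(curve.msd_um2, brute_force_tamsd(pos, 10), rtol=1e-12)

    def test_frame_gaps_rejected(self):
        traj = make_trajectory(np.zeros((10, 2)))
        traj.loc[5:, "frame"] += 2
        with pytest.raises(ValueError, match="gap"):
            compute_tamsd(traj, max_lag=3)

    def test_too_short_trajectory_rejected(self):
        traj = make_trajectory(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            compute_tamsd(traj, max_lag=5)

    @given(
        dx=st.floats(-5, 5), dy=st.floats(-5, 5),
        theta=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 10),
    )
    def test_translation_rotation_scaling_properties(self, dx, dy, theta, scale):
        """MSD is invariant to rigid motions and quadratic in a coordinate scale."""
        rng = np.random.default_rng(8)
        pos = rng.normal(size=(30, 2))
        base = compute_tamsd(make_trajectory(pos), 5).msd_um2
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pos @ rot.T + [dx, dy]
        assert np.allclose(compute_tamsd(make_trajectory(moved), 5).msd_um2, base,
                           rtol=1e-9, atol=1e-9)
        assert np.allclose(compute_tamsd(make_trajectory(scale * pos), 5).msd_um2,
                           scale**2 * base, rtol=1e-9)


class TestEnsembleMsd:
    def test_single_trajectory_identity(self, rng):
        pos = rng.normal(size=(30, 2))
        traj = make_trajectory(pos)
        single = compute_tamsd(traj, 8)
        ens = compute_ensemble_msd(traj, 8)
        assert np.allclose(ens.msd_um2, single.msd_um2)
        assert np.all(ens.n_pairs == 1)

    def test_mean_of_two_curves(self):
        # ballistic tracks with speeds 1 and sqrt(2): TA-MSDs differ by a factor 2
        t1 = make_trajectory([[i, 0] for i in range(12)], trajectory_id=0)
        t2 = make_trajectory([[np.sqrt(2) * i, 0] for i in range(12)], trajectory_id=1)
        ens = compute_ensemble_msd(pd.concat([t1, t2]), 3, frame_interval_s=1.0)
        assert np.allclose(ens.msd_um2, [1.5, 6.0, 13.5])

    def test_mixed_lengths_brute_force_reaverage(self, rng):
        """Longer lags draw on fewer trajectories; counts decrease monotonically."""
        parts, curves = [], {}
        for tid, n in enumerate([12, 15, 20, 31]):
            pos = rng.normal(size=(n, 2))
            parts.append(make_trajectory(pos, trajectory_id=tid))
            curves[tid] = brute_force_tamsd(pos, min(15, n - 1))
        ens = compute_ensemble_msd(pd.concat(parts), 15)
        for k in range(15):
            contributions = [c[k] for c in curves.values() if len(c) > k]
            assert ens.msd_um2[k] == pytest.approx(np.mean(contributions))
            assert ens.n_pairs[k] == len(contributions)
        assert np.all(np.diff(ens.n_pairs) <= 0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compute_ensemble_msd(make_trajectory(np.zeros((0, 2))), 5)


class TestFilter:
    def test_more_than_ten_time_points_boundary(self):
        """Length-10 trajectories are dropped; length-11 are kept."""
        parts = [
            make_trajectory(np.zeros((n, 2)), trajectory_id=n)
            for n in range(5, 16)
        ]
        kept = filter_trajectories(pd.concat(parts), min_points=11)
        kept_ids = set(kept["trajectory_id"])
        assert kept_ids == set(range(11, 16))

    def test_empty_and_all_kept(self):
        empty = make_trajectory(np.zeros((0, 2)))
        assert len(filter_trajectories(empty)) == 0
        parts = [make_trajectory(np.zeros((240, 2)), trajectory_id=i) for i in range(100)]
        kept = filter_trajectories(pd.concat(parts))
        assert kept["trajectory_id"].nunique() == 100


class TestFits:
    @staticmethod
    def curve(msd_values, dt=0.5):
        tau = dt * np.arange(1, len(msd_values) + 1)
        return MSDCurve(tau, msd_values, np.full(len(tau), 100), kind="time_averaged")

    def test_deff_model_identities(self):
        tau = 0.5 * np.arange(1, 11)
        assert fit_deff(self.curve(4 * tau)).D_eff_um2_per_s == pytest.approx(1.0)
        assert fit_deff(self.curve(2 * tau)).D_eff_um2_per_s == pytest.approx(0.5)
        assert fit_deff(self.curve(np.zeros(10))).D_eff_um2_per_s == 0.0

    def test_deff_equals_closed_form_projection(self, rng):
        """lstsq fit equals Σ(τ·MSD)/(4 Σ τ²) exactly (float tolerance)."""
        for _ in range(20):
            msd = rng.uniform(0, 5, size=12)
            c = self.curve(msd)
            fit = fit_deff(c, n_lags=10)
            tau = c.tau_s[:10]
            oracle = np.sum(tau * msd[:10]) / (4.0 * np.sum(tau**2))
            assert fit.D_eff_um2_per_s == pytest.approx(oracle, rel=1e-10)

    def test_deff_free_intercept_removes_noise_offset(self):
        tau = 0.5 * np.arange(1, 11)
        msd = 4 * 0.01 * tau + 0.01  # linear law plus a static-noise plateau
        through = fit_deff(self.curve(msd)).D_eff_um2_per_s
        free = fit_deff(self.curve(msd), intercept=True).D_eff_um2_per_s
        assert free == pytest.approx(0.01, rel=1e-9)
        assert through > free  # the documented positive bias

    def test_deff_requires_enough_lags(self):
        with pytest.raises(ValueError):
            fit_deff(self.curve(np.ones(5)), n_lags=10)

    def test_alpha_exact_power_laws(self):
        tau = 0.5 * np.arange(1, 11)
        fit = fit_alpha(self.curve(4 * tau))
        assert fit.alpha == pytest.approx(1.0)
        assert fit.D_eff_um2_per_s == pytest.approx(1.0)
        assert fit_alpha(self.curve(tau**0.5)).alpha == pytest.approx(0.5)

    def test_alpha_rejects_nonpositive_msd(self):
        msd = np.linspace(0.0, 1.0, 10)  # first value is zero
        with pytest.raises(ValueError, match="non-positive"):
            fit_alpha(self.curve(msd))

    def test_alpha_recovery_on_simulated_ensemble(self):
        """Ensemble α on 10³ noise-free fBm tracks at α=0.7 lands in [0.65, 0.75]."""
        cfg = SimulationConfig(n_trajectories=1000, n_frames=240, D_true=0.01,
                               alpha_true=0.7, loc_error_um=0.0, seed=17)
        ens = compute_ensemble_msd(simulate_condition(cfg), 10)
        assert 0.65 <= fit_alpha(ens).alpha <= 0.75


class TestAnalyzeTrajectories:
    def test_per_trajectory_table_and_alpha_exclusion(self):
        moving = make_trajectory(np.cumsum(np.ones((20, 2)), axis=0), trajectory_id=0)
        frozen = make_trajectory(np.zeros((20, 2)), trajectory_id=1)  # zero MSD: no α
        short = make_trajectory(np.zeros((5, 2)), trajectory_id=2)  # filtered out
        res = analyze_trajectories(pd.concat([moving, frozen, short]), 0.5)
        assert list(res["trajectory_id"]) == [0, 1]
        assert np.isnan(res.loc[res.trajectory_id == 1, "alpha"]).all()
        assert res.loc[res.trajectory_id == 1, "D_eff_um2_per_s"].item() == 0.0

    def test_brownian_parameter_recovery(self):
        """Median per-trajectory D_eff within 10% of D_true for an 800-track ensemble."""
        cfg = SimulationConfig(n_trajectories=800, n_frames=120, D_true=0.02,
                               alpha_true=1.0, loc_error_um=0.0, seed=23)
        res = analyze_trajectories(simulate_condition(cfg), 0.5)
        assert res["D_eff_um2_per_s"].median() == pytest.approx(0.02, rel=0.10)
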