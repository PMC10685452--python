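"""Superposition, RMSF and ΔRMSF."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from detscreen.model import Box, Frame, Trajectory
from detscreen.stability import (
    RMSFProfile,
    delta_rmsf,
    kabsch_superpose,
    residue_rmsf,
    rmsf_convergence,
)
from detscreen.synthetic import (
    ProteinSimParams,
    simulate_protein_fluctuations,
    spaced_reference_coords,
)

from conftest import quaternion_superpose_rmsd


class TestKabsch:
    def test_identity_on_equal_point_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        sup = kabsch_superpose(pts, pts)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(sup.translation, 0.0, atol=1e-10)
        assert sup.rmsd <= 1e-10

    def test_recovers_applied_rigid_motion(self, rng):
        pts = rng.normal(size=(12, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        shift = np.array([1.0, -2.0, 0.5])
        moved = pts @ rot90.T + shift
        sup = kabsch_superpose(moved, pts)
        assert sup.rmsd <= 1e-10
        assert np.allclose(sup.rotation @ rot90, np.eye(3), atol=1e-9)
        assert np.allclose(sup.apply(moved), pts, atol=1e-9)

    def test_rotation_is_always_proper(self, rng):
        for _ in range(20):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            sup = kabsch_superpose(a, b)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
            assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8)

    def test_matches_quaternion_oracle_on_noisy_instances(self, rng):
        """50 random rigid motions + Gaussian noise: rmsd agrees to 1e-9 nm
        with the independent quaternion-eigenvector solution."""
        for _ in range(50):
            n = rng.integers(4, 40)
            ref = rng.normal(size=(n, 3))
            rot = Rotation.random(random_state=rng).as_matrix()
            mobile = ref @ rot.T + rng.normal(size=3) + 0.05 * rng.normal(size=(n, 3))
            sup = kabsch_superpose(mobile, ref)
            assert abs(sup.rmsd - quaternion_superpose_rmsd(mobile, ref)) <= 1e-9

    def test_fitted_rmsd_never_exceeds_unfitted(self, rng):
        a = rng.normal(size=(15, 3))
        for _ in range(10):
            rot = Rotation.random(random_state=rng).as_matrix()
            b = a @ rot.T + rng.normal(size=3) + 0.1 * rng.normal(size=(15, 3))
            sup = kabsch_superpose(b, a)
            unfitted = np.sqrt(np.mean(np.sum((b - a) ** 2, axis=1)))
            assert sup.rmsd <= unfitted + 1e-12

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="three"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line)


def _ou_traj(sigma, n_frames, seed, n_res=16, tau=5.0):
    return simulate_protein_fluctuations(
        ProteinSimParams(
            reference_coords=spaced_reference_coords(n_res),
            sigma=sigma,
            tau=tau,
            n_frames=n_frames,
            seed=seed,
        )
    )


class TestResidueRMSF:
    def test_static_trajectory_has_zero_rmsf(self):
        traj = _ou_traj(0.0, 10, seed=1)
        prof = residue_rmsf(traj)
        assert np.allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_two_frame_displacement_without_fitting(self):
        """One residue at ±0.1 nm about its mean along z → RMSF exactly 0.1."""
        ref = spaced_reference_coords(5)
        box = Box((15.0, 15.0, 15.0))
        up, down = ref.copy(), ref.copy()
        up[2, 2] += 0.1
        down[2, 2] -= 0.1
        traj = _ou_traj(0.0, 2, seed=0, n_res=5)
        traj = Trajectory(traj.topology, [Frame(0.0, box, down), Frame(1.0, box, up)])
        prof = residue_rmsf(traj, fit_selection="none")
        assert prof.rmsf[2] == pytest.approx(0.1, abs=1e-12)
        assert np.allclose(np.delete(prof.rmsf, 2), 0.0, atol=1e-12)

    def test_ou_rmsf_recovers_sigma_sqrt3(self):
        """Unfitted RMSF of the OU toy protein matches σ√3 within 5%."""
        sigma = 0.05
        prof = residue_rmsf(_ou_traj(sigma, 20000, seed=4), fit_selection="none")
        expected = sigma * np.sqrt(3)
        assert np.max(np.abs(prof.rmsf - expected)) / expected <= 0.05

    def test_rmsf_invariant_under_global_rigid_motion(self, rng):
        """Applying one rigid motion to every frame changes fitted RMSF by <1e-6."""
        from scipy.spatial.transform import Rotation

        traj = _ou_traj(0.04, 60, seed=8, n_res=10)
        prof = residue_rmsf(traj)
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        shift = np.array([0.3, 0.1, -0.2])
        moved = Trajectory(
            traj.topology,
            [
                Frame(f.time, f.box, f.coords @ rot.T + shift)
                for f in traj.frames
            ],
        )
        prof2 = residue_rmsf(moved)
        assert np.max(np.abs(prof.rmsf - prof2.rmsf)) <= 1e-6

    def test_single_frame_window_is_an_error(self):
        traj = _ou_traj(0.05, 5, seed=2)
        with pytest.raises(ValueError, match="two frames"):
            residue_rmsf(traj, window=(0.0, 0.0))

    def test_spearman_recovery_of_heterogeneous_sigma(self, rng):
        sigma = np.linspace(0.02, 0.15, 16)
        prof = residue_rmsf(_ou_traj(sigma, 6000, seed=12), fit_selection="none")
        rho = spearmanr(prof.rmsf, sigma).statistic
        assert rho >= 0.99


class TestDeltaRMSF:
    def _profile(self, values):
        values = np.asarray(values, dtype=float)
        return RMSFProfile(
            residue_indices=np.arange(1, len(values) + 1),
            rmsf=values,
            fit_selection="heavy",
            representative="ca-or-heavy-centroid",
            n_frames_used=100,
        )

    def test_identical_profiles_give_zero(self):
        p = self._profile([0.1, 0.2, 0.3])
        d = delta_rmsf(p, p)
        assert np.allclose(d.per_residue_delta, 0.0)
        assert d.average_delta == 0.0

    def test_constant_offset_recovered_exactly(self):
        base = np.array([0.05, 0.10, 0.20, 0.08])
        c = 0.013
        d = delta_rmsf(self._profile(base + c), self._profile(base))
        assert np.allclose(d.per_residue_delta, c)
        assert d.average_delta == pytest.approx(c, abs=1e-15)

    def test_antisymmetry(self):
        a = self._profile([0.1, 0.2, 0.3])
        b = self._profile([0.3, 0.1, 0.25])
        dab = delta_rmsf(a, b)
        dba = delta_rmsf(b, a)
        assert np.allclose(dab.per_residue_delta, -dba.per_residue_delta)
        assert dab.average_delta == pytest.approx(-dba.average_delta)

    def test_mismatched_residue_sets_error_names_difference(self):
        a = self._profile([0.1, 0.2, 0.3])
        b = RMSFProfile(
            residue_indices=np.array([1, 2, 4]),
            rmsf=np.array([0.1, 0.2, 0.3]),
            fit_selection="heavy",
            representative="ca-or-heavy-centroid",
            n_frames_used=100,
        )
        with pytest.raises(ValueError, match=r"\[3, 4\]"):
            delta_rmsf(a, b)

    def test_ou_profiles_recover_sigma_difference(self):
        """σ 0.05 vs 0.07 OU toys → average ΔRMSF ≈ 0.02·√3 ≈ 0.0346 within 5%."""
        ref = residue_rmsf(_ou_traj(0.05, 20000, seed=21), fit_selection="none")
        det = residue_rmsf(_ou_traj(0.07, 20000, seed=22), fit_selection="none")
        d = delta_rmsf(det, ref)
        expected = 0.02 * np.sqrt(3)
        assert expected == pytest.approx(0.0346, abs=5e-5)
        assert abs(d.average_delta - expected) / expected <= 0.05


class TestRMSFConvergence:
    def test_stationary_ou_profiles_converge(self):
        traj = _ou_traj(0.05, 4000, seed=30, n_res=8)
        # theoretical SE of a stationary RMSF estimate with n_eff = n/(2τ)
        n_eff = 2000 / (2 * 5.0)
        se = 0.05 * np.sqrt(3) / np.sqrt(2 * n_eff)
        rep = rmsf_convergence(
            traj, [1999.0, 2999.0, 3999.0], tolerance=3 * se * np.sqrt(8),
            fit_selection="none",
        )
        assert rep.equilibrated

    def test_sigma_jump_breaks_equilibration(self):
        a = _ou_traj(0.04, 500, seed=31, n_res=6)
        b = _ou_traj(0.08, 500, seed=32, n_res=6)
        frames = a.frames + [
            Frame(f.time + 500.0, f.box, f.coords) for f in b.frames
        ]
        traj = Trajectory(a.topology, frames)
        rep = rmsf_convergence(
            traj, [499.0, 999.0], tolerance=0.005, fit_selection="none"
        )
        assert not rep.equilibrated

    def test_single_checkpoint_is_an_error(self):
        traj = _ou_traj(0.05, 50, seed=33)
        with pytest.raises(ValueError, match="two"):
            rmsf_convergence(traj, [49.0], tolerance=1.0)
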