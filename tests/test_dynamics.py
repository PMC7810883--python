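"""Superposition, RMSF/ΔRMSF, clustering and convergence checks."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pdzdyn import (
    RMSFProfile,
    SyntheticSpec,
    Trajectory,
    align_trajectory,
    cluster_conformations,
    combine_replicas,
    compute_rmsf,
    convergence_check,
    delta_rmsf,
    generate_trajectory,
    kabsch_superpose,
    resolve_selection,
    rmsd_series,
)
from pdzdyn.dynamics import DegenerateGeometryError


class TestKabsch:
    def test_identity_when_mobile_equals_reference(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd_nm < 1e-12
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd_nm < 1e-12
        assert np.allclose(res.apply(pts), moved, atol=1e-10)
        assert np.isclose(np.linalg.det(res.rotation), 1.0)

    def test_agrees_with_numerical_minimization_oracle(self):
        """Independent oracle: direct minimization over rotation vectors."""
        rng = np.random.default_rng(42)
        mobile = rng.normal(size=(5, 3))
        reference = rng.normal(size=(5, 3))

        def objective(x):
            rot = Rotation.from_rotvec(x[:3]).as_matrix()
            moved = mobile @ rot.T + x[3:]
            return np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1)))

        best = min(
            (minimize(objective, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
             for x0 in [np.zeros(6), np.r_[1.0, 0, 0, 0, 0, 0], np.r_[0, 2.0, 1.0, 1, 1, 1]]),
            key=lambda r: r.fun,
        )
        res = kabsch_superpose(mobile, reference)
        assert abs(res.rmsd_nm - best.fun) < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_reference_rejected_not_reflected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        mobile = np.random.default_rng(2).normal(size=(4, 3))
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(mobile, line)


class TestAlignment:
    def test_rigid_body_motion_removed(self, small_traj):
        rng = np.random.default_rng(3)
        static = small_traj.coords_nm[0]
        frames = []
        for _ in range(10):
            rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
            frames.append(static @ rot.as_matrix().T + rng.normal(size=3))
        traj = Trajectory(small_traj.topology, np.arange(10.0), np.array(frames))
        aligned = align_trajectory(traj, 0, "name CA")
        rmsds = rmsd_series(aligned, 0, "name CA")
        assert rmsds.max() < 1e-6

    def test_idempotent(self, small_traj):
        once = align_trajectory(small_traj, 0, "name CA")
        twice = align_trajectory(once, 0, "name CA")
        assert np.abs(twice.coords_nm - once.coords_nm).max() < 1e-9

    def test_mean_structure_near_generator_reference(self):
        from pdzdyn.synthetic import build_toy_topology

        spec = SyntheticSpec(seed=4, n_frames=4000, dt_ns=0.5, sigma_nm=0.02)
        _, ref = build_toy_topology(spec)
        traj = generate_trajectory(spec)
        aligned = align_trajectory(traj, ref, "name CA")
        mean = aligned.coords_nm.mean(axis=0)
        # per-atom mean within a few SE of the reference (sigma/sqrt(n_eff))
        assert np.abs(mean - ref).max() < 5 * 0.02 / np.sqrt(4000 * 0.5 / (2 * 1.0))

    def test_selection_too_small_rejected(self, small_traj):
        with pytest.raises(DegenerateGeometryError):
            align_trajectory(small_traj, 0, "resid 264 and name CA")


class TestRMSF:
    def test_static_trajectory_is_zero(self, toy_topology, small_traj):
        static = np.repeat(small_traj.coords_nm[:1], 5, axis=0)
        traj = Trajectory(toy_topology, np.arange(5.0), static, aligned=True)
        prof = compute_rmsf(traj)
        assert np.allclose(prof.rmsf_nm, 0.0)

    def test_two_point_alternation_gives_amplitude(self, toy_topology, small_traj):
        d = 0.07
        coords = np.repeat(small_traj.coords_nm[:1], 4, axis=0)
        ca0 = resolve_selection("name CA", toy_topology)[0]
        coords[::2, ca0, 0] += d
        coords[1::2, ca0, 0] -= d
        traj = Trajectory(toy_topology, np.arange(4.0), coords, aligned=True)
        prof = compute_rmsf(traj)
        assert np.isclose(prof.rmsf_nm[0], d, atol=1e-12)

    def test_unaligned_rejected_without_override(self, small_traj):
        with pytest.raises(ValueError, match="not aligned"):
            compute_rmsf(small_traj)
        compute_rmsf(small_traj, allow_unaligned=True)  # explicit override works

    def test_ou_recovery_and_rigid_motion_invariance(self):
        """RMSF -> sqrt(3)*sigma, and is invariant to a global rigid move."""
        spec = SyntheticSpec(seed=5, n_frames=30000, dt_ns=0.5, sigma_nm=0.05, ca_only=True)
        traj = generate_trajectory(spec)
        prof = compute_rmsf(align_trajectory(traj, 0, "name CA"))
        expected = np.sqrt(3.0) * 0.05
        assert np.abs(prof.rmsf_nm / expected - 1.0).max() < 0.05

        rot = Rotation.from_euler("xyz", [10, 60, -30], degrees=True).as_matrix()
        moved = Trajectory(traj.topology, traj.times_ns,
                           traj.coords_nm @ rot.T + np.array([1.0, -2.0, 0.5]))
        prof2 = compute_rmsf(align_trajectory(moved, 0, "name CA"))
        assert np.abs(prof2.rmsf_nm - prof.rmsf_nm).max() < 1e-9


class TestReplicaCombination:
    def test_identical_replicas_zero_std_any_k(self):
        base = RMSFProfile([1, 2, 3], [0.1, 0.2, 0.3])
        for k in (2, 3, 5):
            comb = combine_replicas([base] * k)
            assert np.allclose(comb.rmsf_nm, base.rmsf_nm)
            assert np.allclose(comb.std_nm, 0.0)
            assert comb.n_replicas == k

    def test_mean_and_sample_std(self):
        comb = combine_replicas([RMSFProfile([1], [0.1]), RMSFProfile([1], [0.3])])
        assert np.isclose(comb.rmsf_nm[0], 0.2)
        assert np.isclose(comb.std_nm[0], 0.1414, atol=1e-4)  # n-1 convention

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            combine_replicas([RMSFProfile([1], [0.1]), RMSFProfile([2], [0.1])])


class TestDeltaRMSF:
    def test_self_difference_is_zero_and_antisymmetric(self):
        rng = np.random.default_rng(6)
        a = RMSFProfile(np.arange(10), rng.uniform(0.05, 0.3, 10))
        b = RMSFProfile(np.arange(10), rng.uniform(0.05, 0.3, 10))
        assert np.allclose(delta_rmsf(a, a).delta_nm, 0.0)
        assert np.allclose(delta_rmsf(a, b).delta_nm, -delta_rmsf(b, a).delta_nm)

    def test_planted_loop_amplification_recovered(self):
        """Variant with doubled loop sigma shows Delta > 0 exactly there."""
        loop = range(264, 278)
        wt_spec = SyntheticSpec(seed=7, n_frames=20000, dt_ns=0.5, sigma_nm=0.03, ca_only=True)
        var_spec = SyntheticSpec(seed=8, n_frames=20000, dt_ns=0.5, sigma_nm=0.03,
                                 sigma_overrides={r: 0.06 for r in loop}, ca_only=True)
        profs = {}
        for name, spec in (("wt", wt_spec), ("var", var_spec)):
            traj = generate_trajectory(spec)
            profs[name] = compute_rmsf(align_trajectory(traj, 0, "name CA"))
        d = delta_rmsf(profs["var"], profs["wt"])
        in_loop = np.isin(d.residue_numbers, list(loop))
        # planted effect: sqrt(3)*(0.06-0.03) ~ 0.052 nm
        assert np.all(d.delta_nm[in_loop] > 0.03)
        assert np.abs(d.delta_nm[~in_loop]).max() < 0.02

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            delta_rmsf(RMSFProfile([1], [0.1]), RMSFProfile([2], [0.1]))


class TestRMSDSeriesAndClustering:
    def test_reference_frame_zero(self, small_traj):
        series = rmsd_series(small_traj, 0, "name CA")
        assert series[0] < 1e-12
        assert np.all(series >= 0)

    def test_identical_frames_single_cluster(self, toy_topology, small_traj):
        static = np.repeat(small_traj.coords_nm[:1], 8, axis=0)
        traj = Trajectory(toy_topology, np.arange(8.0), static, aligned=True)
        res = cluster_conformations(traj, "name CA", 0.15)
        assert res.n_clusters == 1
        assert np.all(res.frame_labels == 0)

    def test_huge_cutoff_single_cluster(self, small_traj):
        res = cluster_conformations(small_traj, "name CA", 100.0)
        assert res.n_clusters == 1

    @staticmethod
    def _three_conformer_traj(order, seed=9):
        """30 frames in 3 loop conformations separated by >> cutoff."""
        spec = SyntheticSpec(seed=seed, n_frames=30, dt_ns=1.0, sigma_nm=0.0)
        traj = generate_trajectory(spec)
        sel = resolve_selection("resid 264-277 and name CA", traj.topology)
        offsets = {0: np.zeros(3), 1: np.array([1.2, 0, 0]), 2: np.array([0, 1.8, 0])}
        coords = traj.coords_nm.copy()
        for f, conf in enumerate(order):
            coords[f][sel] += offsets[conf]
        return Trajectory(traj.topology, traj.times_ns, coords, aligned=True), order

    def test_three_planted_conformers_recovered(self):
        order = [0] * 14 + [1] * 10 + [2] * 6
        traj, truth = self._three_conformer_traj(order)
        res = cluster_conformations(traj, "resid 264-277 and name CA", 0.15)
        assert res.n_clusters == 3
        # labels ordered by size: conformer 0 (14 frames) -> cluster 0, etc.
        assert np.array_equal(res.frame_labels, truth)
        for cid, medoid in enumerate(res.medoid_frames):
            assert res.frame_labels[medoid] == cid

    def test_membership_stable_under_frame_permutation(self):
        order = [0] * 14 + [1] * 10 + [2] * 6
        traj, truth = self._three_conformer_traj(order)
        rng = np.random.default_rng(10)
        perm = rng.permutation(30)
        shuffled = Trajectory(traj.topology, traj.times_ns,
                              traj.coords_nm[perm], aligned=True)
        res = cluster_conformations(shuffled, "resid 264-277 and name CA", 0.15)
        # memberships must match the permuted truth up to label renaming
        truth_perm = np.array(truth)[perm]
        mapping = {}
        for lab, tr in zip(res.frame_labels, truth_perm):
            mapping.setdefault(lab, tr)
            assert mapping[lab] == tr


class TestConvergence:
    def test_identical_replicas(self):
        p = RMSFProfile([1, 2], [0.1, 0.2])
        res = convergence_check([p, p])
        assert res["max_abs_diff_nm"] == 0.0
        assert res["pearson_r"] == 1.0

    def test_anticorrelated_profiles(self):
        res = convergence_check([RMSFProfile([1, 2], [0.1, 0.2]),
                                 RMSFProfile([1, 2], [0.2, 0.1])])
        assert np.isclose(res["pearson_r"], -1.0)

    def test_independent_ou_replicas_converge(self):
        profs = []
        for seed in (21, 22):
            spec = SyntheticSpec(seed=seed, n_frames=30000, dt_ns=0.5,
                                 sigma_nm=0.05, ca_only=True)
            traj = generate_trajectory(spec)
            profs.append(compute_rmsf(align_trajectory(traj, 0, "name CA")))
        res = convergence_check(profs)
        assert res["max_abs_diff_nm"] < 0.01  # ~ sqrt(3)*sigma * O(1/sqrt(n_eff))
        assert res["pearson_r"] > -1.0  # flat truth: r is uninformative, diff is the check
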