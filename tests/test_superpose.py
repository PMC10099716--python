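"""Kabsch superposition against a quaternion oracle; RMSD distributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bafdyn as b
from bafdyn.superpose import DegenerateGeometryError, EmptyDataError
from bafdyn.synthetic import core_ranges


def quaternion_superpose_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Independent oracle: Horn's closed-form quaternion solution.

    Builds the 4x4 key matrix from the correlation of the centred point sets;
    its largest eigenvalue lambda_max gives the minimal residual directly:
    e^2 = (|P|^2 + |Q|^2 - 2 lambda_max) / N.
    """
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    sxx, sxy, sxz = (p[:, 0] * q[:, 0]).sum(), (p[:, 0] * q[:, 1]).sum(), (p[:, 0] * q[:, 2]).sum()
    syx, syy, syz = (p[:, 1] * q[:, 0]).sum(), (p[:, 1] * q[:, 1]).sum(), (p[:, 1] * q[:, 2]).sum()
    szx, szy, szz = (p[:, 2] * q[:, 0]).sum(), (p[:, 2] * q[:, 1]).sum(), (p[:, 2] * q[:, 2]).sum()
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    e2 = ((p**2).sum() + (q**2).sum() - 2.0 * lam) / len(p)
    return float(np.sqrt(max(e2, 0.0)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.normal(size=(10, 3))
        res = b.kabsch_superpose(pts, pts)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-12)
        assert res.core_rmsd < 1e-12

    def test_exact_recovery_of_rigid_motion(self, rng):
        pts = rng.normal(size=(12, 3))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pts @ rot90.T + np.array([1.0, 2.0, 3.0])
        res = b.kabsch_superpose(moved, pts)
        assert res.core_rmsd < 1e-10
        np.testing.assert_allclose(res.apply(moved), pts, atol=1e-10)

    def test_rotation_is_proper(self, rng):
        for _ in range(20):
            mobile = rng.normal(size=(5, 3))
            target = rng.normal(size=(5, 3))
            res = b.kabsch_superpose(mobile, target)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
            np.testing.assert_allclose(
                res.rotation @ res.rotation.T, np.eye(3), atol=1e-10
            )

    def test_matches_quaternion_oracle_on_perturbed_sets(self, rng):
        for _ in range(50):
            target = rng.normal(size=(10, 3))
            mobile = (
                target @ random_rotation(rng).T
                + rng.normal(size=3)
                + rng.normal(0, 0.5, size=(10, 3))
            )
            ours = b.kabsch_superpose(mobile, target).core_rmsd
            oracle = quaternion_superpose_rmsd(mobile, target)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_superposed_rmsd_never_exceeds_raw(self, rng):
        for _ in range(50):
            mobile = rng.normal(size=(8, 3))
            target = rng.normal(size=(8, 3))
            assert b.kabsch_superpose(mobile, target).core_rmsd <= b.rmsd(mobile, target) + 1e-12

    def test_mass_weighted_fit_prioritizes_heavy_atoms(self, rng):
        target = rng.normal(size=(6, 3))
        mobile = target + rng.normal(0, 1.0, size=(6, 3))
        w = np.array([100.0, 1, 1, 1, 1, 1])
        res = b.kabsch_superpose(mobile, target, weights=w)
        moved = res.apply(mobile)
        unweighted = b.kabsch_superpose(mobile, target).apply(mobile)
        assert np.linalg.norm(moved[0] - target[0]) <= np.linalg.norm(unweighted[0] - target[0])

    def test_degenerate_geometry_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            b.kabsch_superpose(line, line + 1.0)
        with pytest.raises(DegenerateGeometryError):
            b.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRegionRmsd:
    def test_zero_for_reference_frames(self, toy_dimer, toy_core):
        traj = b.TrajectoryEnsemble(toy_dimer, np.stack([toy_dimer.coords] * 3))
        vals = b.pooled_monomer_rmsd(
            traj, toy_dimer, toy_core, (5, 12), equilibration_fraction=0.0
        )
        np.testing.assert_allclose(vals, 0.0, atol=1e-10)

    def test_rigid_region_shift_measured_exactly(self, toy_dimer, toy_core):
        frame = toy_dimer.coords.copy()
        arm = [
            i
            for i, a in enumerate(toy_dimer.atoms)
            if a.chain_id == "A" and 5 <= a.residue_number <= 12
        ]
        frame[arm] += np.array([2.0, 0.0, 0.0])
        traj = b.TrajectoryEnsemble(toy_dimer, frame[None])
        core = [b.RegionSpec(f"c{i}", "A", r) for i, r in enumerate(toy_core)]
        vals = b.region_rmsd_series(
            traj, toy_dimer, core, b.RegionSpec("h1", "A", (5, 12))
        )
        assert vals[0] == pytest.approx(2.0, abs=1e-9)

    def test_invariant_to_rigid_motion_of_whole_frame(self, toy_dimer, toy_core, rng):
        traj = b.sample_ensemble(toy_dimer, b.restricted_recipe(n_frames=3, seed=3))
        rot = random_rotation(rng)
        moved = b.TrajectoryEnsemble(
            toy_dimer, traj.frames @ rot.T + np.array([5.0, -3.0, 8.0])
        )
        core = [b.RegionSpec(f"c{i}", "A", r) for i, r in enumerate(toy_core)]
        region = b.RegionSpec("h1", "A", (5, 12))
        ref_vals = b.region_rmsd_series(traj, toy_dimer, core, region)
        moved_vals = b.region_rmsd_series(moved, toy_dimer, core, region)
        np.testing.assert_allclose(moved_vals, ref_vals, atol=1e-9)

    def test_restricted_median_near_basin_center(self, toy_dimer, toy_core):
        traj = b.sample_ensemble(toy_dimer, b.restricted_recipe(n_frames=6000, seed=1))
        vals = b.pooled_monomer_rmsd(traj, toy_dimer, toy_core, (5, 12))
        assert np.median(vals) == pytest.approx(3.0, abs=0.15)


class TestMakeDistribution:
    def test_bimodal_sample_two_modes(self, rng):
        vals = np.concatenate(
            [rng.normal(3.0, 0.4, 3000), rng.normal(5.0, 0.4, 3000)]
        )
        dist = b.make_distribution(vals)
        assert dist.n_modes == 2
        assert dist.modes[0][0] == pytest.approx(3.0, abs=0.2)
        assert dist.modes[1][0] == pytest.approx(5.0, abs=0.2)

    def test_unimodal_sample_one_mode(self, rng):
        dist = b.make_distribution(rng.normal(3.0, 0.4, 6000))
        assert dist.n_modes == 1
        assert dist.modes[0][0] == pytest.approx(3.0, abs=0.2)

    def test_constant_sample(self):
        dist = b.make_distribution(np.full(100, 2.5))
        assert dist.median == pytest.approx(2.5)
        assert dist.n_modes == 1
        assert dist.modes[0][0] == pytest.approx(2.5)

    def test_density_integrates_to_one(self, rng):
        dist = b.make_distribution(rng.normal(3.0, 0.5, 2000))
        area = np.sum(dist.density * np.diff(dist.bin_edges))
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_median_is_50th_percentile(self, rng):
        vals = rng.exponential(2.0, 999)
        dist = b.make_distribution(vals)
        assert dist.median == pytest.approx(np.percentile(vals, 50))

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyDataError):
            b.make_distribution(np.array([1.0]))

    @settings(max_examples=25, deadline=None)
    @given(
        center=st.floats(1.0, 8.0),
        sigma=st.floats(0.2, 1.0),
        seed=st.integers(0, 2**20),
    )
    def test_mode_recovery_property(self, center, sigma, seed):
        """KDE mode detection recovers a Gaussian location within half a sigma."""
        vals = np.random.default_rng(seed).normal(center, sigma, 4000)
        dist = b.make_distribution(vals)
        best = min(dist.modes, key=lambda m: abs(m[0] - center))
        assert abs(best[0] - center) < 0.5 * sigma
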