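"""Geometry primitives, circular medians, RMSF, and descriptor assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from opsintune.descriptors import (ANGLE_SPECS, Trajectory, angle_series_median,
                                   bond_angle, circular_median,
                                   compute_descriptors, dihedral,
                                   read_trajectory_pdb, read_trajectory_tsv,
                                   rmsf_auc, rmsf_per_atom,
                                   write_trajectory_pdb, write_trajectory_tsv)
from opsintune.synthetic import TrajectoryRecipe, base_scaffold, make_trajectory

finite_point = st.tuples(*[st.floats(-10, 10) for _ in range(3)])


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == \
            pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == \
            pytest.approx(180.0)

    def test_fixed_sign_convention(self):
        """Hand-computed oracle: normals n1=(0,0,1), n2=(1,0,0) about the
        axis (0,1,0) give a quarter turn whose sign is fixed at -90."""
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)) == \
            pytest.approx(-90.0)

    def test_collinear_triple_errors(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_reversal_preserves_and_mirror_negates(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(4, 3))
            d = dihedral(*pts)
            assert dihedral(*pts[::-1]) == pytest.approx(d, abs=1e-9)
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            assert dihedral(*mirrored) == pytest.approx(-d, abs=1e-9) or \
                (abs(d) == pytest.approx(180.0, abs=1e-9))

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(4, 3))
        d = dihedral(*pts)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        moved = rot.apply(pts) + np.array([5.0, -2.0, 9.0])
        assert dihedral(*moved) == pytest.approx(d, abs=1e-9)


class TestBondAngle:
    def test_collinear_is_180(self):
        assert bond_angle((0, 0, 0), (1, 0, 0), (2, 0, 0)) == \
            pytest.approx(180.0)

    def test_right_angle(self):
        assert bond_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == \
            pytest.approx(90.0)

    def test_law_of_cosines_oracle(self, rng):
        """Independent oracle: angle from the side lengths via the law of
        cosines agrees to 1e-9 degrees."""
        for _ in range(20):
            p1, p2, p3 = rng.normal(size=(3, 3)) * 3
            a = np.linalg.norm(p1 - p2)
            b = np.linalg.norm(p3 - p2)
            c = np.linalg.norm(p1 - p3)
            expected = np.degrees(
                np.arccos(np.clip((a * a + b * b - c * c) / (2 * a * b),
                                  -1, 1)))
            assert bond_angle(p1, p2, p3) == pytest.approx(expected,
                                                           abs=1e-9)

    def test_zero_length_vector_errors(self):
        with pytest.raises(ValueError, match="zero-length"):
            bond_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


class TestCircularMedian:
    def test_wrap_straddling_series_gives_180(self):
        values = np.array([179.0, -179.0] * 10)
        assert circular_median(values) == pytest.approx(180.0)

    def test_plain_series_matches_ordinary_median(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        assert circular_median(values) == pytest.approx(3.0)

    @given(st.floats(-179, 179), st.integers(0, 2**31 - 1))
    def test_wrapped_normal_location_recovery(self, mu, seed):
        rng = np.random.default_rng(seed)
        draws = (rng.normal(mu, 10.0, size=5000) + 180.0) % 360.0 - 180.0
        assert abs(circular_median(draws) - mu) < 0.5 or \
            abs(abs(circular_median(draws) - mu) - 360.0) < 0.5


class TestAngleSeriesMedian:
    def test_constant_series_returns_the_value(self):
        recipe = TrajectoryRecipe(n_frames=3,
                                  dihedral_targets={"torsion15": (3.64, 0.0)})
        traj, _ = make_trajectory(recipe)
        assert angle_series_median(traj, "torsion15") == \
            pytest.approx(3.64, abs=1e-9)

    def test_alternating_wrap_series(self):
        base = base_scaffold()
        t_plus, _ = make_trajectory(TrajectoryRecipe(
            n_frames=2, dihedral_targets={"torsion15": (179.0, 0.0)}))
        t_minus, _ = make_trajectory(TrajectoryRecipe(
            n_frames=2, dihedral_targets={"torsion15": (-179.0, 0.0)}))
        coords = np.concatenate([t_plus.coords, t_minus.coords] * 3)
        traj = Trajectory(atoms=base.atoms, coords=coords)
        assert angle_series_median(traj, "torsion15") == pytest.approx(
            180.0, abs=1e-6)

    def test_location_recovery_from_wrapped_normal(self):
        recipe = TrajectoryRecipe(
            n_frames=5000, dihedral_targets={"torsion3": (-171.0, 10.0)},
            seed=42)
        traj, _ = make_trajectory(recipe)
        assert angle_series_median(traj, "torsion3") == pytest.approx(
            -171.0, abs=0.5)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        base = base_scaffold()
        traj = Trajectory(atoms=base.atoms,
                          coords=np.repeat(base.coords, 5, axis=0))
        assert rmsf_per_atom(traj).max() < 1e-12

    def test_rigid_motion_removed_by_superposition(self):
        traj, _ = make_trajectory(TrajectoryRecipe(
            n_frames=40, global_motion="random", seed=9))
        assert rmsf_per_atom(traj).max() < 1e-10

    def test_isotropic_jitter_closed_form(self):
        """sigma=0.2 A per axis gives per-atom RMSF near 0.2*sqrt(3),
        slightly reduced by the 6 rigid degrees of freedom the fit
        removes; the linearized expectation tracks it within 1%."""
        traj, gt = make_trajectory(TrajectoryRecipe(
            n_frames=5000, jitter_sigma=0.2, seed=17))
        per_atom = rmsf_per_atom(traj)
        assert per_atom.mean() == pytest.approx(0.2 * np.sqrt(3), rel=0.05)
        expected = np.array(gt["expected_rmsf_per_atom"])
        assert np.allclose(per_atom, expected, atol=0.01)

    def test_superposition_against_mdanalysis(self):
        """Independent cross-check: MDAnalysis computes the same RMSF on
        the same pre-aligned ensemble."""
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rms import RMSF
        from MDAnalysis.coordinates.memory import MemoryReader

        traj, _ = make_trajectory(TrajectoryRecipe(
            n_frames=200, jitter_sigma=0.1, seed=3))
        u = mda.Universe.empty(len(traj.atoms), trajectory=True)
        from opsintune.descriptors import _superpose

        ref = traj.coords.mean(axis=0)
        for _ in range(3):
            fitted = _superpose(traj.coords, ref)
            ref = fitted.mean(axis=0)
        u.load_new(fitted.astype(np.float32), format=MemoryReader)
        ours = rmsf_per_atom(traj)
        theirs = RMSF(u.atoms).run().results.rmsf
        assert np.allclose(ours, theirs, atol=1e-4)

    def test_single_frame_rejected(self):
        base = base_scaffold()
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_per_atom(base)

    def test_degenerate_reference_rejected(self):
        traj = Trajectory(atoms=("A", "B"),
                          coords=np.zeros((3, 2, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            rmsf_per_atom(traj, reference=np.zeros((2, 3)))


class TestRmsfAuc:
    def test_constant_profile_rectangle(self):
        assert rmsf_auc(np.full(10, 0.5)) == pytest.approx(0.5 * 9)

    def test_triangular_profile(self):
        assert rmsf_auc(np.array([0.0, 1.0, 0.0])) == pytest.approx(1.0)

    def test_single_atom_rejected(self):
        with pytest.raises(ValueError, match="2 atoms"):
            rmsf_auc(np.array([1.0]))

    def test_scales_linearly_with_amplitude(self):
        t1, _ = make_trajectory(TrajectoryRecipe(n_frames=2000,
                                                 jitter_sigma=0.1, seed=5))
        t2, _ = make_trajectory(TrajectoryRecipe(n_frames=2000,
                                                 jitter_sigma=0.2, seed=5))
        a1 = rmsf_auc(rmsf_per_atom(t1))
        a2 = rmsf_auc(rmsf_per_atom(t2))
        assert a2 / a1 == pytest.approx(2.0, rel=0.03)


class TestComputeDescriptors:
    def test_static_duplicated_frame(self):
        base = base_scaffold()
        traj = Trajectory(atoms=base.atoms,
                          coords=np.repeat(base.coords, 3, axis=0))
        d = compute_descriptors(traj, "static")
        assert d.rmsf_auc == pytest.approx(0.0, abs=1e-10)
        assert d.torsion15_median == pytest.approx(
            angle_series_median(base, "torsion15"))

    def test_descriptors_invariant_under_global_rigid_motion(self, rng):
        traj, _ = make_trajectory(TrajectoryRecipe(
            n_frames=100, jitter_sigma=0.05, seed=21))
        d0 = compute_descriptors(traj)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5])
        moved = Trajectory(
            atoms=traj.atoms,
            coords=np.array([rot.apply(f) + [3.0, -7.0, 1.0]
                             for f in traj.coords]))
        d1 = compute_descriptors(moved)
        assert d1.torsion15_median == pytest.approx(d0.torsion15_median,
                                                    abs=1e-6)
        assert d1.rmsf_auc == pytest.approx(d0.rmsf_auc, abs=1e-6)

    def test_missing_atom_named_in_error(self):
        traj = Trajectory(atoms=("C1", "C2", "C3"),
                          coords=np.zeros((2, 3, 3)))
        with pytest.raises(ValueError, match="C13"):
            compute_descriptors(traj)


class TestTrajectoryIO:
    def test_tsv_roundtrip_exact(self, tmp_path):
        traj, _ = make_trajectory(TrajectoryRecipe(n_frames=4,
                                                   jitter_sigma=0.1, seed=1))
        p = tmp_path / "t.tsv"
        write_trajectory_tsv(traj, p)
        back = read_trajectory_tsv(p)
        assert back.atoms == traj.atoms
        assert np.allclose(back.coords, traj.coords, atol=1e-6)

    def test_pdb_roundtrip(self, tmp_path):
        traj, _ = make_trajectory(TrajectoryRecipe(n_frames=3,
                                                   jitter_sigma=0.1, seed=2))
        p = tmp_path / "t.pdb"
        write_trajectory_pdb(traj, p)
        back = read_trajectory_pdb(p)
        assert back.n_frames == 3
        assert set(back.atoms) == set(traj.atoms)
        assert np.allclose(back.coords, traj.coords, atol=2e-3)
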