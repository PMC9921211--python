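"""Superposition, RMSD/RMSF/RoG, H-bonds, distances, PCA and FEL."""

import math

import numpy as np
import pandas as pd
import pytest

from screenmd import (
    TrajSimSpec,
    atomic_rmsf,
    com_distance_series,
    free_energy_landscape,
    hbond_count_series,
    make_reference_coords,
    min_distance_series,
    pca,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    rog_series,
    simulate_trajectory,
    superpose,
)
from screenmd.errors import DegenerateFitError
from screenmd.md_analysis import BOLTZMANN_KCAL

from conftest import make_atoms, make_trajectory, random_rotation


def oracle_fit_rmsd(mobile, reference):
    """Independent rigid-fit RMSD via scipy's vector alignment."""
    from scipy.spatial.transform import Rotation

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return float(np.sqrt(((rot.apply(mob_c) - ref_c) ** 2).sum(axis=1).mean()))


class TestSuperpose:
    def test_identical_frames_zero(self, five_atom_frame):
        _, rmsd = superpose(five_atom_frame, five_atom_frame)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_removed(self, five_atom_frame):
        rot_z = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = five_atom_frame @ rot_z.T + np.array([5.0, -3.0, 2.0])
        _, rmsd = superpose(moved, five_atom_frame)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_two_atom_translation_only_fit(self):
        mobile = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        reference = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        _, rmsd = superpose(mobile, reference, rotate=False)
        assert rmsd == pytest.approx(1.0)

    def test_rotational_fit_needs_three_atoms(self):
        two = np.zeros((2, 3))
        with pytest.raises(DegenerateFitError):
            superpose(two, two)

    def test_collinear_atoms_degenerate(self):
        line = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        with pytest.raises(DegenerateFitError):
            superpose(line, line)

    def test_agrees_with_alignment_oracle(self, five_atom_frame):
        rng = np.random.default_rng(0)
        for _ in range(10):
            other = five_atom_frame + rng.normal(0, 0.5, five_atom_frame.shape)
            _, rmsd = superpose(other, five_atom_frame)
            assert rmsd == pytest.approx(oracle_fit_rmsd(other, five_atom_frame), abs=1e-8)


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self, five_atom_frame):
        traj = make_trajectory(np.repeat(five_atom_frame[None], 4, axis=0))
        assert rmsd_series(traj) == pytest.approx(np.zeros(4), abs=1e-12)

    def test_per_frame_rigid_rotation_all_zero(self, five_atom_frame):
        rng = np.random.default_rng(1)
        frames = [five_atom_frame]
        for _ in range(5):
            frames.append(five_atom_frame @ random_rotation(rng).T + rng.normal(size=3))
        traj = make_trajectory(np.array(frames))
        assert np.allclose(rmsd_series(traj), 0.0, atol=1e-10)

    def test_displaced_atom_matches_oracle(self, five_atom_frame):
        displaced = five_atom_frame.copy()
        displaced[4] += [0.0, 0.0, 2.0]
        traj = make_trajectory(np.array([five_atom_frame, displaced]))
        series = rmsd_series(traj)
        assert series[0] == pytest.approx(0.0, abs=1e-12)
        assert series[1] == pytest.approx(oracle_fit_rmsd(displaced, five_atom_frame), abs=1e-8)


class TestRigidInvariance:
    def test_rmsd_rog_rmsf_invariant_under_global_transform(self):
        """One rigid transform applied to every frame changes nothing."""
        traj = simulate_trajectory(
            TrajSimSpec(reference=make_reference_coords(12, seed=2), n_frames=40,
                        amplitude=0.8, mode="gaussian", seed=2)
        )
        rng = np.random.default_rng(3)
        rot, shift = random_rotation(rng), rng.normal(0, 20, 3)
        moved = make_trajectory(traj.coords @ rot.T + shift, atoms=traj.atoms.copy())
        assert np.max(np.abs(rmsd_series(moved) - rmsd_series(traj))) < 1e-8
        assert np.max(np.abs(rog_series(moved) - rog_series(traj))) < 1e-8
        assert np.max(np.abs(atomic_rmsf(moved) - atomic_rmsf(traj))) < 1e-8


class TestRmsf:
    def test_static_trajectory_zero(self, five_atom_frame):
        traj = make_trajectory(np.repeat(five_atom_frame[None], 3, axis=0))
        assert atomic_rmsf(traj, superpose_first=False) == pytest.approx(
            np.zeros(5), abs=1e-12
        )

    def test_single_frame_rejected(self, five_atom_frame):
        traj = make_trajectory(five_atom_frame[None])
        with pytest.raises(ValueError):
            atomic_rmsf(traj)

    def test_sinusoid_amplitude_recovery(self):
        """A densely sampled a·sin(ωt) oscillation has RMSF a/√2."""
        n_frames, amplitude = 2000, 1.3
        t = np.arange(n_frames)
        coords = np.zeros((n_frames, 1, 3))
        coords[:, 0, 0] = amplitude * np.sin(2 * np.pi * 5 * t / n_frames)
        traj = make_trajectory(coords)
        value = atomic_rmsf(traj, superpose_first=False)[0]
        assert value == pytest.approx(amplitude / math.sqrt(2), rel=0.02)

    def test_gaussian_jitter_recovery(self):
        """Isotropic per-axis σ jitter has RMSF σ√3 (chi-square mean)."""
        sigma, n_frames = 0.5, 4000
        traj = simulate_trajectory(
            TrajSimSpec(reference=make_reference_coords(10, seed=4), n_frames=n_frames,
                        amplitude=sigma, mode="gaussian", seed=4)
        )
        values = atomic_rmsf(traj, superpose_first=False)
        # mean-square concentrates: s.e. of rmsf ≈ σ√3 / √(2·3·n)
        se = sigma * math.sqrt(3) / math.sqrt(2 * 3 * n_frames)
        assert np.all(np.abs(values - sigma * math.sqrt(3)) < 3 * se * math.sqrt(10))

    def test_per_residue_uses_calpha_for_protein(self):
        atoms = pd.concat(
            [make_atoms(2), make_atoms(2, name="CB")], ignore_index=True
        )
        atoms.loc[2:, "resid"] = [1, 2]
        coords = np.zeros((50, 4, 3))
        rng = np.random.default_rng(5)
        coords[:, 2, 0] = rng.normal(0, 2.0, 50)  # CB of residue 1 moves
        coords[:, :, :] += rng.normal(0, 1e-9, coords.shape)
        traj = make_trajectory(coords, atoms=atoms)
        series = rmsf(traj, superpose_first=False)
        # residue values come from the static CA atoms, not the mobile CB
        assert series.loc[1] < 0.1

    def test_ligand_residue_averages_over_atoms(self):
        atoms = make_atoms(2, segment="ligand", name="C1", element="C")
        atoms["resid"] = [9, 9]
        coords = np.zeros((100, 2, 3))
        coords[:, 0, 0] = np.sin(np.linspace(0, 10 * np.pi, 100))
        traj = make_trajectory(coords, atoms=atoms)
        series = rmsf(traj, superpose_first=False)
        expected = atomic_rmsf(traj, superpose_first=False).mean()
        assert series.loc[9] == pytest.approx(expected)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_unit_masses(self):
        frame = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        assert radius_of_gyration(frame, mass_weighted=False) == pytest.approx(2.0)

    def test_square_of_side_s(self):
        s = 3.0
        frame = np.array([[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]], dtype=float)
        assert radius_of_gyration(frame, mass_weighted=False) == pytest.approx(
            s / math.sqrt(2)
        )

    def test_mass_weighting_shifts_com(self):
        frame = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        masses = np.array([3.0, 1.0])
        com = 0.25  # (3·0 + 1·1)/4
        expected = math.sqrt((3 * com**2 + 1 * (1 - com) ** 2) / 4)
        assert radius_of_gyration(frame, masses) == pytest.approx(expected)


def hbond_system(o_o_distance, angle_deg=180.0):
    """O–H···O geometry: donor O at origin, H on +x, acceptor placed at the
    requested O···O distance with the requested D–H···A angle."""
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    theta = math.radians(180.0 - angle_deg)  # deviation of HA from the DH extension
    ha_dir = np.array([math.cos(theta), math.sin(theta), 0.0])
    # place acceptor along ha_dir from H such that |D−A| = o_o_distance
    # solve |h + L·ha_dir| = o_o_distance for L > 0
    b = 2 * (h @ ha_dir)
    c = h @ h - o_o_distance**2
    length = (-b + math.sqrt(b**2 - 4 * c)) / 2
    a = h + length * ha_dir
    coords = np.array([[d, h, a]])
    atoms = pd.DataFrame(
        {
            "name": ["O1", "H1", "O2"],
            "element": ["O", "H", "O"],
            "mass": [15.999, 1.008, 15.999],
            "resid": [1, 1, 2],
            "resname": ["LIG", "LIG", "RES"],
            "chain": ["A", "A", "A"],
            "segment": ["ligand", "ligand", "protein"],
        }
    )
    return make_trajectory(coords, atoms=atoms)


class TestHbonds:
    def test_linear_geometry_counts_one(self):
        traj = hbond_system(2.8, angle_deg=180.0)
        counts = hbond_count_series(traj, "name O1", "name O2")
        assert counts.tolist() == [1]

    def test_beyond_distance_cutoff(self):
        traj = hbond_system(5.0, angle_deg=180.0)
        assert hbond_count_series(traj, "name O1", "name O2").tolist() == [0]

    def test_bent_angle_rejected(self):
        traj = hbond_system(2.8, angle_deg=90.0)
        assert hbond_count_series(traj, "name O1", "name O2").tolist() == [0]

    def test_angle_just_inside_cutoff_counts(self):
        traj = hbond_system(2.8, angle_deg=155.0)
        assert hbond_count_series(traj, "name O1", "name O2", angle_cut=30.0).tolist() == [1]

    def test_donor_without_hydrogen_skipped(self):
        traj = hbond_system(2.8)
        # swap roles: the acceptor O2 has no attached H, so no bonds found
        assert hbond_count_series(traj, "name O2", "name O1").tolist() == [0]


class TestDistances:
    def test_identical_selections_zero(self, five_atom_frame):
        traj = make_trajectory(five_atom_frame[None])
        assert com_distance_series(traj, "resid 1:3", "resid 1:3")[0] == pytest.approx(0.0)

    def test_unit_conversion_to_nm(self):
        coords = np.array([[[0.0, 0.0, 0.0], [7.5, 0.0, 0.0]]])
        traj = make_trajectory(coords)
        assert com_distance_series(traj, "resid 1", "resid 2")[0] == pytest.approx(0.75)

    def test_com_of_pair_vs_midpoint(self):
        coords = np.array([[[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [1.0, 0.0, 0.0]]])
        traj = make_trajectory(coords)
        assert com_distance_series(traj, "resid 1 2", "resid 3")[0] == pytest.approx(0.0)

    def test_min_distance_hand_enumerated(self):
        coords = np.array(
            [[[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [3.0, 4.0, 0.0], [6.0, 8.0, 0.0]]]
        )
        traj = make_trajectory(coords)
        # pairs: (0,2)=5, (0,3)=10, (1,2)=8.06..., (1,3)=8.94...
        assert min_distance_series(traj, "resid 1 2", "resid 3 4")[0] == pytest.approx(0.5)

    def test_min_leq_com_distance(self):
        traj = simulate_trajectory(
            TrajSimSpec(reference=make_reference_coords(10, seed=6), n_frames=5,
                        amplitude=1.0, mode="gaussian", seed=6)
        )
        com = com_distance_series(traj, "resid 1:5", "resid 6:10")
        mind = min_distance_series(traj, "resid 1:5", "resid 6:10")
        assert np.all(mind <= com + 1e-12)

    def test_overlapping_selections_zero_min(self, five_atom_frame):
        traj = make_trajectory(five_atom_frame[None])
        assert min_distance_series(traj, "resid 1:4", "resid 3:5")[0] == 0.0


class TestPca:
    def test_motion_in_one_coordinate_is_rank_one(self):
        coords = np.zeros((30, 4, 3))
        coords[:, 0, 0] = np.linspace(-1, 1, 30)
        traj = make_trajectory(coords)
        result = pca(traj, superpose_first=False)
        assert result.eigenvalues[0] > 1e-6
        assert np.all(result.eigenvalues[1:] < 1e-12)

    def test_eigenvalue_sum_equals_trace(self):
        traj = simulate_trajectory(
            TrajSimSpec(reference=make_reference_coords(8, seed=7), n_frames=60,
                        amplitude=0.7, mode="gaussian", seed=7)
        )
        result = pca(traj, superpose_first=False)
        flat = traj.coords.reshape(60, -1)
        trace = np.cov(flat.T).trace()
        assert result.eigenvalues.sum() == pytest.approx(trace, rel=1e-8)

    def test_recovers_injected_mode_variances(self):
        """Two orthogonal synthetic modes with variances 4 and 1."""
        rng = np.random.default_rng(8)
        n = 3000
        coords = np.zeros((n, 4, 3))
        coords[:, 0, 0] = rng.normal(0, 2.0, n)  # variance 4
        coords[:, 1, 1] = rng.normal(0, 1.0, n)  # variance 1
        traj = make_trajectory(coords)
        result = pca(traj, superpose_first=False)
        se1 = 4.0 * math.sqrt(2.0 / n)
        se2 = 1.0 * math.sqrt(2.0 / n)
        assert abs(result.eigenvalues[0] - 4.0) < 3 * se1
        assert abs(result.eigenvalues[1] - 1.0) < 3 * se2

    def test_projections_centered_with_eigenvalue_variance(self):
        traj = simulate_trajectory(
            TrajSimSpec(reference=make_reference_coords(6, seed=9), n_frames=80,
                        amplitude=0.5, mode="gaussian", seed=9)
        )
        result = pca(traj)
        assert np.allclose(result.projections.mean(axis=0), 0.0, atol=1e-10)
        variances = result.projections.var(axis=0, ddof=1)
        np.testing.assert_allclose(variances, result.eigenvalues, rtol=1e-8, atol=1e-12)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA

        traj = simulate_trajectory(
            TrajSimSpec(reference=make_reference_coords(5, seed=10), n_frames=50,
                        amplitude=0.6, mode="gaussian", seed=10)
        )
        result = pca(traj, superpose_first=False)
        sk = SkPCA().fit(traj.coords.reshape(50, -1))
        np.testing.assert_allclose(
            result.eigenvalues[:5], sk.explained_variance_[:5], rtol=1e-8
        )

    def test_single_frame_rejected(self, five_atom_frame):
        traj = make_trajectory(five_atom_frame[None])
        with pytest.raises(ValueError):
            pca(traj)


class TestFel:
    def test_uniform_occupancy_zero_everywhere(self):
        pc = np.array([0.25, 0.75, 0.25, 0.75])
        grid = free_energy_landscape(pc, pc[::-1], bins=2)
        occupied = grid.counts > 0
        assert np.all(grid.delta_g[occupied] == 0.0)

    def test_half_occupancy_bin_value(self):
        pc1 = np.array([0.1] * 4 + [0.9] * 2)
        pc2 = np.zeros(6)
        grid = free_energy_landscape(pc1, pc2, bins=2, temperature=300.0)
        kt = BOLTZMANN_KCAL * 300.0
        values = grid.delta_g[np.isfinite(grid.delta_g)]
        assert sorted(values) == pytest.approx([0.0, kt * math.log(2)])
        assert kt * math.log(2) == pytest.approx(0.413, abs=0.001)

    def test_empty_bins_are_infinite(self):
        grid = free_energy_landscape(
            np.array([0.0, 1.0]), np.array([0.0, 1.0]), bins=3
        )
        assert np.isinf(grid.delta_g).any()

    def test_counts_conserve_frames(self):
        rng = np.random.default_rng(11)
        pc1, pc2 = rng.normal(size=500), rng.normal(size=500)
        grid = free_energy_landscape(pc1, pc2, bins=20)
        assert grid.counts.sum() == 500

    def test_identical_frames_single_occupied_bin(self):
        pc = np.zeros(10)
        grid = free_energy_landscape(pc, pc, bins=5)
        assert (grid.counts > 0).sum() == 1
        assert grid.delta_g[grid.counts > 0][0] == 0.0

    def test_minimum_is_exactly_zero(self):
        rng = np.random.default_rng(12)
        grid = free_energy_landscape(rng.normal(size=200), rng.normal(size=200))
        assert np.min(grid.delta_g[np.isfinite(grid.delta_g)]) == 0.0
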