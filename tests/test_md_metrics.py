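"""Superposition RMSD, Daura clustering, χ1 dihedrals and hydrogen bonds,
each checked against an independent brute-force implementation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from oracles import daura_brute_force, hbond_brute_force

from quenchscan.md_metrics import (
    InterfaceSelection,
    Trajectory,
    ca_superpose_rmsd,
    chi1_angle,
    chi1_density,
    chi1_series,
    daura_cluster,
    dihedral,
    hbond_series,
    read_multimodel_pdb,
    rmsd_fit,
    superpose,
    validate_unwrapped,
    write_multimodel_pdb,
)
from quenchscan.synthetic_data import make_trajectory


def _random_rigid(rng):
    rot = Rotation.random(rng=rng)
    trans = rng.normal(0, 2.0, 3)
    return lambda x: rot.apply(x) + trans


# ---------------------------------------------------------------------------
# RMSD / superposition


class TestRmsdFit:
    def test_identical_frames_zero(self, rng):
        a = rng.normal(size=(40, 3))
        assert rmsd_fit(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, rng):
        a = rng.normal(size=(40, 3))
        b = _random_rigid(rng)(a)
        assert rmsd_fit(a, b) == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_noise_rmsd_matches_expectation(self):
        """Per-coordinate noise sd σ gives RMSD ≈ σ√3 for many atoms."""
        rng = np.random.default_rng(2)
        sigma = 0.05
        a = rng.normal(size=(500, 3))
        b = a + rng.normal(0, sigma, (500, 3))
        assert rmsd_fit(a, b) == pytest.approx(sigma * math.sqrt(3), rel=0.05)

    def test_symmetry(self, rng):
        a = rng.normal(size=(25, 3))
        b = a + rng.normal(0, 0.1, (25, 3))
        assert abs(rmsd_fit(a, b) - rmsd_fit(b, a)) < 1e-12

    def test_degenerate_configurations_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            rmsd_fit(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# Daura clustering


def _raw_trajectory(coords):
    n_atoms = coords.shape[1]
    atoms = pd.DataFrame({
        "res_id": np.arange(n_atoms), "res_name": "GLY",
        "atom_name": "CA", "chain": "A",
    })
    return Trajectory(coords=coords, atoms=atoms)


class TestDauraCluster:
    def test_identical_frames_form_one_cluster(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 8, 3)), (6, 1, 1))
        res = daura_cluster(_raw_trajectory(coords), None, cutoff=0.1)
        assert res.populations.tolist() == [1.0]
        assert np.all(res.assignments == 0)

    def test_planted_two_conformer_split(self):
        traj, manifest = make_trajectory(cluster_plan=(0.7, 0.3), n_frames=40,
                                         seed=4)
        sel = InterfaceSelection()
        res = daura_cluster(traj, sel, cutoff=0.1)
        np.testing.assert_allclose(res.populations, [0.7, 0.3], atol=1e-9)
        # frames of one planted conformer land in one recovered cluster
        planted = manifest["conformer_of_frame"]
        for conf in (0, 1):
            assert len(set(res.assignments[planted == conf])) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_frames = int(rng.integers(5, 51))
        coords = rng.normal(0, 0.045, size=(n_frames, 8, 3))
        traj = _raw_trajectory(coords)
        res = daura_cluster(traj, None, cutoff=0.1)
        ref_assign, ref_pops, ref_centers = daura_brute_force(coords, 0.1)
        np.testing.assert_array_equal(res.assignments, ref_assign)
        np.testing.assert_allclose(res.populations, ref_pops)
        np.testing.assert_array_equal(res.centers, ref_centers)

    def test_population_invariants(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(0, 0.05, size=(30, 8, 3))
        res = daura_cluster(_raw_trajectory(coords), None, cutoff=0.1)
        assert res.populations.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.populations) <= 1e-12)
        assert res.populations[0] >= 1.0 / res.populations.size
        # every frame assigned exactly once
        assert np.all(res.assignments >= 0)


# ---------------------------------------------------------------------------
# dihedrals


class TestChi1:
    @staticmethod
    def _traj_from_positions(pos):
        atoms = pd.DataFrame({
            "res_id": [500] * 4, "res_name": ["LEU"] * 4,
            "atom_name": ["N", "CA", "CB", "CG"], "chain": "A",
        })
        return Trajectory(coords=pos[None, :, :], atoms=atoms)

    def test_anti_periplanar_is_180(self):
        pos = np.array([
            [0.0, 0.1, 0.0],   # N
            [0.0, 0.0, 0.0],   # CA
            [0.15, 0.0, 0.0],  # CB
            [0.15, -0.1, 0.0],  # CG opposite side: trans
        ])
        traj = self._traj_from_positions(pos)
        assert chi1_angle(traj, 0, 500) == pytest.approx(180.0, abs=1e-9)

    def test_rotation_about_ca_cb_shifts_angle(self):
        """Rotating CG by +37° about the CA→CB axis shifts χ1 by +37°
        (rotation-matrix oracle)."""
        rng = np.random.default_rng(8)
        pos = np.array([
            [0.0, 0.12, 0.02], [0.0, 0.0, 0.0],
            [0.15, 0.01, -0.01], [0.22, -0.1, 0.08],
        ]) + rng.normal(0, 0.005, (4, 3))
        traj = self._traj_from_positions(pos)
        before = chi1_angle(traj, 0, 500)
        axis = pos[2] - pos[1]
        rot = Rotation.from_rotvec(np.deg2rad(37.0) * axis / np.linalg.norm(axis))
        pos2 = pos.copy()
        pos2[3] = rot.apply(pos[3] - pos[1]) + pos[1]
        after = chi1_angle(self._traj_from_positions(pos2), 0, 500)
        assert (after - before) % 360.0 == pytest.approx(37.0, abs=1e-6)

    def test_invariant_under_global_rigid_motion(self, rng):
        pos = np.array([
            [0.0, 0.12, 0.02], [0.0, 0.0, 0.0],
            [0.15, 0.01, -0.01], [0.22, -0.1, 0.08],
        ])
        moved = _random_rigid(rng)(pos)
        a = chi1_angle(self._traj_from_positions(pos), 0, 500)
        b = chi1_angle(self._traj_from_positions(moved), 0, 500)
        assert a == pytest.approx(b, abs=1e-9)

    def test_residue_without_gamma_rejected(self):
        atoms = pd.DataFrame({
            "res_id": [1] * 3, "res_name": ["ALA"] * 3,
            "atom_name": ["N", "CA", "CB"], "chain": "A",
        })
        traj = Trajectory(coords=np.zeros((1, 3, 3)) + np.arange(3)[None, :, None],
                          atoms=atoms)
        with pytest.raises(ValueError, match="no chi1"):
            chi1_angle(traj, 0, 1)

    def test_planted_rotamer_schedule_recovered(self):
        traj, manifest = make_trajectory(
            cluster_plan=(1.0,), n_frames=30, seed=12,
            rotamer_schedule={501: [(300.0, 0.8), (200.0, 0.2)]},
        )
        measured = chi1_series(traj, 501)
        np.testing.assert_allclose(np.sort(measured),
                                   np.sort(manifest["chi1"][501]), atol=1.0)


class TestChi1Density:
    def test_single_angle_occupies_one_bin(self):
        centers, density = chi1_density(np.full(50, 300.0), bin_width=5.0)
        assert np.count_nonzero(density) == 1
        assert np.sum(density) * 5.0 == pytest.approx(1.0)

    def test_bimodal_mass_ratio(self):
        angles = np.concatenate([np.full(80, 300.0), np.full(20, 200.0)])
        centers, density = chi1_density(angles, bin_width=5.0)
        mass300 = density[np.argmin(np.abs(centers - 302.5))]
        mass200 = density[np.argmin(np.abs(centers - 202.5))]
        assert mass300 / mass200 == pytest.approx(4.0, rel=1e-9)

    def test_uniform_angles_near_flat(self):
        rng = np.random.default_rng(9)
        angles = rng.uniform(0, 360, 100_000)
        _, density = chi1_density(angles, bin_width=5.0)
        assert np.max(np.abs(density - 1.0 / 360.0)) <= 0.1 / 360.0

    @given(st.lists(st.floats(-720.0, 720.0), min_size=1, max_size=200))
    @settings(derandomize=True, max_examples=40)
    def test_density_integrates_to_one(self, angles):
        _, density = chi1_density(np.array(angles), bin_width=5.0)
        assert np.sum(density) * 5.0 == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# hydrogen bonds


def _single_pair_traj(d, h, a):
    atoms = pd.DataFrame({
        "res_id": [1, 1, 2], "res_name": ["SER", "SER", "SER"],
        "atom_name": ["N", "H", "O"], "chain": "A",
    })
    coords = np.array([[d, h, a]])
    return Trajectory(coords=coords, atoms=atoms)


class TestHbondSeries:
    def test_ideal_linear_bond_present(self):
        traj = _single_pair_traj([0, 0, 0], [0.1, 0, 0], [0.29, 0, 0])
        series = hbond_series(traj, [(0, 1, 2)])
        assert series.occupancy[(0, 1, 2)][0]

    def test_boundary_values_inclusive(self):
        ang = math.radians(30.0)
        acceptor = [0.35 * math.cos(ang), 0.35 * math.sin(ang), 0.0]
        traj = _single_pair_traj([0, 0, 0], [0.1, 0, 0], acceptor)
        series = hbond_series(traj, [(0, 1, 2)])
        assert series.occupancy[(0, 1, 2)][0]

    def test_matches_brute_force_on_random_geometries(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            d = rng.normal(0, 0.2, 3)
            h = d + 0.1 * _unit(rng)
            a = d + rng.uniform(0.05, 0.6) * _unit(rng)
            traj = _single_pair_traj(d, h, a)
            mine = bool(hbond_series(traj, [(0, 1, 2)]).occupancy[(0, 1, 2)][0])
            assert mine == hbond_brute_force(d, h, a, 0.35, 30.0)

    def test_invariant_under_rigid_motion(self, rng):
        d, h, a = [0, 0, 0], [0.1, 0.01, 0], [0.3, 0.05, 0.02]
        move = _random_rigid(rng)
        pts = np.array([d, h, a])
        t1 = _single_pair_traj(*pts)
        t2 = _single_pair_traj(*move(pts))
        assert (hbond_series(t1, [(0, 1, 2)]).occupancy[(0, 1, 2)][0]
                == hbond_series(t2, [(0, 1, 2)]).occupancy[(0, 1, 2)][0])

    def test_planted_schedule_recovered_exactly(self):
        traj, manifest = make_trajectory(
            cluster_plan=(1.0,), n_frames=30, seed=13,
            hbond_schedule=[{"donor_res": 497, "acceptor_res": 503,
                             "frames": list(range(10, 21))}],
        )
        hb = manifest["hbonds"][0]
        series = hbond_series(traj, [(hb["donor"], hb["hydrogen"], hb["acceptor"])])
        occ = series.occupancy[(hb["donor"], hb["hydrogen"], hb["acceptor"])]
        np.testing.assert_array_equal(occ, hb["occupancy"])

    def test_empty_pair_list_gives_empty_series(self):
        traj, _ = make_trajectory(n_frames=5, seed=1)
        series = hbond_series(traj, [])
        assert series.occupancy == {}
        assert series.counts_per_frame().tolist() == [0] * 5


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# trajectory plumbing


class TestTrajectoryIO:
    def test_multimodel_pdb_round_trip(self, tmp_path):
        traj, _ = make_trajectory(cluster_plan=(0.5, 0.5), n_frames=6, seed=3)
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(traj, str(path))
        back = read_multimodel_pdb(str(path))
        assert back.n_frames == traj.n_frames
        assert back.n_atoms == traj.n_atoms
        # PDB stores 3 decimals in Angstrom: 1e-4 nm round-trip error
        np.testing.assert_allclose(back.coords, traj.coords, atol=2e-4)
        assert list(back.atoms["atom_name"]) == list(traj.atoms["atom_name"])

    def test_validate_unwrapped_rejects_broken_bonds(self):
        traj, _ = make_trajectory(n_frames=3, seed=2)
        validate_unwrapped(traj)  # intact chain passes
        bad = Trajectory(coords=traj.coords.copy(), atoms=traj.atoms)
        ca = traj.atom_indices(res_ids=[500], atom_names=["CA"])[0]
        bad.coords[1, ca] += np.array([5.0, 0.0, 0.0])  # wrapped jump
        with pytest.raises(ValueError, match="periodic"):
            validate_unwrapped(bad)

    def test_interface_selection_backbone_atoms(self):
        traj, _ = make_trajectory(n_frames=2, seed=1, n_residues=18,
                                  first_res_id=495)
        sel = InterfaceSelection(icl4_range=(1050, 1080), nbd1_range=(495, 512))
        idx = sel.backbone_indices(traj)
        sub = traj.atoms.iloc[idx]
        assert set(sub["atom_name"]) == {"N", "CA", "C"}
        assert set(sub["res_id"]) == set(range(495, 513))


class TestCaSuperposeRmsd:
    def test_rigid_copy_gives_zero(self, tmp_path, rng):
        traj, _ = make_trajectory(n_frames=1, seed=7, n_residues=20)
        moved = Trajectory(
            coords=_random_rigid(rng)(traj.coords[0])[None, :, :],
            atoms=traj.atoms,
        )
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_multimodel_pdb(traj, str(p1))
        write_multimodel_pdb(moved, str(p2))
        rmsd = ca_superpose_rmsd(str(p1), str(p2))
        assert rmsd == pytest.approx(0.0, abs=5e-3)  # Angstrom, PDB rounding

    def test_known_deformation_measured(self, tmp_path):
        rng = np.random.default_rng(31)
        traj, _ = make_trajectory(n_frames=1, seed=8, n_residues=20)
        ca_idx = traj.atom_indices(atom_names=["CA"])
        noisy = Trajectory(coords=traj.coords.copy(), atoms=traj.atoms)
        noise = rng.normal(0, 0.05, (ca_idx.size, 3))  # nm
        noisy.coords[0, ca_idx] += noise
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_multimodel_pdb(traj, str(p1))
        write_multimodel_pdb(noisy, str(p2))
        rmsd = ca_superpose_rmsd(str(p2), str(p1))
        # 0.05 nm per-coordinate sd -> ~0.87 Angstrom RMSD
        assert rmsd == pytest.approx(0.05 * math.sqrt(3) * 10, rel=0.25)
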