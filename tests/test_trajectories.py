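"""Trajectory loading and geometry kernels against brute-force oracles."""

import numpy as np
import pytest

from oxltools.structures import Atom
from oxltools.trajectories import (
    DensityGrid,
    Topology,
    Trajectory,
    dihedral_angle,
    geometric_center,
    load_trajectory,
    shell_water_counts,
    trajectory_rmsd,
    water_density_grid,
    write_multimodel_pdb,
)

from conftest import atom_line


def _toy_traj(coords, groups=None, box=None):
    n_atoms = coords.shape[1]
    atoms = [Atom("A", i + 1, "GLY", "CA", "C", coords[0, i]) for i in range(n_atoms)]
    topo = Topology(atoms=atoms)
    for label, idx in (groups or {}).items():
        topo.add_group(label, idx)
    return Trajectory(topo, coords, box=box)


class TestLoaders:
    def test_multimodel_pdb(self, tmp_path):
        lines = []
        for m in range(3):
            lines.append(f"MODEL     {m + 1:4d}")
            for i in range(5):
                lines.append(atom_line(i + 1, "CA", "GLY", "A", i + 1,
                                       float(i + m), 0.0, 0.0))
            lines.append("ENDMDL")
        lines.append("END")
        path = tmp_path / "traj.pdb"
        path.write_text("\n".join(lines) + "\n")
        traj = load_trajectory(None, path)
        assert traj.n_frames == 3
        assert traj.n_atoms == 5
        assert traj.frame(2)[0, 0] == pytest.approx(2.0)

    def test_dcd_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(4, 6, 3)) * 10.0
        traj = _toy_traj(coords)
        pdb_path = tmp_path / "top.pdb"
        write_multimodel_pdb(_toy_traj(coords[:1]), pdb_path)
        dcd_path = tmp_path / "frames.dcd"
        import MDAnalysis as mda

        u = mda.Universe(str(pdb_path))
        with mda.Writer(str(dcd_path), n_atoms=6) as w:
            for f in range(4):
                u.atoms.positions = coords[f]
                w.write(u.atoms)
        back = load_trajectory(pdb_path, dcd_path, format="dcd")
        assert back.n_frames == 4
        np.testing.assert_allclose(back.coords_array(), coords, atol=1e-3)

    def test_atom_count_mismatch(self, tmp_path):
        rng = np.random.default_rng(1)
        coords6 = rng.normal(size=(2, 6, 3))
        pdb6 = tmp_path / "six.pdb"
        write_multimodel_pdb(_toy_traj(coords6[:1]), pdb6)
        dcd6 = tmp_path / "six.dcd"
        import MDAnalysis as mda

        u = mda.Universe(str(pdb6))
        with mda.Writer(str(dcd6), n_atoms=6) as w:
            u.atoms.positions = coords6[0]
            w.write(u.atoms)
        pdb5 = tmp_path / "five.pdb"
        write_multimodel_pdb(_toy_traj(rng.normal(size=(1, 5, 3))), pdb5)
        with pytest.raises(Exception, match="5|mismatch"):
            load_trajectory(pdb5, dcd6, format="dcd")


class TestGeometricCenter:
    def test_two_points(self):
        assert geometric_center(np.array([[0.0, 0, 0], [2.0, 0, 0]])) == pytest.approx(
            [1.0, 0, 0]
        )

    def test_single_atom(self):
        np.testing.assert_allclose(geometric_center(np.array([[1.5, -2.0, 3.0]])),
                                   [1.5, -2.0, 3.0])

    def test_matches_direct_summation(self):
        pts = np.random.default_rng(11).normal(size=(1000, 3))
        oracle = np.array([pts[:, d].sum() / len(pts) for d in range(3)])
        np.testing.assert_allclose(geometric_center(pts), oracle, atol=1e-12)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            geometric_center(np.empty((0, 3)))


class TestDihedral:
    def test_orthogonal_construction(self):
        phi = dihedral_angle([1, 0, 0], [0, 0, 0], [0, 1, 0], [0, 1, 1])
        assert abs(phi) == pytest.approx(90.0, abs=1e-9)

    def test_trans_planar(self):
        phi = dihedral_angle([1, 1, 0], [0, 1, 0], [0, -1, 0], [-1, -1, 0])
        assert abs(phi) == pytest.approx(180.0, abs=1e-9)

    def test_cis_planar(self):
        phi = dihedral_angle([1, 1, 0], [0, 1, 0], [0, -1, 0], [1, -1, 0])
        assert phi == pytest.approx(0.0, abs=1e-9)

    def test_reversal_symmetry_and_mirror_antisymmetry(self):
        """Torsions are invariant under atom-order reversal and negate under
        mirror reflection — the two defining symmetries of the standard
        sign convention."""
        rng = np.random.default_rng(8)
        mirror = np.array([1.0, 1.0, -1.0])
        for _ in range(50):
            p = rng.normal(size=(4, 3)) * 3.0
            fwd = dihedral_angle(*p)
            assert dihedral_angle(*p[::-1]) == pytest.approx(fwd, abs=1e-9)
            assert dihedral_angle(*(p * mirror)) == pytest.approx(-fwd, abs=1e-9)

    def test_against_mdanalysis(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.normal(size=(4, 3)) * 3.0
            ours = dihedral_angle(*p)
            ref = np.degrees(calc_dihedrals(p[0], p[1], p[2], p[3]))
            assert ours == pytest.approx(float(ref), abs=1e-3)  # MDAnalysis is float32

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            dihedral_angle([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])


class TestTrajectoryRmsd:
    def test_reference_frame_zero(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(5, 30, 3))
        traj = _toy_traj(coords, groups={"all": np.arange(30)})
        series = trajectory_rmsd(traj, coords[0], "all")
        assert series[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_body_motion_is_invisible(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(30, 3)) * 4.0
        frames = []
        for k in range(6):
            t = np.radians(15.0 * k)
            rot = np.array([[np.cos(t), -np.sin(t), 0],
                            [np.sin(t), np.cos(t), 0], [0, 0, 1]])
            frames.append(base @ rot.T + k * np.array([1.0, -2.0, 0.5]))
        traj = _toy_traj(np.stack(frames), groups={"all": np.arange(30)})
        series = trajectory_rmsd(traj, base, "all")
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_noise_level_matches_closed_form(self):
        """Mean RMSD under iid Gaussian noise ≈ σ·sqrt(3·(1−1/N))."""
        rng = np.random.default_rng(4)
        n_atoms, sigma = 500, 0.1
        base = rng.normal(size=(n_atoms, 3)) * 10.0
        frames = base[None] + rng.normal(size=(100, n_atoms, 3)) * sigma
        traj = _toy_traj(frames, groups={"all": np.arange(n_atoms)})
        series = trajectory_rmsd(traj, base, "all")
        expected = sigma * np.sqrt(3.0 * (1.0 - 1.0 / n_atoms))
        assert series.mean() == pytest.approx(expected, rel=0.05)

    def test_size_mismatch(self):
        traj = _toy_traj(np.zeros((2, 4, 3)) + np.arange(4)[None, :, None],
                         groups={"all": np.arange(4)})
        with pytest.raises(ValueError, match="reference"):
            trajectory_rmsd(traj, np.zeros((3, 3)), "all")


class TestShellCounts:
    def test_planted_distances(self):
        # ligand at origin; waters at 3, 6, 10, 20 Å
        coords = np.zeros((1, 5, 3))
        for i, d in enumerate([3.0, 6.0, 10.0, 20.0]):
            coords[0, i + 1, 0] = d
        traj = _toy_traj(coords, groups={"lig": [0], "wat": [1, 2, 3, 4]})
        counts = shell_water_counts(traj, "lig", "wat", radii=[4, 8, 15])
        np.testing.assert_array_equal(counts[0], [1, 2, 3])

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(-20, 20, size=(3, 200, 3))
        traj = _toy_traj(coords, groups={"lig": [0, 1], "wat": np.arange(2, 200)})
        counts = shell_water_counts(traj, "lig", "wat", radii=[4, 8, 15])
        assert np.all(np.diff(counts, axis=1) >= 0)

    def test_equals_bruteforce(self):
        rng = np.random.default_rng(7)
        n_wat = 2000
        coords = np.concatenate(
            [rng.normal(size=(1, 4, 3)) * 2.0, rng.uniform(-25, 25, size=(1, n_wat, 3))],
            axis=1,
        )
        traj = _toy_traj(coords, groups={"lig": np.arange(4),
                                         "wat": np.arange(4, 4 + n_wat)})
        radii = [4.0, 8.0, 15.0]
        counts = shell_water_counts(traj, "lig", "wat", radii=radii)
        diff = coords[0, 4:, None, :] - coords[0, None, :4, :]
        mind = np.sqrt((diff ** 2).sum(-1)).min(axis=1)
        brute = [(mind <= r).sum() for r in radii]
        np.testing.assert_array_equal(counts[0], brute)

    def test_periodic_minimum_image(self):
        box = np.array([10.0, 10.0, 10.0])
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 9.5  # 0.5 Å away through the boundary
        traj = _toy_traj(coords, groups={"lig": [0], "wat": [1]}, box=box)
        counts = shell_water_counts(traj, "lig", "wat", radii=[1.0, 2.0, 3.0])
        np.testing.assert_array_equal(counts[0], [1, 1, 1])

    def test_bad_radii(self):
        traj = _toy_traj(np.zeros((1, 2, 3)), groups={"lig": [0], "wat": [1]})
        with pytest.raises(ValueError):
            shell_water_counts(traj, "lig", "wat", radii=[8, 4])


class TestDensityGrid:
    def test_stationary_water_single_voxel(self):
        coords = np.zeros((10, 4, 3))
        coords[:, :3, :] = np.array([[0, 0, 0], [4.0, 0, 0], [0, 4.0, 0]])[None]
        coords[:, 3, :] = [1.5, 1.5, 1.5]  # voxel centre for 1 Å voxels from origin
        traj = _toy_traj(coords, groups={"alg": [0, 1, 2], "wat": [3]})
        extent = np.array([[0.0, 3.0], [0.0, 3.0], [0.0, 3.0]])
        grid = water_density_grid(traj, "wat", "alg", voxel=1.0, extent=extent)
        assert grid.values[1, 1, 1] == pytest.approx(1.0)
        assert grid.total() == pytest.approx(1.0)

    def test_mass_conservation(self):
        rng = np.random.default_rng(10)
        n_wat = 300
        coords = np.concatenate(
            [rng.normal(size=(5, 4, 3)), rng.normal(size=(5, n_wat, 3)) * 5.0], axis=1
        )
        coords[:, :4, :] = coords[0, :4, :][None]  # rigid align group
        traj = _toy_traj(coords, groups={"alg": np.arange(4),
                                         "wat": np.arange(4, 4 + n_wat)})
        extent = np.array([[-20.0, 20.0]] * 3)
        grid = water_density_grid(traj, "wat", "alg", voxel=2.0, extent=extent)
        in_extent = np.mean([
            np.all((coords[f, 4:] >= -20) & (coords[f, 4:] < 20), axis=1).sum()
            for f in range(5)
        ])
        assert grid.total() == pytest.approx(in_extent, abs=1e-9)

    def test_equals_bruteforce_binning(self):
        rng = np.random.default_rng(12)
        n_wat = 500
        wat = rng.normal(size=(3, n_wat, 3)) * 3.0
        align = rng.normal(size=(4, 3)) * 6.0
        coords = np.concatenate([np.tile(align, (3, 1, 1)), wat], axis=1)
        traj = _toy_traj(coords, groups={"alg": np.arange(4),
                                         "wat": np.arange(4, 4 + n_wat)})
        extent = np.array([[-12.0, 12.0]] * 3)
        grid = water_density_grid(traj, "wat", "alg", voxel=1.5, extent=extent)
        edges = [np.arange(-12.0, 12.0 + 0.75, 1.5)] * 3
        brute = np.zeros(grid.shape)
        for f in range(3):  # align group static => alignment is identity
            h, _ = np.histogramdd(wat[f], bins=edges)
            brute += h
        np.testing.assert_allclose(grid.values, brute / 3.0, atol=1e-12)

    def test_save_load_roundtrip(self, tmp_path):
        grid = DensityGrid(origin=np.zeros(3), voxel=1.0,
                           values=np.arange(8.0).reshape(2, 2, 2))
        grid.save(tmp_path / "grid")
        back = DensityGrid.load(tmp_path / "grid")
        np.testing.assert_allclose(back.values, grid.values)
        assert back.voxel == 1.0
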