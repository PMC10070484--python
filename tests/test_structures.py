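"""Structure I/O, selection, superposition and composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxltools.structures import (
    SelectionQuery,
    Structure,
    ca_rmsd,
    kabsch_superpose,
    read_structure,
    residue_composition,
    select,
    write_structure,
)

from conftest import atom_line, structure_from_atoms, toy_chain


class TestReadStructure:
    def test_single_model_roundtrip(self, three_atom_pdb):
        st_ = read_structure(three_atom_pdb)
        assert st_.n_models == 1
        assert st_.n_atoms == 3
        np.testing.assert_allclose(
            st_.coordinates(0),
            [[11.104, 6.134, -6.504], [11.639, 6.071, -5.147], [12.759, 7.093, -4.974]],
        )
        assert [a.atom_name for a in st_.models[0]] == ["N", "CA", "C"]

    def test_two_identical_models(self, two_model_pdb):
        st_ = read_structure(two_model_pdb)
        assert st_.n_models == 2
        np.testing.assert_allclose(st_.coordinates(0), st_.coordinates(1))

    def test_model_atom_count_mismatch_names_model(self, tmp_path):
        lines = [
            "MODEL        1",
            atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            atom_line(2, "CA", "GLY", "A", 2, 1, 0, 0),
            "ENDMDL",
            "MODEL        2",
            atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            "ENDMDL",
            "END",
        ]
        path = tmp_path / "bad.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="model 2"):
            read_structure(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")

    def test_insertion_code_rejected(self, tmp_path):
        path = tmp_path / "icode.pdb"
        path.write_text(atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, icode="A") + "\nEND\n")
        with pytest.raises(ValueError, match="insertion code"):
            read_structure(path)

    def test_hetero_flag_and_altloc_policy(self, tmp_path):
        lines = [
            atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            atom_line(2, "CB", "SER", "A", 2, 1, 0, 0, altloc="A"),
            atom_line(3, "CB", "SER", "A", 2, 2, 0, 0, altloc="B"),
            atom_line(4, "O", "HOH", "A", 101, 3, 0, 0, element="O", record="HETATM"),
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        st_ = read_structure(path)
        # altloc B dropped, water kept as hetero
        assert st_.n_atoms == 3
        assert [a.is_hetero for a in st_.models[0]] == [False, False, True]

    def test_write_read_roundtrip(self, tmp_path):
        original = structure_from_atoms(toy_chain(5))
        path = tmp_path / "out.pdb"
        write_structure(original, path)
        back = read_structure(path)
        np.testing.assert_allclose(
            back.coordinates(0), original.coordinates(0), atol=1e-3
        )


class TestSelect:
    def test_calpha_only(self):
        st_ = structure_from_atoms(toy_chain(5))
        atoms = select(st_, 0, SelectionQuery(calpha_only=True))
        assert len(atoms) == 5
        assert all(a.atom_name == "CA" for a in atoms)

    def test_range_arithmetic(self):
        st_ = structure_from_atoms(toy_chain(404, first_residue=11))  # covers 11..414
        atoms = select(st_, 0, SelectionQuery(residue_ranges=[(15, 410)], calpha_only=True))
        assert len(atoms) == 396

    def test_zero_matches_is_error(self):
        st_ = structure_from_atoms(toy_chain(5))
        with pytest.raises(ValueError, match="OXL"):
            select(st_, 0, SelectionQuery(residue_names={"OXL"}))

    def test_empty_query_matches_all(self):
        st_ = structure_from_atoms(toy_chain(7))
        assert len(select(st_, 0, SelectionQuery())) == 7


def _random_points(n, seed):
    return np.random.default_rng(seed).normal(size=(n, 3)) * 5.0


def _rot_z(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]])


class TestKabsch:
    def test_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_recovers_rotation_and_translation(self):
        ref = _random_points(10, 0)
        mobile = ref @ _rot_z(90).T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(mobile, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        angle = np.degrees(np.arccos(np.clip((np.trace(res.rotation) - 1) / 2, -1, 1)))
        assert angle == pytest.approx(90.0, abs=1e-6)

    def test_optimality_vs_random_rotations(self):
        """The Kabsch RMSD beats thousands of random proper rotations."""
        rng = np.random.default_rng(42)
        ref = rng.normal(size=(100, 3)) * 5.0
        mobile = ref + rng.normal(size=(100, 3)) * 0.1
        best = kabsch_superpose(mobile, ref).rmsd
        xm = mobile - mobile.mean(axis=0)
        xr = ref - ref.mean(axis=0)
        from scipy.spatial.transform import Rotation

        rots = Rotation.random(2000, random_state=7)
        for rot in rots:
            trial = np.sqrt(np.mean(np.sum((xm @ rot.as_matrix().T - xr) ** 2, axis=1)))
            assert best <= trial + 1e-12

    def test_reflection_never_returned(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(20, 3))
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(mirrored, ref)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotation_validity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        res = kabsch_superpose(a, b)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_input_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|rank"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCaRmsd:
    def test_identical_structures(self):
        a = structure_from_atoms(toy_chain(20))
        report = ca_rmsd(a, a)
        assert report.rmsd == pytest.approx(0.0, abs=1e-12)
        assert report.n_pairs == 20

    def test_uniform_displacement_without_superposition(self):
        a = structure_from_atoms(toy_chain(20))
        b = structure_from_atoms(toy_chain(20, offset=np.array([1.0, 0.0, 0.0])))
        report = ca_rmsd(a, b, pre_superpose=False)
        assert report.rmsd == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_with_superposition(self):
        rng = np.random.default_rng(5)
        a_atoms = toy_chain(30)
        b_atoms = toy_chain(30)
        jitter = rng.normal(size=(30, 3)) * 0.5
        from oxltools.structures import Atom

        b_atoms = [
            Atom(x.chain_id, x.residue_number, x.residue_name, x.atom_name,
                 x.element, x.position + jitter[i], x.is_hetero)
            for i, x in enumerate(b_atoms)
        ]
        a = structure_from_atoms(a_atoms)
        b = structure_from_atoms(b_atoms)
        assert ca_rmsd(a, b).rmsd == pytest.approx(ca_rmsd(b, a).rmsd, abs=1e-9)

    def test_dropped_residues_reported(self):
        a = structure_from_atoms(toy_chain(20))
        b = structure_from_atoms(toy_chain(15))  # residues 16..20 missing
        report = ca_rmsd(a, b)
        assert report.n_pairs == 15
        assert [r for _, r in report.dropped_a] == [16, 17, 18, 19, 20]

    def test_empty_pairing_is_error(self):
        a = structure_from_atoms(toy_chain(5, chain="A"))
        b = structure_from_atoms(toy_chain(5, chain="B"))
        with pytest.raises(ValueError, match="no C"):
            ca_rmsd(a, b)


class TestComposition:
    def test_counts_and_fraction(self):
        rep = residue_composition("GGGA")
        assert rep.count("G") == 3
        assert rep.fraction("G") == pytest.approx(75.0)

    @settings(deadline=None, max_examples=25)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=60),
           st.randoms(use_true_random=False))
    def test_order_invariance_and_conservation(self, seq, rnd):
        rep = residue_composition(seq)
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        rep2 = residue_composition("".join(shuffled))
        assert rep.counts == rep2.counts
        assert sum(rep.counts.values()) == rep.total == len(seq)
        assert sum(rep.fractions.values()) == pytest.approx(100.0, abs=1e-9)

    def test_illegal_character_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            residue_composition("GGZG")

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            residue_composition("")
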