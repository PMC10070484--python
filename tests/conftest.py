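"""Shared fixtures: hand-built PDB text and small planted trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from oxltools.structures import Atom, Structure


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    element: str = "C",
    record: str = "ATOM",
    altloc: str = " ",
    icode: str = " ",
) -> str:
    """One fixed-width PDB coordinate record."""
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record:<6s}{serial:5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


THREE_ATOM_PDB = "\n".join([
    atom_line(1, "N", "GLY", "A", 1, 11.104, 6.134, -6.504, "N"),
    atom_line(2, "CA", "GLY", "A", 1, 11.639, 6.071, -5.147, "C"),
    atom_line(3, "C", "GLY", "A", 1, 12.759, 7.093, -4.974, "C"),
    "END",
]) + "\n"


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    body = THREE_ATOM_PDB.replace("END\n", "")
    text = f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{body}ENDMDL\nEND\n"
    path = tmp_path / "two_model.pdb"
    path.write_text(text)
    return path


def toy_chain(
    n_residues: int,
    chain: str = "A",
    first_residue: int = 1,
    offset: np.ndarray | None = None,
) -> list[Atom]:
    """A synthetic Cα-only helix-like chain for pairing/RMSD tests."""
    atoms = []
    shift = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    for i in range(n_residues):
        theta = 2.0 * np.pi * i / 3.6
        pos = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]) + shift
        atoms.append(Atom(chain, first_residue + i, "ALA", "CA", "C", pos))
    return atoms


def structure_from_atoms(atoms: list[Atom]) -> Structure:
    return Structure(models=[atoms])
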