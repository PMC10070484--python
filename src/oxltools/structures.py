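"""Protein structures: PDB I/O, atom selection, superposition and composition.

This module holds the static-structure side of the toolkit: reading PDB
entries (e.g. the occluded and outward-facing crystal forms of a
transporter), selecting atom subsets, Kabsch superposition, Cα RMSD between
conformations, and residue-composition statistics such as the glycine
fraction that matters for bending-prone transmembrane helices.

Parsing and serialisation of the PDB format are delegated to :mod:`gemmi`;
the classes here are a thin, analysis-oriented view of its output.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "SelectionQuery",
    "SuperpositionResult",
    "CompositionReport",
    "RmsdReport",
    "read_structure",
    "write_structure",
    "select",
    "kabsch_superpose",
    "ca_rmsd",
    "residue_composition",
]

#: Twenty standard amino acids, one-letter alphabet (plus X for unknown).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    """A single atom record with author numbering preserved."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    is_hetero: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.residue_number < -999:
            raise ValueError(f"residue_number {self.residue_number} below PDB minimum -999")


@dataclass
class Structure:
    """An ordered stack of models sharing one topology.

    ``models[i]`` is the atom list of model ``i``; every model has the same
    atoms in the same order. ``sequence_per_chain`` maps chain id to a
    one-letter polymer sequence (SEQRES when present, else derived from
    ATOM records with ``sequence_from_seqres`` cleared).
    """

    models: list[list[Atom]]
    sequence_per_chain: dict[str, str] = field(default_factory=dict)
    source_id: str = ""
    sequence_from_seqres: bool = False

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return len(self.models[0]) if self.models else 0

    def coordinates(self, model_index: int = 0) -> np.ndarray:
        """(N, 3) coordinate array of one model."""
        atoms = self.models[model_index]
        return np.array([a.position for a in atoms], dtype=float)


@dataclass
class SelectionQuery:
    """Conjunction of atom filters; an empty query matches every atom.

    ``residue_ranges`` are inclusive (start, end) author-number ranges; a
    residue matches if it falls in any range.
    """

    chains: set[str] | None = None
    residue_ranges: list[tuple[int, int]] | None = None
    residue_names: set[str] | None = None
    atom_names: set[str] | None = None
    heavy_only: bool = False
    calpha_only: bool = False

    def matches(self, atom: Atom) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
            lo <= atom.residue_number <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.residue_names is not None and atom.residue_name not in self.residue_names:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.heavy_only and atom.element.upper() == "H":
            return False
        if self.calpha_only and atom.atom_name != "CA":
            return False
        return True

    def describe(self) -> str:
        clauses = []
        if self.chains is not None:
            clauses.append(f"chains={sorted(self.chains)}")
        if self.residue_ranges is not None:
            clauses.append(f"residue_ranges={self.residue_ranges}")
        if self.residue_names is not None:
            clauses.append(f"residue_names={sorted(self.residue_names)}")
        if self.atom_names is not None:
            clauses.append(f"atom_names={sorted(self.atom_names)}")
        if self.heavy_only:
            clauses.append("heavy_only")
        if self.calpha_only:
            clauses.append("calpha_only")
        return ", ".join(clauses) if clauses else "<match all>"


@dataclass
class SuperpositionResult:
    """Proper rotation + translation minimising RMSD, and the RMSD itself.

    The transform maps mobile coordinates onto the reference frame:
    ``x' = R @ x + t``.
    """

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class CompositionReport:
    """Residue-type counts and percentages for a polymer sequence."""

    counts: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        return {aa: 100.0 * n / self.total for aa, n in self.counts.items()}

    def count(self, one_letter: str) -> int:
        return self.counts.get(one_letter, 0)

    def fraction(self, one_letter: str) -> float:
        return 100.0 * self.count(one_letter) / self.total

    def to_json(self) -> str:
        return json.dumps(
            {"total": self.total, "counts": self.counts, "fractions": self.fractions},
            indent=2, sort_keys=True,
        )


@dataclass
class RmsdReport:
    """Cα RMSD between two structures with the pairing that produced it."""

    rmsd: float
    n_pairs: int
    dropped_a: list[tuple[str, int]]
    dropped_b: list[tuple[str, int]]
    superposition: SuperpositionResult | None = None


# ---------------------------------------------------------------------------
# PDB I/O


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    HETATM records are retained with ``is_hetero`` set. Alternate locations
    other than blank or 'A' are dropped so each model is a single
    deterministic conformer. Residues with insertion codes are rejected.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()

    models: list[list[Atom]] = []
    for model in st:
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                if res.seqid.icode.strip():
                    raise ValueError(
                        f"insertion code {res.seqid.icode!r} at {chain.name}{res.seqid.num} "
                        "is not supported"
                    )
                for at in res:
                    if at.altloc not in ("\0", "", "A"):
                        continue
                    atoms.append(Atom(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        atom_name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_hetero=(res.het_flag == "H"),
                    ))
        models.append(atoms)

    if not models or not models[0]:
        raise ValueError(f"{path}: no atoms found")
    n0 = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n0:
            raise ValueError(
                f"{path}: model {i + 1} has {len(m)} atoms, expected {n0} as in model 1"
            )

    sequences, from_seqres = _extract_sequences(st, models[0])
    return Structure(
        models=models,
        sequence_per_chain=sequences,
        source_id=st.name or path.stem,
        sequence_from_seqres=from_seqres,
    )


def _extract_sequences(st: gemmi.Structure, atoms: list[Atom]) -> tuple[dict[str, str], bool]:
    seqres: dict[str, str] = {}
    for ent in st.entities:
        if ent.entity_type != gemmi.EntityType.Polymer or not ent.full_sequence:
            continue
        seq = "".join(_THREE_TO_ONE.get(gemmi.Entity.first_mon(m), "X")
                      for m in ent.full_sequence)
        # subchain labels like 'Axp' start with the chain name
        for sub in ent.subchains:
            seqres[sub[0]] = seq
    if seqres:
        return seqres, True
    # fall back to ATOM-derived sequence (polymer residues only)
    warnings.warn("no SEQRES records; sequence derived from ATOM records may have gaps")
    derived: dict[str, str] = {}
    seen: set[tuple[str, int]] = set()
    for a in atoms:
        if a.is_hetero or a.residue_name not in _THREE_TO_ONE:
            continue
        key = (a.chain_id, a.residue_number)
        if key in seen:
            continue
        seen.add(key)
        derived[a.chain_id] = derived.get(a.chain_id, "") + _THREE_TO_ONE[a.residue_name]
    return derived, False


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure (all models) as a PDB file."""
    st = gemmi.Structure()
    st.name = structure.source_id or "XXXX"
    for i, atoms in enumerate(structure.models):
        model = gemmi.Model(i + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        for a in atoms:
            chain = chain_map.get(a.chain_id)
            if chain is None:
                model.add_chain(gemmi.Chain(a.chain_id))
                chain = model[len(model) - 1]  # add_chain copies; keep the live ref
                chain_map[a.chain_id] = chain
            res = None
            if len(chain) > 0:
                last = chain[len(chain) - 1]
                if last.seqid.num == a.residue_number and last.name == a.residue_name:
                    res = last
            if res is None:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                res.het_flag = "H" if a.is_hetero else "A"
                chain.add_residue(res)
                res = chain[len(chain) - 1]
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.position)
            res.add_atom(at)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Selection


def select(structure: Structure, model_index: int, query: SelectionQuery) -> list[Atom]:
    """Atoms of one model matching all clauses of ``query``, in file order.

    Raises if nothing matches, naming the query, so silent empty selections
    cannot propagate into downstream geometry.
    """
    atoms = [a for a in structure.models[model_index] if query.matches(a)]
    if not atoms:
        raise ValueError(f"selection matched zero atoms (query: {query.describe()})")
    return atoms


# ---------------------------------------------------------------------------
# Superposition and RMSD


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Uses the SVD construction; if the optimal orthogonal transform is a
    reflection, the sign of the smallest singular vector is flipped so the
    result is always a proper rotation (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"coordinate shapes differ: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of shape (N, 3)")

    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr
    h = x.T @ y
    if np.linalg.matrix_rank(h) < 2:
        raise ValueError("degenerate (collinear or rank-deficient) coordinate sets")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    rmsd = _rmsd(mobile @ rot.T + trans, reference)
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd,
                               n_atoms=mobile.shape[0])


def ca_rmsd(
    struct_a: Structure,
    struct_b: Structure,
    residue_ranges: Sequence[tuple[str, int, int]] | None = None,
    pre_superpose: bool = True,
    model_a: int = 0,
    model_b: int = 0,
) -> RmsdReport:
    """Cα RMSD between two structures paired by (chain, author residue number).

    ``residue_ranges`` restricts the comparison to inclusive (chain, start,
    end) windows; ``None`` uses every modelled Cα. Residues present on only
    one side are dropped and reported, so a printed "all residues" figure
    can be reproduced over the modelled intersection.
    """

    def _ca_map(structure: Structure, model: int) -> dict[tuple[str, int], np.ndarray]:
        out: dict[tuple[str, int], np.ndarray] = {}
        for a in structure.models[model]:
            if a.atom_name == "CA" and not a.is_hetero:
                out.setdefault((a.chain_id, a.residue_number), a.position)
        return out

    def _in_ranges(key: tuple[str, int]) -> bool:
        if residue_ranges is None:
            return True
        return any(key[0] == ch and lo <= key[1] <= hi for ch, lo, hi in residue_ranges)

    ca_a = {k: v for k, v in _ca_map(struct_a, model_a).items() if _in_ranges(k)}
    ca_b = {k: v for k, v in _ca_map(struct_b, model_b).items() if _in_ranges(k)}
    common = sorted(set(ca_a) & set(ca_b))
    if not common:
        raise ValueError("no Cα residue pairs in common between the two structures")

    xa = np.array([ca_a[k] for k in common])
    xb = np.array([ca_b[k] for k in common])
    sup = None
    if pre_superpose:
        sup = kabsch_superpose(xa, xb)
        rmsd = sup.rmsd
    else:
        rmsd = _rmsd(xa, xb)
    return RmsdReport(
        rmsd=rmsd,
        n_pairs=len(common),
        dropped_a=sorted(set(ca_a) - set(ca_b)),
        dropped_b=sorted(set(ca_b) - set(ca_a)),
        superposition=sup,
    )


def ca_rmsd_chain_pair(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    start: int,
    end: int,
    model: int = 0,
) -> RmsdReport:
    """Cα RMSD between two chains of one entry over a residue window.

    Convenience for comparing crystallographically independent copies, e.g.
    the two transporter molecules in one asymmetric unit. Pairing is by
    residue number; superposition is always applied.
    """
    sub_a = Structure(models=[[a for a in structure.models[model] if a.chain_id == chain_a]])
    sub_b = Structure(models=[[a for a in structure.models[model] if a.chain_id == chain_b]])
    # renumber onto a shared chain key so ca_rmsd pairs by residue number
    for sub in (sub_a, sub_b):
        sub.models[0] = [
            Atom("X", a.residue_number, a.residue_name, a.atom_name, a.element,
                 a.position, a.is_hetero)
            for a in sub.models[0]
        ]
    return ca_rmsd(sub_a, sub_b, residue_ranges=[("X", start, end)], pre_superpose=True)


# ---------------------------------------------------------------------------
# Composition


def residue_composition(sequence: str) -> CompositionReport:
    """Count residue types in a one-letter sequence.

    Percentages are exact ratios; rounding is left to presentation so that
    e.g. a glycine fraction prints as 12.4% only at the formatting step.
    """
    if not sequence:
        raise ValueError("empty sequence")
    for i, ch in enumerate(sequence):
        if ch not in AA_ALPHABET:
            raise ValueError(f"illegal residue character {ch!r} at position {i}")
    counts = dict(Counter(sequence))
    return CompositionReport(counts=counts, total=len(sequence))
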