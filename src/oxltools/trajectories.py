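"""Trajectory model, readers, and the geometry kernels used by every analysis.

A :class:`Trajectory` is an ordered stack of coordinate frames over a fixed
:class:`Topology` (atom metadata plus named index groups such as
``"binding_site"`` or ``"water_O"``). Frames are addressed by 0-based index;
the frame index is the primary time axis and ``dt`` is metadata only, so
every analysis works on trajectories without timestamps.

Multi-model PDB is read natively (via the structures module); DCD and XTC
go through MDAnalysis. Distance computations use the minimum-image
convention when an orthorhombic box is present and plain Euclidean geometry
otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import Atom, Structure, kabsch_superpose, read_structure

__all__ = [
    "Topology",
    "Trajectory",
    "DihedralTrace",
    "DensityGrid",
    "load_trajectory",
    "geometric_center",
    "dihedral_angle",
    "trajectory_rmsd",
    "shell_water_counts",
    "water_density_grid",
    "pairwise_distance",
]


@dataclass
class Topology:
    """Atom metadata (no coordinates) plus named atom-index groups."""

    atoms: list[Atom]
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def add_group(self, label: str, indices: Sequence[int]) -> None:
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError(f"group {label!r} is empty")
        if len(np.unique(idx)) != idx.size:
            raise ValueError(f"group {label!r} has duplicate indices")
        if idx.min() < 0 or idx.max() >= self.n_atoms:
            raise ValueError(f"group {label!r} indices out of range 0..{self.n_atoms - 1}")
        self.groups[label] = idx

    def group(self, label: str) -> np.ndarray:
        try:
            return self.groups[label]
        except KeyError:
            raise KeyError(
                f"unknown group {label!r}; defined groups: {sorted(self.groups)}"
            ) from None

    def indices_where(self, **kwargs) -> np.ndarray:
        """Indices of atoms matching attribute filters, e.g. ``residue_name='OXL'``."""
        out = [
            i for i, a in enumerate(self.atoms)
            if all(getattr(a, k) == v for k, v in kwargs.items())
        ]
        return np.asarray(out, dtype=int)

    def find_atom(self, chain_id: str, residue_number: int, atom_name: str) -> int:
        """Index of exactly one atom; raises if missing or ambiguous."""
        hits = self.indices_where(
            chain_id=chain_id, residue_number=residue_number, atom_name=atom_name
        )
        if hits.size == 0:
            raise ValueError(f"no atom {chain_id}/{residue_number}/{atom_name}")
        if hits.size > 1:
            raise ValueError(f"atom spec {chain_id}/{residue_number}/{atom_name} is ambiguous")
        return int(hits[0])


class Trajectory:
    """In-memory trajectory: (n_frames, N, 3) coordinates over a Topology.

    ``box`` is either ``None`` or an (n_frames, 3) array of orthorhombic box
    lengths in Å. ``dt`` is the time per frame in ps when known.
    """

    def __init__(
        self,
        topology: Topology,
        coords: np.ndarray,
        dt: float | None = None,
        box: np.ndarray | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must have shape (n_frames, N, 3), got {coords.shape}")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frame atom count {coords.shape[1]} != topology atom count {topology.n_atoms}"
            )
        self.topology = topology
        self._coords = coords
        self.dt = dt
        if box is not None:
            box = np.asarray(box, dtype=float)
            if box.shape == (3,):
                box = np.tile(box, (coords.shape[0], 1))
            if box.shape != (coords.shape[0], 3):
                raise ValueError("box must be (3,) or (n_frames, 3) orthorhombic lengths")
        self.box = box

    @property
    def n_frames(self) -> int:
        return self._coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self._coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        """(N, 3) coordinates of frame ``i`` (0-based)."""
        return self._coords[i]

    def frame_box(self, i: int) -> np.ndarray | None:
        return None if self.box is None else self.box[i]

    def __iter__(self) -> Iterator[np.ndarray]:
        for i in range(self.n_frames):
            yield self._coords[i]

    def coords_array(self) -> np.ndarray:
        """The full (n_frames, N, 3) array (no copy)."""
        return self._coords


@dataclass
class DihedralTrace:
    """Per-frame signed torsion angle in degrees, range (−180, 180]."""

    phi: np.ndarray
    atom_quadruple: tuple[int, int, int, int] | tuple[str, str, str, str]

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(self.phi <= -180.0) or np.any(self.phi > 180.0):
            raise ValueError("torsion values must lie in (-180, 180]")

    @property
    def abs_phi(self) -> np.ndarray:
        """Unsigned torsion |φ| in [0, 180]."""
        return np.abs(self.phi)

    def __len__(self) -> int:
        return len(self.phi)


# ---------------------------------------------------------------------------
# Readers


def topology_from_structure(structure: Structure) -> Topology:
    """Topology from the first model of a Structure, with standard groups.

    Predefines ``"water_O"`` (oxygen atoms of HOH/WAT/TIP3 residues) when
    waters are present; other groups are added by the caller.
    """
    atoms = structure.models[0]
    topo = Topology(atoms=list(atoms))
    water_o = [
        i for i, a in enumerate(atoms)
        if a.residue_name in ("HOH", "WAT", "TIP3", "SOL") and a.element.upper() == "O"
    ]
    if water_o:
        topo.add_group("water_O", water_o)
    return topo


def load_trajectory(
    topology_path: str | Path | None,
    coords_path: str | Path,
    format: str = "multi-model-pdb",
    dt: float | None = None,
) -> Trajectory:
    """Load a trajectory from multi-model PDB (native) or DCD/XTC (MDAnalysis).

    For ``multi-model-pdb`` the coordinate file itself carries the topology;
    ``topology_path`` may be None or the same file. For ``dcd``/``xtc``,
    ``topology_path`` must be a PDB whose atom count matches the frames.
    """
    coords_path = Path(coords_path)
    if not coords_path.exists():
        raise FileNotFoundError(coords_path)

    if format == "multi-model-pdb":
        structure = read_structure(coords_path)
        topo = topology_from_structure(structure)
        coords = np.stack([structure.coordinates(i) for i in range(structure.n_models)])
        return Trajectory(topo, coords, dt=dt)

    if format in ("dcd", "xtc"):
        import MDAnalysis as mda

        if topology_path is None:
            raise ValueError(f"{format} trajectories need a topology file")
        structure = read_structure(topology_path)
        topo = topology_from_structure(structure)
        u = mda.Universe(str(topology_path), str(coords_path))
        if len(u.atoms) != topo.n_atoms:
            raise ValueError(
                f"atom-count mismatch: topology has {topo.n_atoms}, "
                f"trajectory has {len(u.atoms)}"
            )
        frames = []
        boxes = []
        has_box = True
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float).copy())
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                has_box = False
            else:
                boxes.append(dims[:3].astype(float).copy())
        file_dt = getattr(u.trajectory, "dt", None)
        return Trajectory(
            topo,
            np.stack(frames),
            dt=dt if dt is not None else file_dt,
            box=np.stack(boxes) if (has_box and boxes) else None,
        )

    raise ValueError(f"unsupported trajectory format: {format!r}")


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write every frame of a trajectory as one MODEL block of a PDB file."""
    from .structures import write_structure

    models = []
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        models.append([
            Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                 a.element, frame[j], a.is_hetero)
            for j, a in enumerate(traj.topology.atoms)
        ])
    write_structure(Structure(models=models, source_id="TRAJ"), path)


# ---------------------------------------------------------------------------
# Geometry kernels


def geometric_center(coords: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean position of an atom set."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("geometric_center of an empty atom set")
    return coords.reshape(-1, 3).mean(axis=0)


def pairwise_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> np.ndarray:
    """Distance between points ``a`` and ``b`` (broadcasting), minimum-image if boxed."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, range (−180, 180].

    Standard atan2 construction on the three bond vectors; positive sense is
    the IUPAC convention (clockwise rotation of p4 relative to p1 looking
    down p2→p3).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise ValueError("degenerate geometry: zero-length bond vector")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate geometry: collinear points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    # negated so the sign matches the common MD convention (e.g. MDAnalysis):
    # invariant under atom-order reversal, negated under mirror reflection
    phi = -np.degrees(np.arctan2(y, x))
    if phi <= -180.0:  # map -180 into the (−180, 180] convention
        phi += 360.0
    return float(phi)


def dihedral_trace(traj: Trajectory, quadruple: Sequence[int]) -> DihedralTrace:
    """Per-frame torsion over four atom indices."""
    i, j, k, l = (int(q) for q in quadruple)
    phi = np.array([
        dihedral_angle(f[i], f[j], f[k], f[l]) for f in traj
    ])
    return DihedralTrace(phi=phi, atom_quadruple=(i, j, k, l))


def trajectory_rmsd(
    traj: Trajectory,
    reference: np.ndarray,
    selection: str,
) -> np.ndarray:
    """Per-frame Cα-style RMSD of a selection after Kabsch superposition.

    ``reference`` must hold coordinates for the selection's atoms in group
    order (e.g. the selection coordinates of a crystal structure).
    """
    idx = traj.topology.group(selection)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (idx.size, 3):
        raise ValueError(
            f"reference shape {reference.shape} != selection size ({idx.size}, 3)"
        )
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = kabsch_superpose(traj.frame(f)[idx], reference).rmsd
    return out


def shell_water_counts(
    traj: Trajectory,
    ligand_group: str,
    water_group: str,
    radii: Sequence[float] = (4.0, 8.0, 15.0),
) -> np.ndarray:
    """Waters within each cutoff radius of the ligand, per frame.

    A water counts toward radius ``r`` when its minimum distance to any
    ligand atom is ≤ r, so the counts are non-decreasing in r. Waters are
    represented by their oxygen atoms (one count per molecule). Uses a k-d
    tree per frame; with a periodic box the tree is built on wrapped
    coordinates with periodic boundary support.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly ascending")
    lig_idx = traj.topology.group(ligand_group)
    wat_idx = traj.topology.group(water_group)

    counts = np.empty((traj.n_frames, radii.size), dtype=int)
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        lig = frame[lig_idx]
        wat = frame[wat_idx]
        box = traj.frame_box(f)
        # min distance from each water to any ligand atom = nearest-neighbour query
        if box is None:
            mind, _ = cKDTree(lig).query(wat)
        else:
            mind, _ = cKDTree(np.mod(lig, box), boxsize=box).query(np.mod(wat, box))
        counts[f] = [(mind <= r).sum() for r in radii]
    return counts


@dataclass
class DensityGrid:
    """Mean per-frame water occupancy on a regular voxel grid.

    ``values[i, j, k]`` is the average number of water oxygens per frame
    whose (aligned) position falls in voxel (i, j, k), so the grid sum
    equals the mean in-extent water count.
    """

    origin: np.ndarray  # (3,) lower corner, Å
    voxel: float  # Å
    values: np.ndarray  # (nx, ny, nz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def total(self) -> float:
        return float(self.values.sum())

    def save(self, path_prefix: str | Path) -> None:
        """Write ``<prefix>.json`` (header) and ``<prefix>.tsv`` (flat values)."""
        prefix = Path(path_prefix)
        header = {
            "origin": list(map(float, self.origin)),
            "voxel": self.voxel,
            "shape": list(self.shape),
            "order": "C",
        }
        prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))
        np.savetxt(prefix.with_suffix(".tsv"), self.values.ravel()[None], delimiter="\t")

    @classmethod
    def load(cls, path_prefix: str | Path) -> "DensityGrid":
        prefix = Path(path_prefix)
        header = json.loads(prefix.with_suffix(".json").read_text())
        values = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t").reshape(header["shape"])
        return cls(origin=np.asarray(header["origin"]), voxel=header["voxel"], values=values)


def water_density_grid(
    traj: Trajectory,
    water_group: str,
    align_group: str,
    voxel: float,
    extent: np.ndarray,
    reference: np.ndarray | None = None,
) -> DensityGrid:
    """Time-averaged water occupancy after superposing each frame.

    Each frame is Kabsch-aligned on ``align_group`` onto ``reference``
    (default: the align group's frame-0 coordinates) before the water
    oxygens are binned. ``extent`` is a (3, 2) array of [min, max] bounds in
    the aligned coordinate frame; bounds are snapped to whole voxels.
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    extent = np.asarray(extent, dtype=float)
    if extent.shape != (3, 2) or np.any(extent[:, 1] <= extent[:, 0]):
        raise ValueError("extent must be (3, 2) [min, max] bounds")
    align_idx = traj.topology.group(align_group)
    wat_idx = traj.topology.group(water_group)
    if reference is None:
        reference = traj.frame(0)[align_idx]

    n_bins = np.ceil((extent[:, 1] - extent[:, 0]) / voxel).astype(int)
    edges = [extent[d, 0] + voxel * np.arange(n_bins[d] + 1) for d in range(3)]
    acc = np.zeros(tuple(n_bins))
    any_water = False
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        sup = kabsch_superpose(frame[align_idx], reference)
        wat = sup.apply(frame[wat_idx])
        hist, _ = np.histogramdd(wat, bins=edges)
        if hist.sum() > 0:
            any_water = True
        acc += hist
    if not any_water:
        import warnings

        warnings.warn("density extent excludes all waters; returning a zero grid")
    return DensityGrid(origin=extent[:, 0].copy(), voxel=voxel, values=acc / traj.n_frames)
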