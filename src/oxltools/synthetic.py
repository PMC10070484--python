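"""Synthetic trajectories and assay curves with exactly known ground truth.

Every analysis in this package is tested against data whose generating
process is known frame by frame. The generator emulates, at desk scale,
the ingredients of a transporter binding/gating simulation study:

* ligand binding/unbinding as a two-state telegraph process per ligand —
  bound frames place the ligand centroid at the binding-site centre plus
  isotropic Gaussian jitter, unbound frames place it uniformly in a distant
  spherical shell;
* gate order parameters as two-state Gaussian distance processes realised
  by pseudo-atom pairs on a fixed axis;
* shell-structured waters: per-frame Poisson counts placed uniformly in
  concentric shells around a central probe atom, the remainder parked in a
  far reservoir so the atom count stays constant;
* the ligand O-C-C-O torsion as a wrapped-normal mixture keyed to the
  conformational state, realised by twisting a four-atom template about
  its central bond;
* two-state thermal unfolding curves from the Gibbs–Helmholtz model plus
  additive Gaussian noise.

All randomness flows through one ``numpy`` generator keyed by an explicit
seed, so identical specs give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .assays import MeltingCurve, gh_model
from .structures import Atom
from .trajectories import Topology, Trajectory

__all__ = [
    "GateSpec",
    "SyntheticTrajectorySpec",
    "GroundTruth",
    "generate_trajectory",
    "generate_melting_curve",
    "oxalate_template",
]


@dataclass
class GateSpec:
    """Two-state Gaussian distance process for one gate residue pair."""

    label: str
    residue_a: int
    residue_b: int
    mean_by_state: tuple[float, float] = (6.0, 10.0)  # Å, (closed, open)
    sigma: float = 0.3
    p_open: float = 0.0   # per-frame switch probability closed -> open
    p_close: float = 0.0  # per-frame switch probability open -> closed
    schedule: np.ndarray | None = None  # explicit per-frame 0/1 states

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("gate sigma must be positive")
        for p in (self.p_open, self.p_close):
            if not 0.0 <= p <= 1.0:
                raise ValueError("switch probabilities must be in [0, 1]")


@dataclass
class SyntheticTrajectorySpec:
    """Study-scale defaults for a planted transporter trajectory.

    The binding-site model is five pseudo-atoms on a ring (standing in for
    the five binding-site residues) whose geometric centre is the origin,
    plus a central probe atom for exact shell-count bookkeeping. Ligand
    telegraph rates default to a stationary bound probability of 0.77
    with visible binding/unbinding traffic; see the classmethod presets
    for the high-occupancy regime.
    """

    seed: int
    n_frames: int = 1000
    dt: float = 1000.0  # ps per frame (1 ns)
    # binding site
    site_n_atoms: int = 5
    site_radius: float = 2.0  # Å ring radius
    # ligands
    n_ligands: int = 3
    sigma_bound: float = 1.0  # Å; P(centre within 5 Å) > 0.9999
    shell_r_min: float = 10.0  # Å, must exceed cutoff + 3 sigma_bound
    shell_r_max: float = 20.0
    p_bind: float = 0.0067
    p_unbind: float = 0.002
    ligand_schedule: np.ndarray | None = None  # (n_frames, n_ligands) 0/1
    cutoff: float = 5.0  # Å, the bound criterion the data are built for
    # gates
    gates: list[GateSpec] = field(default_factory=lambda: [
        GateSpec("periplasmic", 38, 240),
        GateSpec("cytoplasmic", 128, 332, mean_by_state=(7.0, 9.0)),
    ])
    # waters: Poisson mean counts within the nested radii
    water_radii: tuple[float, ...] = (4.0, 8.0, 15.0)
    water_means: tuple[float, ...] = (2.0, 10.0, 40.0)
    # torsion mixture (means deg, sigmas deg, weights) keyed by gate-0 state
    torsion_by_state: dict[int, tuple[tuple[float, ...], tuple[float, ...], tuple[float, ...]]] = field(
        default_factory=lambda: {
            0: ((50.0, 130.0), (6.0, 6.0), (0.5, 0.5)),
            1: ((60.0, 120.0), (12.0, 12.0), (0.5, 0.5)),
        }
    )
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma_bound <= 0:
            raise ValueError("sigma_bound must be positive")
        if self.shell_r_min <= self.cutoff + 3 * self.sigma_bound:
            raise ValueError(
                "shell_r_min must exceed cutoff + 3*sigma_bound so unbound frames "
                "cannot satisfy the bound criterion"
            )
        if self.shell_r_max <= self.shell_r_min:
            raise ValueError("shell_r_max must exceed shell_r_min")
        for p in (self.p_bind, self.p_unbind):
            if not 0.0 <= p <= 1.0:
                raise ValueError("telegraph probabilities must be in [0, 1]")
        if len(self.water_means) != len(self.water_radii):
            raise ValueError("water_means must match water_radii in length")
        if np.any(np.diff(self.water_radii) <= 0):
            raise ValueError("water radii must be strictly ascending")

    @classmethod
    def high_occupancy(cls, seed: int, **kwargs) -> "SyntheticTrajectorySpec":
        """Preset with stationary bound probability ≈ 0.986 (rare unbinding)."""
        kwargs.setdefault("p_bind", 0.0352)
        kwargs.setdefault("p_unbind", 0.0005)
        return cls(seed=seed, **kwargs)

    @classmethod
    def low_occupancy(cls, seed: int, **kwargs) -> "SyntheticTrajectorySpec":
        """Preset with stationary bound probability ≈ 0.77 (frequent exchange)."""
        kwargs.setdefault("p_bind", 0.0067)
        kwargs.setdefault("p_unbind", 0.002)
        return cls(seed=seed, **kwargs)

    @property
    def stationary_bound_probability(self) -> float:
        s = self.p_bind + self.p_unbind
        return self.p_bind / s if s > 0 else 0.0


@dataclass
class GroundTruth:
    """Planted per-frame states and the quantities the analyses estimate."""

    ligand_states: np.ndarray  # (n_frames, n_ligands) bool
    gate_states: np.ndarray  # (n_frames, n_gates) int
    gate_distances: np.ndarray  # (n_frames, n_gates) planted sampled distances
    torsion_phi: np.ndarray  # (n_frames,) planted signed torsion, deg
    torsion_components: np.ndarray  # (n_frames,) mixture component index
    shell_counts: np.ndarray  # (n_frames, n_radii) planted cumulative counts
    stationary_bound_probability: float

    @property
    def occupancy_site(self) -> float:
        return float(self.ligand_states.any(axis=1).mean())

    @property
    def occupancy_per_ligand(self) -> np.ndarray:
        return self.ligand_states.mean(axis=0)

    def transition_frames(self, ligand: int) -> np.ndarray:
        s = self.ligand_states[:, ligand].astype(int)
        return np.nonzero(np.diff(s))[0] + 1

    def to_json(self) -> str:
        return json.dumps({
            "occupancy_site": self.occupancy_site,
            "occupancy_per_ligand": self.occupancy_per_ligand.tolist(),
            "stationary_bound_probability": self.stationary_bound_probability,
            "gate_state_fractions": self.gate_states.mean(axis=0).tolist(),
            "n_frames": int(self.ligand_states.shape[0]),
        }, indent=2)


# oxalate-like geometry: C-C 1.55 Å, C-O 1.25 Å, O-C-C angle 120°
_CC = 1.55
_CO = 1.25
_SIN60 = np.sin(np.radians(60.0))
_COS60 = 0.5


def oxalate_template(phi_deg: float) -> np.ndarray:
    """Four-atom O1-C1-C2-O2 template with the given O-C-C-O torsion.

    Returns (4, 3) coordinates centred on the atom centroid; the torsion of
    the returned geometry equals ``phi_deg`` exactly (by construction of
    the standard internal-coordinate placement).
    """
    phi = np.radians(phi_deg)
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([_CC, 0.0, 0.0])
    o1 = c1 + _CO * np.array([-_COS60, _SIN60, 0.0])
    o2 = c2 + _CO * np.array([_COS60, _SIN60 * np.cos(phi), _SIN60 * np.sin(phi)])
    coords = np.stack([o1, c1, c2, o2])
    return coords - coords.mean(axis=0)


def _telegraph(rng: np.random.Generator, n: int, p01: float, p10: float) -> np.ndarray:
    """Two-state Markov chain started from its stationary distribution."""
    s = p01 + p10
    p_stat = p01 / s if s > 0 else 0.0
    states = np.empty(n, dtype=int)
    states[0] = 1 if rng.random() < p_stat else 0
    u = rng.random(n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        if states[t - 1] == 0:
            states[t] = 1 if u[t - 1] < p01 else 0
        else:
            states[t] = 0 if u[t - 1] < p10 else 1
    return states


def _uniform_shell(rng: np.random.Generator, n: int, r_min: float, r_max: float) -> np.ndarray:
    """Uniform points in the spherical shell r_min < r < r_max."""
    u = rng.random(n)
    r = (u * (r_max**3 - r_min**3) + r_min**3) ** (1.0 / 3.0)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r[:, None] * v


def _random_rotations(rng: np.random.Generator, n: int) -> Rotation:
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q)


def generate_trajectory(spec: SyntheticTrajectorySpec) -> tuple[Trajectory, GroundTruth]:
    """Realise the planted processes of ``spec`` as coordinates.

    The returned trajectory's topology defines the groups ``binding_site``
    (the ring pseudo-atoms), ``site_centre`` (the probe atom at the exact
    site centre), ``ligand_<i>`` for each ligand, ``water_O``, and per-gate
    Cα pseudo-atoms on chain A with the spec's residue numbers.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    # --- planted state processes -------------------------------------------
    if spec.ligand_schedule is not None:
        lig_states = np.asarray(spec.ligand_schedule, dtype=int)
        if lig_states.shape != (n, spec.n_ligands):
            raise ValueError("ligand_schedule must have shape (n_frames, n_ligands)")
    else:
        lig_states = np.column_stack([
            _telegraph(rng, n, spec.p_bind, spec.p_unbind)
            for _ in range(spec.n_ligands)
        ])

    gate_states = np.empty((n, len(spec.gates)), dtype=int)
    gate_dists = np.empty((n, len(spec.gates)))
    for k, g in enumerate(spec.gates):
        if g.schedule is not None:
            st = np.asarray(g.schedule, dtype=int)
            if st.shape != (n,):
                raise ValueError(f"gate {g.label!r} schedule must have length n_frames")
        else:
            st = _telegraph(rng, n, g.p_open, g.p_close)
        gate_states[:, k] = st
        means = np.asarray(g.mean_by_state)[st]
        gate_dists[:, k] = means + g.sigma * rng.standard_normal(n)
        # distances must stay positive; the defaults put means many sigma above 0
        np.clip(gate_dists[:, k], 0.1, None, out=gate_dists[:, k])

    conf_state = gate_states[:, 0] if spec.gates else np.zeros(n, dtype=int)
    tors_phi = np.empty(n)
    tors_comp = np.empty(n, dtype=int)
    for t in range(n):
        means, sigmas, weights = spec.torsion_by_state[int(conf_state[t])]
        c = rng.choice(len(weights), p=np.asarray(weights) / np.sum(weights))
        phi = rng.normal(means[c], sigmas[c])
        phi = ((phi + 180.0) % 360.0) - 180.0  # wrap into (-180, 180]
        if phi == -180.0:
            phi = 180.0
        tors_phi[t] = phi
        tors_comp[t] = c

    n_shells = len(spec.water_radii)
    shell_counts_per = rng.poisson(spec.water_means, size=(n, n_shells))
    total_mean = float(np.sum(spec.water_means))
    n_water = int(np.ceil(total_mean + 8.0 * np.sqrt(max(total_mean, 1.0))))
    # capacity guard (the 8-sigma reservoir margin makes this a no-op in practice):
    # trim outermost shells first until the frame total fits the fixed atom count
    for t in np.nonzero(shell_counts_per.sum(axis=1) > n_water)[0]:
        for s in range(n_shells - 1, -1, -1):
            excess = shell_counts_per[t].sum() - n_water
            if excess <= 0:
                break
            take = min(excess, shell_counts_per[t, s])
            shell_counts_per[t, s] -= take
    # cumulative planted counts within each radius
    shell_cum = np.cumsum(shell_counts_per, axis=1)

    # --- topology ----------------------------------------------------------
    atoms: list[Atom] = []
    site_idx = []
    angles = 2.0 * np.pi * np.arange(spec.site_n_atoms) / spec.site_n_atoms
    site_ring = spec.site_radius * np.column_stack(
        [np.cos(angles), np.sin(angles), np.zeros_like(angles)]
    )
    for i in range(spec.site_n_atoms):
        site_idx.append(len(atoms))
        atoms.append(Atom("S", i + 1, "SIT", f"S{i + 1}", "C", site_ring[i]))
    cen_idx = len(atoms)
    atoms.append(Atom("S", 99, "CEN", "CEN", "C", np.zeros(3)))

    gate_atom_idx = []
    gate_resnames = {38: "THR", 240: "VAL", 128: "MET", 332: "PRO"}
    for k, g in enumerate(spec.gates):
        centre = np.array([0.0, 0.0, 40.0 + 15.0 * k])
        ia = len(atoms)
        atoms.append(Atom("A", g.residue_a, gate_resnames.get(g.residue_a, "GLY"),
                          "CA", "C", centre))
        ib = len(atoms)
        atoms.append(Atom("A", g.residue_b, gate_resnames.get(g.residue_b, "GLY"),
                          "CA", "C", centre))
        gate_atom_idx.append((ia, ib, centre))

    lig_atom_idx = []
    for j in range(spec.n_ligands):
        base = len(atoms)
        for name, el in (("O1", "O"), ("C1", "C"), ("C2", "C"), ("O2", "O")):
            atoms.append(Atom("L", j + 1, "OXL", name, el, np.zeros(3), is_hetero=True))
        lig_atom_idx.append(np.arange(base, base + 4))

    wat_idx = []
    for w in range(n_water):
        wat_idx.append(len(atoms))
        atoms.append(Atom("W", w + 1, "HOH", "O", "O", np.zeros(3), is_hetero=True))

    topo = Topology(atoms=atoms)
    topo.add_group("binding_site", site_idx)
    topo.add_group("site_centre", [cen_idx])
    for j in range(spec.n_ligands):
        topo.add_group(f"ligand_{j + 1}", lig_atom_idx[j])
    topo.add_group("water_O", wat_idx)
    for k, g in enumerate(spec.gates):
        topo.add_group(f"gate_{g.label}", [gate_atom_idx[k][0], gate_atom_idx[k][1]])

    # --- coordinates -------------------------------------------------------
    n_atoms = len(atoms)
    coords = np.zeros((n, n_atoms, 3))
    coords[:, site_idx, :] = site_ring[None, :, :]
    coords[:, cen_idx, :] = 0.0

    axis = np.array([1.0, 0.0, 0.0])
    for k, (ia, ib, centre) in enumerate(gate_atom_idx):
        half = 0.5 * gate_dists[:, k][:, None] * axis[None, :]
        coords[:, ia, :] = centre[None, :] - half
        coords[:, ib, :] = centre[None, :] + half

    # ligand placement: planted torsion template, random rigid orientation,
    # centroid from the telegraph state
    rots = _random_rotations(rng, n * spec.n_ligands)
    bound_jitter = spec.sigma_bound * rng.standard_normal((n, spec.n_ligands, 3))
    unbound_pos = _uniform_shell(
        rng, n * spec.n_ligands, spec.shell_r_min, spec.shell_r_max
    ).reshape(n, spec.n_ligands, 3)
    for t in range(n):
        template = oxalate_template(tors_phi[t])
        for j in range(spec.n_ligands):
            rot = rots[t * spec.n_ligands + j]
            centroid = (
                bound_jitter[t, j] if lig_states[t, j] else unbound_pos[t, j]
            )
            coords[t, lig_atom_idx[j], :] = rot.apply(template) + centroid

    # waters: planted shell counts around the probe, remainder in a reservoir
    res_lo = spec.water_radii[-1] + 10.0
    res_hi = res_lo + 10.0
    bounds = (0.0,) + tuple(spec.water_radii)
    for t in range(n):
        placed = 0
        for s in range(n_shells):
            k_s = int(shell_counts_per[t, s])
            if k_s:
                coords[t, wat_idx[placed]:wat_idx[placed] + k_s, :] = _uniform_shell(
                    rng, k_s, bounds[s], bounds[s + 1]
                )
                placed += k_s
        rest = n_water - placed
        if rest:
            coords[t, wat_idx[placed]:wat_idx[placed] + rest, :] = _uniform_shell(
                rng, rest, res_lo, res_hi
            )

    box = None
    if spec.box is not None:
        box = np.tile(np.asarray(spec.box, dtype=float), (n, 1))
        # shift everything into the box interior around its centre
        coords += np.asarray(spec.box) / 2.0

    traj = Trajectory(topo, coords, dt=spec.dt, box=box)
    truth = GroundTruth(
        ligand_states=lig_states.astype(bool),
        gate_states=gate_states,
        gate_distances=gate_dists,
        torsion_phi=tors_phi,
        torsion_components=tors_comp,
        shell_counts=shell_cum,
        stationary_bound_probability=spec.stationary_bound_probability,
    )
    return traj, truth


def generate_melting_curve(
    tm: float,
    dh: float,
    dcp: float,
    t_grid_k: Sequence[float],
    noise_sigma: float,
    seed: int,
    label: str = "synthetic",
) -> tuple[MeltingCurve, dict]:
    """Two-state unfolding curve: gh_model(T) plus Gaussian noise.

    Returns the curve and a truth record echoing the planted parameters.
    """
    t = np.asarray(t_grid_k, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    signal = gh_model(t, tm, dh, dcp)
    if noise_sigma > 0:
        signal = signal + noise_sigma * rng.standard_normal(t.size)
    curve = MeltingCurve(temperatures_k=t, signal=signal, label=label)
    truth = {"Tm_K": tm, "dH_kcal_mol": dh, "dCp_kcal_mol_K": dcp,
             "noise_sigma": noise_sigma, "seed": seed}
    return curve, truth
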