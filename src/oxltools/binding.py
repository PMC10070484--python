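"""Ligand-binding criterion, occupancy statistics and event segmentation.

The bound state follows a geometric-centre criterion: a ligand is bound in
a frame when the distance between the geometric centre of the ligand and
that of the binding-site residues is at or below a cutoff (5 Å by default,
the value used for oxalate binding to the transporter's Gln34 / Tyr35 /
Arg272 / Tyr328 / Lys355 site). Occupancy is the fraction of frames with
at least one bound ligand; per-ligand occupancies are reported alongside.
Because consecutive frames are autocorrelated, the optional standard error
uses a moving-block bootstrap rather than a binomial formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trajectories import Trajectory, geometric_center, pairwise_distance

__all__ = [
    "BindingConfig",
    "BindingTrace",
    "BindingEvent",
    "OccupancyReport",
    "binding_trace",
    "occupancy",
    "segment_events",
]


@dataclass
class BindingConfig:
    """Parameters of the geometric-centre bound criterion.

    ``cutoff`` is inclusive: distance ≤ cutoff counts as bound.
    ``site_atom_policy`` selects which site atoms enter the centre
    ("heavy-atoms" drops hydrogens; "all" keeps everything).
    """

    cutoff: float = 5.0
    site_group: str = "binding_site"
    ligand_groups: Sequence[str] = ("ligand_1",)
    min_dwell: int = 1
    site_atom_policy: str = "heavy-atoms"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_dwell < 1:
            raise ValueError("min_dwell must be >= 1")
        if self.site_atom_policy not in ("heavy-atoms", "all"):
            raise ValueError(f"unknown site_atom_policy {self.site_atom_policy!r}")


@dataclass
class BindingTrace:
    """Per-ligand centre-to-centre distances and bound masks.

    ``distances`` has shape (n_frames, n_ligands); ``bound`` is the same
    shape boolean; ``site_occupied`` is the per-frame OR over ligands.
    """

    distances: np.ndarray
    bound: np.ndarray
    ligand_labels: list[str]
    cutoff: float

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]

    @property
    def site_occupied(self) -> np.ndarray:
        return self.bound.any(axis=1)


@dataclass(frozen=True)
class BindingEvent:
    """One contiguous bound interval (frames inclusive)."""

    ligand: str
    start: int
    end: int

    @property
    def dwell(self) -> int:
        return self.end - self.start + 1


@dataclass
class OccupancyReport:
    """Occupancy of the site and of each ligand, with optional bootstrap SE."""

    occupancy: float
    n_frames: int
    per_ligand: dict[str, float]
    standard_error: float | None = None
    config: BindingConfig | None = None

    def to_json(self) -> str:
        payload = {
            "occupancy": self.occupancy,
            "n_frames": self.n_frames,
            "per_ligand": self.per_ligand,
            "standard_error": self.standard_error,
        }
        if self.config is not None:
            payload["config"] = {
                "cutoff": self.config.cutoff,
                "site_group": self.config.site_group,
                "ligand_groups": list(self.config.ligand_groups),
                "min_dwell": self.config.min_dwell,
                "site_atom_policy": self.config.site_atom_policy,
            }
        return json.dumps(payload, indent=2)


def binding_trace(traj: Trajectory, config: BindingConfig) -> BindingTrace:
    """Centre-to-centre distance and bound mask for every ligand and frame.

    Distances are minimum-image when the trajectory carries an orthorhombic
    box. The bound mask applies the inclusive cutoff directly; dwell-time
    debouncing is left to :func:`segment_events`.
    """
    topo = traj.topology
    site_idx = topo.group(config.site_group)
    if config.site_atom_policy == "heavy-atoms":
        heavy = np.array([topo.atoms[i].element.upper() != "H" for i in site_idx])
        site_idx = site_idx[heavy]
        if site_idx.size == 0:
            raise ValueError(f"site group {config.site_group!r} has no heavy atoms")
    lig_indices = [topo.group(g) for g in config.ligand_groups]

    n_lig = len(lig_indices)
    distances = np.empty((traj.n_frames, n_lig))
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        box = traj.frame_box(f)
        site_c = geometric_center(frame[site_idx])
        for j, idx in enumerate(lig_indices):
            lig_c = geometric_center(frame[idx])
            distances[f, j] = pairwise_distance(lig_c, site_c, box)
    bound = distances <= config.cutoff
    return BindingTrace(
        distances=distances,
        bound=bound,
        ligand_labels=list(config.ligand_groups),
        cutoff=config.cutoff,
    )


def occupancy(
    trace: BindingTrace,
    bootstrap: bool = False,
    block: int = 100,
    n_boot: int = 1000,
    seed: int | None = None,
) -> OccupancyReport:
    """Fraction of frames with ≥ 1 bound ligand, plus per-ligand occupancies.

    With ``bootstrap=True`` a moving-block bootstrap of the site-occupied
    mask gives a standard error that respects frame autocorrelation.
    """
    if trace.n_frames < 1:
        raise ValueError("empty binding trace")
    site = trace.site_occupied.astype(float)
    occ = float(site.mean())
    per_ligand = {
        lab: float(trace.bound[:, j].mean())
        for j, lab in enumerate(trace.ligand_labels)
    }
    se = None
    if bootstrap:
        se = _moving_block_bootstrap_se(site, block=block, n_boot=n_boot, seed=seed)
    return OccupancyReport(
        occupancy=occ, n_frames=trace.n_frames, per_ligand=per_ligand,
        standard_error=se,
    )


def _moving_block_bootstrap_se(
    series: np.ndarray, block: int, n_boot: int, seed: int | None
) -> float:
    n = series.size
    block = min(block, n)
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n / block))
    starts_max = n - block + 1
    means = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, starts_max, size=n_blocks)
        sample = np.concatenate([series[s:s + block] for s in starts])[:n]
        means[b] = sample.mean()
    return float(means.std(ddof=1))


def segment_events(
    mask: np.ndarray, min_dwell: int = 1, ligand: str = "ligand"
) -> list[BindingEvent]:
    """Maximal bound runs of length ≥ ``min_dwell`` as ordered events.

    Shorter bound runs are treated as excursions and merged into the
    surrounding unbound state (debounce). Start/end frames are inclusive.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size < 1:
        raise ValueError("empty mask")
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    events: list[BindingEvent] = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            in_run = True
            start = i
        elif not m and in_run:
            in_run = False
            if i - start >= min_dwell:
                events.append(BindingEvent(ligand=ligand, start=start, end=i - 1))
    if in_run and mask.size - start >= min_dwell:
        events.append(BindingEvent(ligand=ligand, start=start, end=mask.size - 1))
    return events
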