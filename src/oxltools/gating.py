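"""Gate order parameters, H-bond traces, side-chain flips and state maps.

Alternating-access transporters open and close residue-pair "gates" on the
two membrane sides. Here the periplasmic gate (Thr38–Val240) and the
cytoplasmic gate (Met128–Pro332) Cα distances serve as order parameters: a
2-D histogram over the two distances maps the conformational landscape,
and frames are classified against reference points (e.g. the occluded and
outward-facing crystal forms). The module also tracks single hydrogen
bonds by heavy-atom distance, detects side-chain flips with a hysteresis
two-state classifier, and segments a trajectory into stages from joint
state labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trajectories import Trajectory, pairwise_distance

__all__ = [
    "GateDefinition",
    "GateTrace",
    "HBondTrace",
    "FlipEvent",
    "StateAssignment",
    "Stage",
    "gate_trace",
    "hbond_trace",
    "detect_flip",
    "conformation_landscape",
    "stage_segmentation",
]

#: Residue pairs used as gate order parameters in this system (Cα atoms).
DEFAULT_GATES = {
    "periplasmic": ((38, "CA"), (240, "CA")),
    "cytoplasmic": ((128, "CA"), (332, "CA")),
}


@dataclass(frozen=True)
class GateDefinition:
    """One residue-pair order parameter; each spec is (chain, resnum, atom)."""

    label: str
    atom_a: tuple[str, int, str]
    atom_b: tuple[str, int, str]

    @classmethod
    def calpha(cls, label: str, chain: str, res_a: int, res_b: int) -> "GateDefinition":
        return cls(label, (chain, res_a, "CA"), (chain, res_b, "CA"))


@dataclass
class GateTrace:
    """Per-frame distance for each named gate; shape (n_frames, n_gates)."""

    distances: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances <= 0):
            raise ValueError("gate distances must be positive")

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]

    def series(self, label: str) -> np.ndarray:
        return self.distances[:, self.labels.index(label)]


@dataclass
class HBondTrace:
    """Donor–acceptor heavy-atom distance with an inclusive on/off cutoff."""

    distance: np.ndarray
    cutoff: float

    @property
    def bonded(self) -> np.ndarray:
        return self.distance <= self.cutoff


@dataclass(frozen=True)
class FlipEvent:
    """A two-state transition of a 1-D coordinate (e.g. a side-chain flip)."""

    onset: int
    coordinate: str
    pre_state: str
    post_state: str
    dwell_before: int
    dwell_after: int


@dataclass
class StateAssignment:
    """Per-frame conformational labels with the reference points used."""

    labels: np.ndarray  # array of str
    references: dict[str, tuple[float, float]]
    radius: float

    def fraction(self, state: str) -> float:
        return float(np.mean(self.labels == state))


@dataclass(frozen=True)
class Stage:
    """Contiguous frame interval [start, end] sharing one joint label."""

    start: int
    end: int  # inclusive
    label: str

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


def gate_trace(traj: Trajectory, gates: Sequence[GateDefinition]) -> GateTrace:
    """Pairwise gate distances per frame (minimum-image when boxed)."""
    topo = traj.topology
    pairs = [
        (topo.find_atom(*g.atom_a), topo.find_atom(*g.atom_b)) for g in gates
    ]
    out = np.empty((traj.n_frames, len(gates)))
    for f in range(traj.n_frames):
        frame = traj.frame(f)
        box = traj.frame_box(f)
        for j, (ia, ib) in enumerate(pairs):
            out[f, j] = pairwise_distance(frame[ia], frame[ib], box)
    return GateTrace(distances=out, labels=[g.label for g in gates])


def hbond_trace(
    traj: Trajectory,
    donor: tuple[str, int, str],
    acceptor: tuple[str, int, str],
    cutoff: float = 3.5,
) -> HBondTrace:
    """Heavy-atom H-bond distance series (e.g. Thr38 OG1 to Val240 O).

    The criterion is distance-only: bonded when donor–acceptor distance ≤
    cutoff (3.5 Å default). Angles are deliberately not evaluated.
    """
    topo = traj.topology
    i_d = topo.find_atom(*donor)
    i_a = topo.find_atom(*acceptor)
    dist = np.array([
        pairwise_distance(traj.frame(f)[i_d], traj.frame(f)[i_a], traj.frame_box(f))
        for f in range(traj.n_frames)
    ])
    return HBondTrace(distance=dist, cutoff=cutoff)


def detect_flip(
    series: np.ndarray,
    low: float | None = None,
    high: float | None = None,
    min_dwell: int = 50,
    coordinate: str = "coordinate",
    state_names: tuple[str, str] = ("low", "high"),
) -> list[FlipEvent]:
    """Two-state transitions of a 1-D series with hysteresis and debouncing.

    The state changes only when the series crosses the *far* threshold
    (above ``high`` to enter the high state, below ``low`` to return), so
    noise between the thresholds cannot toggle the state. Transitions whose
    new state persists fewer than ``min_dwell`` frames are discarded in
    pairs, which preserves strict alternation of directions. Thresholds
    default to the 25th/75th percentiles of the series.
    """
    series = np.asarray(series, dtype=float)
    if low is None or high is None:
        q25, q75 = np.percentile(series, [25, 75])
        low = q25 if low is None else low
        high = q75 if high is None else high
    if not low < high:
        raise ValueError(f"thresholds must satisfy low < high, got {low} >= {high}")
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")

    state = 0 if series[0] < 0.5 * (low + high) else 1
    transitions: list[tuple[int, int]] = []  # (onset frame, new state)
    for i, x in enumerate(series):
        if state == 0 and x > high:
            state = 1
            transitions.append((i, 1))
        elif state == 1 and x < low:
            state = 0
            transitions.append((i, 0))

    # debounce: drop transition pairs whose intermediate dwell is too short
    changed = True
    while changed:
        changed = False
        for k in range(len(transitions) - 1):
            if transitions[k + 1][0] - transitions[k][0] < min_dwell:
                del transitions[k:k + 2]
                changed = True
                break
    if transitions and series.size - transitions[-1][0] < min_dwell:
        transitions.pop()

    events: list[FlipEvent] = []
    prev_onset = 0
    for k, (onset, new_state) in enumerate(transitions):
        next_onset = transitions[k + 1][0] if k + 1 < len(transitions) else series.size
        events.append(FlipEvent(
            onset=onset,
            coordinate=coordinate,
            pre_state=state_names[1 - new_state],
            post_state=state_names[new_state],
            dwell_before=onset - prev_onset,
            dwell_after=next_onset - onset,
        ))
        prev_onset = onset
    return events


def conformation_landscape(
    trace: GateTrace,
    references: Mapping[str, tuple[float, float]],
    bin_width: float = 0.5,
    radius: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, StateAssignment]:
    """2-D histogram over the two gate distances plus a state assignment.

    Returns ``(hist, x_edges, y_edges, assignment)``. The histogram counts
    sum to ``n_frames``. Each frame is labelled with the reference state
    whose (periplasmic, cytoplasmic) point is nearest, provided both axis
    deviations are within ``radius`` Å; otherwise "intermediate".
    """
    if trace.distances.shape[1] != 2:
        raise ValueError("conformation_landscape needs exactly two gates")
    if not references:
        raise ValueError("at least one reference state is required")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    x = trace.distances[:, 0]
    y = trace.distances[:, 1]

    def _edges(v: np.ndarray) -> np.ndarray:
        lo = np.floor(v.min() / bin_width) * bin_width
        hi = np.ceil(v.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        return np.arange(lo, hi + 0.5 * bin_width, bin_width)

    x_edges = _edges(x)
    y_edges = _edges(y)
    hist, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))

    names = list(references)
    pts = np.array([references[n] for n in names])  # (K, 2)
    dx = x[:, None] - pts[None, :, 0]
    dy = y[:, None] - pts[None, :, 1]
    within = (np.abs(dx) <= radius) & (np.abs(dy) <= radius)
    d2 = dx**2 + dy**2
    d2[~within] = np.inf
    nearest = np.argmin(d2, axis=1)
    labels = np.array([
        names[k] if np.isfinite(d2[i, k]) else "intermediate"
        for i, k in enumerate(nearest)
    ])
    assignment = StateAssignment(
        labels=labels,
        references={n: tuple(map(float, references[n])) for n in names},
        radius=radius,
    )
    return hist, x_edges, y_edges, assignment


def stage_segmentation(
    state_labels: Sequence[str],
    dihedral_labels: Sequence[str] | None = None,
    min_stage: int = 1,
) -> list[Stage]:
    """Partition frames into maximal runs of the joint state label.

    The joint label is ``conformation|dihedral-state`` when a second series
    is given. Runs shorter than ``min_stage`` are merged into the preceding
    stage (the first run merges forward instead). The returned stages
    always partition [0, n_frames) exactly.
    """
    state_labels = list(state_labels)
    if not state_labels:
        raise ValueError("empty label series")
    if dihedral_labels is not None:
        if len(dihedral_labels) != len(state_labels):
            raise ValueError("label series lengths differ")
        joint = [f"{a}|{b}" for a, b in zip(state_labels, dihedral_labels)]
    else:
        joint = state_labels

    runs: list[Stage] = []
    start = 0
    for i in range(1, len(joint) + 1):
        if i == len(joint) or joint[i] != joint[start]:
            runs.append(Stage(start=start, end=i - 1, label=joint[start]))
            start = i

    if min_stage > 1:
        merged: list[Stage] = []
        for run in runs:
            if run.n_frames < min_stage and merged:
                prev = merged[-1]
                merged[-1] = Stage(start=prev.start, end=run.end, label=prev.label)
            else:
                merged.append(run)
        # a short leading run merges forward into its successor
        if merged and merged[0].n_frames < min_stage and len(merged) > 1:
            nxt = merged[1]
            merged[0:2] = [Stage(start=merged[0].start, end=nxt.end, label=nxt.label)]
        # absorbing short runs can leave equal-label neighbours; coalesce them
        coalesced: list[Stage] = []
        for run in merged:
            if coalesced and coalesced[-1].label == run.label:
                prev = coalesced[-1]
                coalesced[-1] = Stage(start=prev.start, end=run.end, label=prev.label)
            else:
                coalesced.append(run)
        runs = coalesced
    return runs
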