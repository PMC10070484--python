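"""Oxalate O-C-C-O torsion traces, oxygen-equivalence folding and state peaks.

The torsion about the oxalate C–C bond distinguishes a planar ion (0°)
from perpendicular carboxylates (90°). Because each carboxylate carries
two equivalent oxygens, a measured torsion φ and 180° − φ describe the
same physical conformer under the alternate oxygen choice; the folding
convention here reports both and flags the smaller magnitude as canonical
(so a 40–50° state and its 130–140° image are recognised as one state).
Histograms are built on |φ| with light smoothing and prominence-based
peak detection, enough to resolve e.g. a double-peaked 60°/120° population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .trajectories import DihedralTrace, Trajectory, dihedral_angle

__all__ = [
    "FoldedAngle",
    "TorsionStateReport",
    "occo_trace",
    "fold_equivalent",
    "torsion_histogram",
]


@dataclass(frozen=True)
class FoldedAngle:
    """A torsion magnitude and its alternate-oxygen equivalent.

    ``canonical`` is the smaller of |φ| and 180° − |φ|; at 90° the pair is
    self-dual and the raw value is canonical.
    """

    raw_abs: float
    alternate: float

    @property
    def canonical(self) -> float:
        return min(self.raw_abs, self.alternate)

    @property
    def canonical_is_raw(self) -> bool:
        return self.raw_abs <= self.alternate


@dataclass
class TorsionStateReport:
    """|φ| histogram with smoothed-peak positions (degrees)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: list[float]
    smoothing_bins: int
    prominence_fraction: float
    folded: bool

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())


def occo_trace(
    traj: Trajectory,
    ligand_group: str,
    atom_names: Sequence[str] = ("O1", "C1", "C2", "O2"),
) -> DihedralTrace:
    """Per-frame signed O-C-C-O torsion of one ligand.

    ``atom_names`` picks one oxygen per carboxylate plus the two carbons,
    in chain order, within the ligand's atom group. Which oxygen pair is
    tracked is the caller's naming choice; use :func:`fold_equivalent` to
    relate the two possible conventions.
    """
    topo = traj.topology
    group = topo.group(ligand_group)
    quad = []
    for name in atom_names:
        hits = [int(i) for i in group if topo.atoms[i].atom_name == name]
        if not hits:
            raise ValueError(f"atom {name!r} not found in group {ligand_group!r}")
        if len(hits) > 1:
            raise ValueError(f"atom name {name!r} ambiguous in group {ligand_group!r}")
        quad.append(hits[0])
    phi = np.array([
        dihedral_angle(f[quad[0]], f[quad[1]], f[quad[2]], f[quad[3]]) for f in traj
    ])
    return DihedralTrace(phi=phi, atom_quadruple=tuple(quad))


def fold_equivalent(phi: float) -> FoldedAngle:
    """Alternate-oxygen equivalent of a torsion angle.

    For φ in (−180, 180], returns |φ| and 180° − |φ|: swapping which
    oxygen of a carboxylate is tracked maps one onto the other.
    """
    if not (-180.0 < phi <= 180.0):
        raise ValueError(f"torsion {phi} outside (-180, 180]")
    raw = abs(phi)
    return FoldedAngle(raw_abs=raw, alternate=180.0 - raw)


def torsion_histogram(
    trace: DihedralTrace,
    bin_width: float = 5.0,
    smoothing_bins: int = 3,
    prominence_fraction: float = 0.1,
    fold: bool = False,
) -> TorsionStateReport:
    """Histogram of |φ| over [0°, 180°] with moving-average peak detection.

    Peaks are local maxima of the smoothed counts with prominence at least
    ``prominence_fraction`` × the maximum smoothed count, reported at bin
    centres. With ``fold=True`` angles are first canonicalised via
    :func:`fold_equivalent`, making the peaks invariant to the oxygen-pair
    labelling (at the cost of folding 0–180° onto 0–90°).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(trace) == 0:
        raise ValueError("empty torsion trace")
    values = trace.abs_phi
    if fold:
        values = np.minimum(values, 180.0 - values)
    edges = np.arange(0.0, 180.0 + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)

    if smoothing_bins > 1:
        kernel = np.ones(smoothing_bins)
        # edge-corrected moving average: divide by the actual window coverage
        # so boundary bins are not artificially depressed
        smoothed = np.convolve(counts, kernel, mode="same") / np.convolve(
            np.ones_like(counts, dtype=float), kernel, mode="same"
        )
    else:
        smoothed = counts.astype(float)
    if smoothed.max() > 0:
        idx, _ = find_peaks(smoothed, prominence=prominence_fraction * smoothed.max())
    else:
        idx = np.array([], dtype=int)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TorsionStateReport(
        bin_edges=edges,
        counts=counts,
        peaks=[float(centers[i]) for i in idx],
        smoothing_bins=smoothing_bins,
        prominence_fraction=prominence_fraction,
        folded=fold,
    )
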