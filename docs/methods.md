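# Methods

This note documents the models, conventions and numerical choices behind
`oxltools`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what each procedure assumes, which knobs matter,
and what the synthetic-data tests do and do not demonstrate.

## Scientific setting

OxlT, the oxalate:formate antiporter of the gut bacterium *Oxalobacter
formigenes*, is a major facilitator superfamily (MFS) transporter that
cycles between outward-facing, occluded and inward-facing conformations
(alternating access). The analyses here characterise that cycle from
molecular-dynamics trajectories and biochemical assay curves:

* **Ligand binding** — an oxalate ion is *bound* in a frame when the
  distance between the geometric centres of the ion and of the five
  binding-site residues (Gln34, Tyr35, Arg272, Tyr328, Lys355) is at most
  a cutoff, 5 Å by default. Occupancy is the fraction of frames with at
  least one bound ligand.
* **Gating** — the Cα distances of the periplasmic (Thr38–Val240) and
  cytoplasmic (Met128–Pro332) gate residue pairs serve as order
  parameters; a 2-D histogram over them maps the conformational
  landscape, and frames are classified against reference points taken
  from crystal structures.
* **Hydration** — water oxygens within 4, 8 and 15 Å of the bound ligand
  count the solvation of the pocket; a voxel grid of aligned water
  positions resolves where water is admitted or blocked.
* **Ligand conformation** — the O-C-C-O torsion about the oxalate C–C
  bond distinguishes the twisted bound conformer (~60°) from the
  solution conformer (~90°).
* **Thermal-shift assays** — melting curves from a GFP thermal-shift
  experiment are fitted with a two-state Gibbs–Helmholtz model to extract
  the apparent melting temperature Tm; the shift ΔTm on ligand addition
  measures binding. Transport time courses are summarised by their
  initial velocity.

## Models and conventions

### Superposition and RMSD

Rigid-body superposition uses the Kabsch SVD construction. When the
optimal orthogonal transform is a reflection (negative determinant), the
sign of the smallest singular vector is flipped, so the result is always
a proper rotation; this is asserted to 1e−9 in tests. Cα RMSD between two
structures pairs residues by (chain, author residue number); residues
present on only one side are dropped and reported, so "all residues"
comparisons are over the modelled intersection. Insertion codes are
rejected rather than guessed at. Alternate locations keep conformer 'A'
(or blank) only, giving deterministic single-conformer geometry.

### Distances and periodicity

Distances use the minimum-image convention only when an orthorhombic box
accompanies the trajectory; toy and synthetic systems without a box use
plain Euclidean geometry. Triclinic boxes are out of scope.

### Torsion angles

`dihedral_angle` uses the standard atan2 construction with the sign
convention of the mainstream MD toolchains (cross-checked against
MDAnalysis): torsions are invariant under atom-order reversal and negate
under mirror reflection, with range (−180°, 180°]. Because each oxalate
carboxylate has two equivalent oxygens, φ and 180° − φ describe the same
conformer under the alternate oxygen choice; `fold_equivalent` exposes
the pair and flags min(|φ|, 180° − |φ|) as canonical. Torsion histograms
are built on |φ| in 5° bins, smoothed with an edge-corrected 3-bin moving
average; peaks are local maxima with prominence ≥ 10% of the smoothed
maximum. The edge correction matters: an uncorrected `same`-mode moving
average depresses boundary bins and fabricates peaks on flat data.

### Binding criterion and occupancy

The bound criterion is inclusive (distance ≤ cutoff) — stated explicitly
because a bare "cutoff distance of 5 Å" leaves the boundary open. The
site centre uses heavy atoms of the site residues by default. Occupancy
is reported both for the site (any ligand bound) and per ligand. The
standard error uses a moving-block bootstrap (default block 100 frames,
1000 resamples, seeded) because frames are strongly autocorrelated; a
binomial SE would be badly overconfident. Event segmentation returns
maximal bound runs; runs shorter than `min_dwell` are treated as
excursions and merged into the surrounding unbound state.

### Flip detection and staging

Side-chain flips (e.g. the Gln34 latch) are detected on any 1-D
coordinate with a hysteresis two-state classifier: the state changes only
on crossing the far threshold, so noise between thresholds cannot
toggle it. Thresholds default to the series' 25th/75th percentiles and
`min_dwell` to 50 frames; transitions whose new state persists less than
`min_dwell` are discarded in pairs, which preserves strict alternation
of event directions. The coordinate is deliberately caller-chosen
(distance of the side-chain amide centroid from the site centre, a χ
dihedral, …) since no single convention is canonical.

Stage segmentation partitions frames into maximal runs of a joint
(conformation, torsion-state) label; runs shorter than `min_stage` merge
into the preceding stage (a short leading run merges forward), and
equal-label neighbours produced by the merging are coalesced. The result
always partitions [0, n_frames) exactly.

### Landscape classification

Frames are labelled with the nearest reference state in the gate-distance
plane, accepted only if both axis deviations are within a radius (default
1.5 Å); otherwise "intermediate". Reference points are supplied by the
caller (typically computed from crystal structures), never hard-coded.

### Gibbs–Helmholtz fit

The folded fraction is f(T) = 1 / (1 + exp(−ΔG(T)/RT)) with

    ΔG(T) = ΔH·(1 − T/Tm) − ΔCp·[(Tm − T) + T·ln(T/Tm)],

ΔH in kcal/mol at Tm, ΔCp in kcal/mol/K, R = 1.987204×10⁻³ kcal/mol/K.
Signals are normalised so the unheated sample is 1 and background 0;
out-of-range values are preserved (clamping would bias the fit) and
normalised fluorescence is identified with the folded fraction — no
separate baseline slopes are fitted, since the normalisation already
anchors both plateaus. Fitting is unweighted nonlinear least squares
(`scipy.optimize.curve_fit`): initial Tm from the 0.5 crossing (linear
interpolation), ΔH = 100 kcal/mol, ΔCp = 0. ΔCp is freely fitted but can
be pinned to 0 (`fix_dcp`), the recommended guard on the typical 30–80 °C
range where ΔCp is ill-conditioned. Curves whose normalised span is
below 0.3 carry no usable transition and return an unconverged fit with
NaN parameters instead of a number. ΔTm standard errors add in
quadrature from the per-fit Jacobian SEs.

### Initial rates

Ordinary least squares over points with t ≤ 600 s (configurable),
requiring at least three in-window points. R² is reported so saturated or
curved traces are visible.

## Synthetic data: what it emulates, what it does not

`oxltools.synthetic` generates trajectories whose generating process is
known exactly per frame, enabling closure tests (estimate vs planted
value) for every analysis:

* **Binding** is a per-ligand two-state telegraph process started from
  its stationary distribution. Bound frames put the ligand centroid at
  the site centre + isotropic Gaussian (σ = 1 Å, so the 5 Å criterion
  captures > 99.99% of bound frames); unbound frames sample a 10–20 Å
  shell, which the validator requires to clear cutoff + 3σ. As a result
  the analysis mask reproduces the planted states *exactly*, and
  recovery tests probe the estimator statistics, not geometric slop.
  Two presets mirror the study regimes: a high-affinity site
  (stationary bound probability 0.986, rare unbinding) and an exchanging
  site (0.770, visible binding/unbinding traffic). The desk-scale
  default is 1000 frames at 1 ns/frame with 3 ligands.
* **Gates** are pseudo-atom pairs on a fixed axis whose separation is a
  two-state Gaussian process (defaults: closed 6 Å / open 10 Å, σ =
  0.3 Å — a ≫ 6σ separation, where classification should be
  essentially error-free).
* **Waters** are single pseudo-oxygens (matching the one-count-per-
  molecule convention) with per-frame Poisson counts placed uniformly in
  concentric shells around a central probe atom; surplus waters park in
  a far reservoir so the topology is constant. Shell counts measured
  against the probe equal the planted counts exactly.
* **Torsion** states are wrapped-normal mixtures keyed to the
  conformational state (occluded-like: 50°/130°; outward-like:
  60°/120°), realised by twisting a 4-atom O-C-C-O template about its
  C–C bond; the realised torsion equals the sampled value to machine
  precision.
* **Melting curves** are gh_model plus iid Gaussian noise (σ = 0.02 by
  default).

All randomness flows through a single `numpy.random.default_rng(seed)`;
identical specs are bit-identical.

The generator plants *geometry*, not physics: no forces, no protein
internal motion beyond the gate and torsion coordinates, no correlated
water structure, no drift or baseline artefacts in assay curves. Passing
closure tests therefore demonstrates the estimators are correct and
well-calibrated under the stated noise models — not that the criteria
are optimal for real force-field output, where excursion frames near the
cutoff, broken hydrogen-bond geometries and baseline drifts occur.

## Problem sizes

Recovery tests run at 4000–6000 frames per condition and the acceptance
script at 10 000 frames × 8 replicate trajectories per binding regime,
100 (tests) or 50 (script) melting-curve replicates, and a 10⁴
random-rotation oracle for superposition optimality. These sizes put
Monte-Carlo error comfortably inside the 3-standard-error acceptance
bands; binding occupancy is averaged over replicate trajectories because
telegraph dwell times (up to ~2000 frames in the high-affinity regime)
make single-trajectory occupancy estimates heavy-tailed.

## Known limitations

* Reference numbers tied to the deposited crystal structures (PDB 8HPK /
  8HPJ) and archived trajectories (Zenodo 7597686) can only be checked
  when that data is reachable; the corresponding tests fail with a clear
  diagnostic otherwise rather than silently skipping.
* PDB output rounds coordinates to 10⁻³ Å; pipelines that round-trip
  through PDB can flip the bound state of frames lying exactly on the
  cutoff.
* The hydrogen-bond criterion is distance-only (donor–acceptor heavy
  atoms, ≤ 3.5 Å); no angular term.
* Water density grids align on a Kabsch fit of the align group and
  assume an orthorhombic (or absent) box.
* The Gibbs–Helmholtz parameterisation assumes two-state unfolding;
  intermediates or aggregation-coupled unfolding bias Tm.
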