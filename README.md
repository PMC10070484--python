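# oxltools

Analysis toolkit for the alternating-access cycle of OxlT, the
oxalate:formate antiporter of the gut bacterium *Oxalobacter formigenes*
— and, more generally, for any MFS-type transporter studied with
molecular-dynamics trajectories and thermal-shift binding assays.

Oxalate-degrading gut bacteria take up dietary oxalate through OxlT,
lowering the host's kidney-stone risk. Characterising how OxlT binds
oxalate and switches between outward-facing, occluded and inward-facing
conformations involves a recurring set of post-processing steps. This
package implements them as a tested library plus a thin CLI:

* **structures** — PDB I/O, atom selection, Kabsch superposition, Cα RMSD
  between conformations, residue composition (e.g. the glycine fraction
  behind helix bending).
* **trajectories** — trajectory model (multi-model PDB natively, DCD/XTC
  via MDAnalysis) and geometry kernels: geometric centres, torsions,
  per-frame RMSD, hydration-shell counts, aligned water-density grids.
* **binding** — the geometric-centre bound criterion (ligand-to-site
  centre distance ≤ 5 Å by default), occupancy with moving-block
  bootstrap errors, binding/unbinding event segmentation.
* **gating** — gate order parameters (periplasmic Thr38–Val240 and
  cytoplasmic Met128–Pro332 Cα distances), hydrogen-bond traces,
  hysteresis flip detection, the 2-D conformational landscape with state
  classification, and trajectory stage segmentation.
* **ligandconf** — oxalate O-C-C-O torsion traces, the alternate-oxygen
  equivalence (φ ↔ 180° − φ), torsion-state histograms with peak
  detection.
* **assays** — melting-curve normalisation, two-state Gibbs–Helmholtz
  fitting (Tm, ΔH, ΔCp), ΔTm with propagated errors, initial-rate
  regression of transport time courses.
* **synthetic** — seeded generators that plant telegraph binding,
  two-state gates, shell-structured waters, torsion mixtures and noisy
  melting curves with exactly known ground truth.

The central statistics, in brief: a ligand is *bound* when
|centre(ligand) − centre(site)| ≤ d_c (d_c = 5 Å); occupancy is the
fraction of frames with a bound ligand. Melting curves are fitted with
f(T) = 1/(1 + e^(−ΔG/RT)), ΔG(T) = ΔH(1 − T/Tm) − ΔCp[(Tm − T) +
T ln(T/Tm)]. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

Generate a trajectory with a planted exchanging binding site, measure
occupancy, and fit a pair of synthetic melting curves:

```python
import numpy as np
from oxltools.synthetic import (SyntheticTrajectorySpec, generate_trajectory,
                                generate_melting_curve)
from oxltools.binding import BindingConfig, binding_trace, occupancy, segment_events
from oxltools.assays import fit_gh, delta_tm

spec = SyntheticTrajectorySpec.low_occupancy(seed=7, n_frames=5000, n_ligands=1)
traj, truth = generate_trajectory(spec)
trace = binding_trace(traj, BindingConfig(ligand_groups=["ligand_1"]))
rep = occupancy(trace, bootstrap=True, seed=0)
events = segment_events(trace.bound[:, 0], min_dwell=1)
print(f"measured occupancy:  {rep.occupancy:.4f}")
print(f"planted occupancy:   {truth.occupancy_site:.4f} "
      f"(stationary p = {truth.stationary_bound_probability:.3f})")
print(f"binding events: {len(events)}; longest dwell: "
      f"{max(e.dwell for e in events)} frames")

grid = np.linspace(303.0, 353.0, 26)
apo, _ = generate_melting_curve(320.0, 120.0, 0.0, grid, 0.02, seed=1)
holo, _ = generate_melting_curve(324.0, 120.0, 0.0, grid, 0.02, seed=2)
fit = fit_gh(apo, fix_dcp=True)
print(f"apo Tm: {fit.tm:.2f} +/- {fit.se_tm:.2f} K (planted 320 K)")
shift, se = delta_tm(fit_gh(holo, fix_dcp=True), fit)
print(f"delta Tm: {shift:+.2f} +/- {se:.2f} K (planted +4 K)")
```

Output:

```
measured occupancy:  0.9064
planted occupancy:   0.9064 (stationary p = 0.770)
binding events: 5; longest dwell: 1592 frames
apo Tm: 320.05 +/- 0.08 K (planted 320 K)
delta Tm: +3.96 +/- 0.11 K (planted +4 K)
```

The measured occupancy equals the planted per-frame truth exactly — the
generator places bound/unbound ligands so the 5 Å criterion is decisive —
while the single-trajectory value (0.906) differs from the stationary
probability (0.770) because binding dwell times span hundreds of frames;
averaging over replicate trajectories recovers the stationary value
(see the acceptance script below). The Tm and ΔTm fits recover the
planted thermodynamics within their standard errors.

The same pipeline runs from the shell:

```sh
oxlt simulate --seed 7 --n-frames 1000 --out sim
oxlt binding --coords sim.traj.pdb --site resname:SIT \
     --ligand resname:OXL --cutoff 5 --out bind
oxlt gates --coords sim.traj.pdb --gate peri:A/38/CA-A/240/CA \
     --gate cyto:A/128/CA-A/332/CA --ref occluded:6.0,7.0 \
     --ref outward:10.0,9.0 --out gates
```

Each run writes TSV/JSON artifacts and a manifest echoing all parameters.

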