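# Methods

## System and observables

The package analyses trajectories of a lipid-anchored peripheral protein on
a planar two-leaflet bilayer whose normal is the +z axis.  The archetype is
farnesylated, GTP-bound KRas-4B on an anionic DOPC/DOPS (4:1) membrane with
0% or 30% cholesterol: a catalytic domain (residues 1–166) tethered by a
flexible hypervariable region (HVR, residues 167–185) whose C-terminal
farnesyl group (FAR) anchors into the inner leaflet.  All lengths are nm,
angles degrees, times ps.  PDB input (Å) is converted on read; only
orthorhombic boxes are supported and triclinic input is rejected explicitly,
which keeps every periodic-image computation exact and testable.

### Bilayer structure

* Leaflets are split by the sign of `z − median(z_P)` over the lipid
  phosphorus atoms.  The median split (rather than the sign of z) is robust
  when the bilayer drifts from the box centre and is deterministic.
* The bilayer centre `z0` is the mean z of all lipid phosphates per frame;
  phosphorus is used because it is the head-group marker the thickness
  definition is phrased in.
* Area per lipid `A = Lx·Ly / N_leaflet`, where `N_leaflet` counts **all**
  amphiphiles in one leaflet, cholesterol analogues included.  A single A is
  therefore reported for mixed membranes; a per-species (Voronoi) partial
  area is out of scope.  This convention is recorded in the run summary.
* Thickness `Δz = ⟨z_P⟩_upper − ⟨z_P⟩_lower`.
* Time averages are taken over an analysis window defaulting to the final
  50% of frames (the equilibrated second half of a production run);
  uncertainties are standard errors of contiguous block means (default 10
  blocks), the conservative choice for time-correlated series — for an
  AR(1)-correlated signal the block error exceeds the naive i.i.d. standard
  error, which the suite checks.

### Depth profiles

A moiety's depth is the signed distance of its **unweighted geometric
centre** (not mass-weighted) from `z0` along the normal, positive toward
the protein-bearing leaflet (the sign is fixed by which side of `z0` a
reference selection sits on in the first frame).  Preferred localisations
are the local maxima of the 0.1-nm-bin depth histogram, keeping peaks with
at least 25% of the highest bin's probability; 0.1 nm resolves the reported
anchored localisations (1.30 vs 1.73 nm) while staying populated at
few-hundred-frame sample sizes.

### Anchor-motif RMSD

The conformational flexibility of the 5-residue HVR motif (K-S-K-T-K,
residues 180–184) is measured as `RMSD = sqrt((1/n) Σ_i d_i²)` over atom
pairs after optimal **proper** rigid superposition (Kabsch via SVD with the
determinant correction; reflections excluded), so rigid tumbling of the
protein contributes nothing.  The default atom set is the backbone
(N, CA, C, O — the common convention for short-peptide conformational
RMSD); the reference is the first frame of the analysis window, which is
deterministic and recorded in the output.

### Orientation order parameters and states

* `z` — the Cα132–Cα183 separation, linking lobe 2 of the catalytic domain
  to the membrane-proximal HVR.  The default is the literal 3D Euclidean
  distance; a normal-projection mode (`|Δz|`) is selectable by config since
  the source definition does not disambiguate.  Intramolecular vectors are
  never minimum-image wrapped: the protein is assumed whole (unwrapped), and
  wrapping an internal vector would corrupt the angles.
* `Θ` — angle between the membrane normal and the β1-strand vector
  Cα5→Cα9; `Φ` — angle between the normal and the α5-helix vector
  Cα156→Cα163.  Both vectors run N→C along the backbone, the one convention
  consistent across the two vectors; flipping a vector maps an angle to its
  supplement, so the convention is written into the run summary.
* Orientation states are assigned by nearest centre in the (z, cosΘ) plane,
  with centres OS1 (1.86, −0.5), OS2 (4.97, 1), OS0 (3.33, 0.9).  Only the
  centres, not the basin boundaries, are published, so a normalised
  Euclidean distance is used with per-axis scales z_scale = 5 nm (a
  plausible z span) and cos_scale = 2 (the full cosine range), both
  configurable; ties break deterministically OS1 → OS0 → OS2.
* Density maps are probability-normalised 2D histograms (default 50×50 bins
  over the data range padded 5%; per-bin probability rather than counts) with
  marginal distributions and the argmax bin centre as the mode, ties to the
  lowest bin indices.

### Radial distribution functions

`g(r)` histograms minimum-image A–B distances in shells of width dr
(default 0.05 nm) up to `r_max ≤ min(box)/2`, normalised per frame by
`N_A · ρ_B · V_shell` with exact shell volumes; self-pairs are excluded
when the selections coincide.  A uniform ideal gas gives g = 1 within
sampling noise, and the integral of `ρ_B g(r) 4πr² dr` reproduces the mean
neighbour count — both are asserted in the suite.

## Synthetic trajectory generator

The generator produces the statistical structure the analyses assume, with
every target known exactly; it is first-class, tested code, not a fixture.

* **Slab**: one particle per amphiphile (a phosphate-like "P" particle per
  phospholipid, 4:1 DOPC/DOPS naming; a sterol-like "C3/CHOL" particle per
  cholesterol analogue), on a square lattice per leaflet at ±thickness/2.
  The lateral box is constructed as `Lx = Ly = sqrt(N_leaflet · A_target)`,
  so the area-per-lipid estimator inverts the construction exactly.
  Cholesterol presence rescales the target area by a condensation factor
  (presets use the ratio of the reported chol-30% to chol-0% areas).
  Gaussian jitter (default σ = 0.05 nm in presets) emulates thermal
  disorder; jitter ≥ half the leaflet spacing is rejected to keep leaflets
  identifiable.  Default 152 lipids per leaflet (304 total), matching the
  studied system size.
* **Protein**: a rigid pseudo-scaffold with one Cα per marker residue
  (5, 9, 132, 156, 163), backbone N/CA/C/O for HVR residues 180–184, and
  5-atom FAR and GTP clusters whose offsets sum to zero so their geometric
  centres are exact.  Body-fixed geometry: |β1| = 1.2 nm, |α5| = 1.05 nm,
  inter-vector angle γ = 60°, Cα132–Cα183 arm = 1.86 nm.
* **Placement**: for requested (Θ, Φ), a deterministic two-stage rotation
  puts β1 on the Θ-cone in the xz-plane, then rotates about β1 until α5
  meets the Φ-cone, choosing the non-negative out-of-plane solution (the
  smaller rotation) on ties.  The attainable Φ interval at given Θ is
  `[|Θ−γ|, min(Θ+γ, 360−Θ−γ)]`; infeasible requests raise an error naming
  that interval — placement never clamps silently, and accepted requests
  are realised to ≲1e-6°.  The FAR centre is translated to the requested
  depth; the GTP cluster, representing an independently bound ligand, is
  then shifted along z to its own depth.
* **Dynamics**: the anchor depth can follow a two-state discrete-time
  Markov switch between an inserted and a solvated level (preset
  1.73/3.90 nm, switch probability 0.02 per frame), the simplest process
  reproducing the observed bimodal anchoring/release behaviour.  Angles can
  follow a mean-reverting AR(1) process about the preset centre with
  stationary standard deviation σ_angle (presets 6–8°) and memory
  ρ = 0.95 (a ~20 ns orientational correlation time at 1 ns/frame),
  reflected into [0, 180]°; a mean-reverting process is used rather than a
  pure reflected random walk because the observed orientation densities are
  unimodal about a centre, which a driftless walk cannot reproduce.  Before
  placement, Φ is projected into the feasible interval (1° margin) given
  the current Θ, and the projected value is recorded as the request, so the
  ground-truth table always matches what was realised.
* **Determinism**: a single seeded generator drives everything; identical
  spec + seed give bitwise-identical trajectories and truth tables.

### Presets

Membrane targets are the reported per-system values (A: 0.679 / 0.523 /
0.679 / 0.525 nm²; Δz: 3.84 / 4.35 / 3.89 / 4.23 nm for wt-0%, wt-30%,
onc-0%, onc-30%).  Orientation centres: (80°, 105°) for onc-30%,
(99°, 83°) onc-0%, (59°, 52.5°) wt-0%, (53°, 37°) wt-30%.  Depths: wt-0%
FAR 1.30 / GTP 4.38 nm; wt-30% two-state FAR 1.73/3.90, GTP 2.39 nm;
onc-0% GTP 2.78 nm.  Two depth values are the package's own choices where
only relative information is reported: onc-0% FAR is set to 1.47 nm so the
onc-30% anchor (1.30 nm) is 0.17 nm deeper, and the onc-30% GTP depth is
set to 4.38 nm to represent domain-bound GTP by analogy with the wt-0%
value.

### What the generator does and does not emulate

It reproduces the *observables*' statistical structure: exact bilayer
geometry targets, bimodal anchoring, drifting unimodal orientation
densities, known marker geometry.  It does **not** model lipid chemistry,
solvent, electrostatics, or internal protein flexibility — the scaffold is
rigid, so the z order parameter is constant at 1.86 nm (the active-state
value) and orientation-state labels on synthetic runs discriminate via cosΘ
only; the OS0/OS2 basins at other z values are exercised through directly
synthesised (z, cosΘ) records in the suite.  Likewise the HVR-motif RMSD on
synthetic runs measures the coordinate-noise floor, not conformational
dynamics.  Passing tests therefore demonstrate correctness of the
estimators and pipeline plumbing under known truth, not fidelity of any MD
force field.

## Problem sizes and numerical choices

The analysis drivers default to 600-frame runs (3000 frames for the
two-state anchoring preset, so both depth states are well sampled at ~60
expected switches; 1500 frames for orientation densities), 339 particles —
sizes at which every statistical check has comfortable power while a full
driver or acceptance run completes in seconds.  Histogram modes for drifting
angles use 8–12 bins: with ρ = 0.95 the effective sample count is ~2.5% of
the frame count, and finer bins would make the sample mode an unreliable
estimator of the stationary mode.  Tolerances follow from the generator:
noise-free recoveries are asserted to 1e-6 (placement tolerance), jittered
recoveries to 3-sigma CLT bounds derived from the jitter, and histogram
modes to one bin width.

## Known limitations

* Orthorhombic boxes only; no velocities, forces, topology or bond
  perception.
* Whole-molecule unwrapping is assumed for the protein, not performed.
* OS basin geometry is a nearest-centre model with configurable scales, not
  a free-energy-based partition; no kinetics or Markov-state modelling.
* Area per lipid is a single lateral-area quotient; no Voronoi/partial
  areas, deuterium order parameters or undulation spectra.
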