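# memorient

Trajectory analysis of how a lipid-anchored peripheral protein — modelled on
farnesylated, GTP-bound KRas-4B — sits on an anionic lipid bilayer, and how
membrane cholesterol shifts it between orientation states.  The package is
aimed at molecular-simulation practitioners who want the full chain of
membrane/orientation observables as a reusable, tested library rather than
one-off analysis scripts, together with a synthetic trajectory generator that
makes every stage verifiable against known ground truth without running MD.

## What it computes

Given a multi-frame coordinate trajectory (GRO or multi-model PDB) and a
declarative atom-selection config:

* **Bilayer structure** — leaflet assignment by median phosphate z, area per
  lipid `A = Lx·Ly / N_leaflet` (all amphiphiles counted), thickness
  `Δz = ⟨z_P,upper⟩ − ⟨z_P,lower⟩`, time averages with block-averaged
  standard errors, and percent-change comparisons (sterol condensation).
* **Moiety depth profiles** — signed distance of the farnesyl (FAR) and GTP
  geometric centres from the bilayer centre along the normal; histogram
  modes as "preferred localisations".
* **Anchor-motif RMSD** — Kabsch-superposed RMSD
  `RMSD = sqrt((1/n) Σ d_i²)` of the 5-residue HVR motif (K-S-K-T-K,
  residues 180–184) against a reference frame.
* **Orientation order parameters** — per frame:
  `z` = |Cα132 − Cα183| (nm), `Θ` = angle(normal, Cα5→Cα9),
  `Φ` = angle(normal, Cα156→Cα163); 2D probability maps over (z, cosΘ) and
  (Θ, Φ) with marginals and modes; nearest-centre classification into the
  orientation states OS1 (1.86, −0.5), OS2 (4.97, 1), OS0 (3.33, 0.9) and
  their occupancies.
* **Radial distribution functions** — g(r) between named selections under
  minimum-image periodicity, ideal-gas normalised.

The `memorient.synthetic` module generates ground-truthed pseudo-trajectories
(304-lipid two-leaflet slab, rigid pseudo-protein scaffold placed at exactly
requested (Θ, Φ) and anchor depth, two-state anchoring dynamics, drifting
orientations) with presets for the four studied systems
(`wt_chol0`, `wt_chol30`, `onc_chol0`, `onc_chol30`).

## Worked example

```sh
memorient synth --preset wt_chol30 --seed 3 --n-frames 40 --out t.gro
memorient membrane-metrics --traj t.gro --blocks 5 --out m.csv
memorient depth --traj t.gro --moiety far_group --out d.csv
```

prints (stderr log):

```
[memorient] wrote 40 frames to t.gro; truth: t.gro.truth.csv; spec: t.gro.spec.json
[memorient] A = 0.5230 (0.0000) nm^2, dz = 4.349 (0.002) nm -> m.csv
[memorient] far_group: mean 1.730 nm, preferred localisations [1.75] nm -> d.csv
```

`A = 0.523 nm²` and `Δz = 4.35 nm` recover this preset's membrane targets
(the 30%-cholesterol condensed bilayer) exactly up to the lipid jitter, and
the farnesyl anchor sits at its inserted localisation ≈1.73 nm from the
bilayer centre.  A longer run of the same preset also populates the solvated
level near 3.90 nm, giving the bimodal depth histogram; the oncogenic
chol-30% preset (`memorient run --preset onc_chol30 ...`) reports majority
OS1 occupancy with the (Θ, Φ) mode near (80°, 105°).

The same analyses are available as a library (see `analysis/01…06_*.py` for
narrative drivers writing tables under `results/`), and as one orchestrated
run: `memorient run --preset onc_chol30 --seed 1 --outdir results/run`
writes per-stage CSVs plus a `summary.json` keyed by a config hash.

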