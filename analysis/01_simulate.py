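#!/usr/bin/env python
"""Generate the four study-condition synthetic trajectories.

Emulates the wild-type / oncogenic protein on cholesterol-free and
30%-cholesterol anionic membranes: bilayer structure targets from the
reported per-system table, anchor-depth and orientation-centre targets from
the reported localisations.  Trajectories (multi-frame GRO) and ground-truth
tables go to scratch/trajectories/ (large, regenerable); a manifest of what
was generated goes to results/.

Usage: python analysis/01_simulate.py [--frames N] [--seed S]
"""

import argparse
from pathlib import Path

import pandas as pd

from memorient import PRESETS, generate_trajectory, preset_spec, write_trajectory

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--frames", type=int, default=600)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    outdir = ROOT / "scratch" / "trajectories"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, name in enumerate(sorted(PRESETS)):
        spec = preset_spec(name, seed=args.seed + i, n_frames=args.frames)
        frames, truth = generate_trajectory(spec)
        traj = outdir / f"{name}.gro"
        write_trajectory(frames, traj)
        truth.to_csv(outdir / f"{name}.truth.csv", index=False)
        rows.append(dict(preset=name, n_frames=len(frames),
                         n_atoms=frames[0].n_atoms,
                         target_apl=spec.effective_apl,
                         target_thickness=spec.target_thickness,
                         theta=spec.theta, phi=spec.phi, seed=spec.seed,
                         path=str(traj.relative_to(ROOT))))
        print(f"{name}: {len(frames)} frames, {frames[0].n_atoms} atoms "
              f"-> {traj}")
    manifest = ROOT / "results" / "simulation_manifest.csv"
    manifest.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(manifest, index=False)
    print(f"manifest -> {manifest}")


if __name__ == "__main__":
    main()
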