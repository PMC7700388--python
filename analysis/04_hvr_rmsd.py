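#!/usr/bin/env python
"""Internal conformational RMSD of the 5-residue HVR motif (K-S-K-T-K).

Superposed RMSD of the motif's backbone atoms against the first analysed
frame.  The synthetic scaffold is rigid apart from optional marker noise, so
this measures the pipeline's ability to separate internal deformation from
rigid tumbling: with noise-free placement the series is identically zero;
with coordinate noise sigma it fluctuates at the noise floor, far below the
0.24–0.42 nm conformational amplitudes of a real flexible motif.  Writes
results/hvr_rmsd.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from memorient import PRESETS, generate_trajectory, hvr_rmsd_series, preset_spec
from memorient.io_core import resolve_selection, selection_from_config, \
    DEFAULT_SELECTION_CONFIG
from memorient.membrane import analysis_window

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--frames", type=int, default=600)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--marker-noise", type=float, default=0.02,
                    help="coordinate noise (nm) standing in for internal "
                         "flexibility of the motif")
    args = ap.parse_args()
    rows = []
    for i, name in enumerate(sorted(PRESETS)):
        spec = preset_spec(name, seed=args.seed + i, n_frames=args.frames,
                           marker_noise_sigma=args.marker_noise)
        frames, _ = generate_trajectory(spec)
        frames = frames[analysis_window(len(frames), 0.5)]
        hvr = resolve_selection(frames[0], selection_from_config(
            DEFAULT_SELECTION_CONFIG, "hvr_motif"))
        rs = hvr_rmsd_series(frames, hvr, reference=0)
        rows.append(dict(system=name, rmsd_mean=rs.values.mean(),
                         rmsd_min=rs.values.min(), rmsd_max=rs.values.max()))
        print(f"{name}: motif RMSD mean {rs.values.mean():.3f} nm "
              f"(range {rs.values.min():.3f}-{rs.values.max():.3f})")
    out = ROOT / "results" / "hvr_rmsd.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"-> {out}")


if __name__ == "__main__":
    main()
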