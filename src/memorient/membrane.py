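"""Bilayer structural metrics: leaflet assignment, area per lipid, thickness.

The bilayer normal is the +z axis throughout.  The bilayer centre z0 is the
mean z of all lipid phosphorus atoms of a frame, and leaflets are split by the
sign of (z - median z) so a bilayer that drifts away from the box centre is
still partitioned correctly.

Area per lipid A = (box_x * box_y) / n_amphiphiles_per_leaflet counts every
amphiphile in the leaflet (phospholipids and cholesterol alike) in the
denominator, so a single A is reported for mixed-composition membranes.
Thickness Δz = mean z(upper phosphates) - mean z(lower phosphates).

Time averages carry block-averaged standard errors, the conservative
convention for correlated molecular-dynamics series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateBilayerError, DomainError
from .io_core import Frame

__all__ = ["MembraneFrame", "BilayerMetrics", "assign_leaflets",
           "area_per_lipid", "thickness", "percent_change",
           "summarize_metrics", "compute_bilayer_series", "analysis_window"]

#: Membrane normal used everywhere in the package.
NORMAL = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class MembraneFrame:
    """Leaflet decomposition of one frame."""

    upper_P: np.ndarray          # indices of upper-leaflet phosphates
    lower_P: np.ndarray          # indices of lower-leaflet phosphates
    center_z: float              # bilayer centre z0, nm
    n_lipids_per_leaflet: int    # amphiphiles per leaflet (A denominator)
    normal: np.ndarray = field(default_factory=lambda: NORMAL.copy())


def assign_leaflets(frame: Frame, lipid_P: np.ndarray,
                    amphiphile: np.ndarray | None = None) -> MembraneFrame:
    """Split phosphate atoms into upper/lower leaflets.

    Parameters
    ----------
    lipid_P
        Indices of the phosphorus (head-group marker) atoms.
    amphiphile
        Indices of *all* leaflet-forming particles (phospholipids plus any
        cholesterol analogues).  Defaults to ``lipid_P``.  Used only to count
        the area-per-lipid denominator; the split itself and the bilayer
        centre use phosphates.
    """
    lipid_P = np.asarray(lipid_P, dtype=int)
    if lipid_P.size < 2:
        raise DomainError("need at least two phosphate atoms to form a bilayer")
    zP = frame.coordinates[lipid_P, 2]
    z_split = float(np.median(zP))
    upper = lipid_P[zP > z_split]
    lower = lipid_P[zP <= z_split]
    if upper.size == 0 or lower.size == 0 or np.ptp(zP) < 1e-9:
        raise DegenerateBilayerError(
            "all phosphate atoms lie in a single leaflet")
    center_z = float(zP.mean())
    if amphiphile is None:
        n_per_leaflet = int(round(lipid_P.size / 2))
    else:
        amphiphile = np.asarray(amphiphile, dtype=int)
        za = frame.coordinates[amphiphile, 2]
        n_per_leaflet = int(round(amphiphile.size / 2))
        # sanity: the amphiphile set must also straddle the split
        if np.all(za > z_split) or np.all(za <= z_split):
            raise DegenerateBilayerError(
                "amphiphile particles lie in a single leaflet")
    mf = MembraneFrame(upper_P=upper, lower_P=lower, center_z=center_z,
                       n_lipids_per_leaflet=n_per_leaflet)
    return mf


def area_per_lipid(frame: Frame, mf: MembraneFrame) -> float:
    """Lateral box area divided by amphiphiles per leaflet, nm^2."""
    if mf.n_lipids_per_leaflet <= 0:
        raise DomainError("no lipids in leaflet")
    return float(frame.box[0] * frame.box[1] / mf.n_lipids_per_leaflet)


def thickness(frame: Frame, mf: MembraneFrame) -> float:
    """Mean phosphate-to-phosphate separation along the normal, nm."""
    if len(mf.upper_P) == 0 or len(mf.lower_P) == 0:
        raise DomainError("both leaflets must be non-empty")
    z = frame.coordinates[:, 2]
    return float(z[mf.upper_P].mean() - z[mf.lower_P].mean())


def percent_change(reference: float, value: float) -> tuple[float, int]:
    """Percent decrease of ``value`` relative to ``reference``.

    Returns ``(unrounded_percent, rounded_percent)`` where the percent is
    ``100 * (reference - value) / reference``; a negative result means an
    increase.
    """
    if reference <= 0:
        raise DomainError("reference must be positive")
    p = 100.0 * (reference - value) / reference
    return float(p), int(round(p))


def summarize_metrics(series: np.ndarray, n_blocks: int = 10
                      ) -> tuple[float, float]:
    """Time average with a block-averaged standard error.

    The series is divided into ``n_blocks`` contiguous blocks; the error is
    the standard error of the block means, which remains honest when frames
    are time-correlated.  Requires at least two frames per block.
    """
    x = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise DomainError("need at least two blocks")
    block_length = x.size // n_blocks
    if block_length < 2:
        raise DomainError(
            f"series of length {x.size} too short for {n_blocks} blocks "
            "(need >= 2 frames per block)")
    trimmed = x[: block_length * n_blocks]
    means = trimmed.reshape(n_blocks, block_length).mean(axis=1)
    err = float(means.std(ddof=1) / np.sqrt(n_blocks))
    return float(x.mean()), err


@dataclass
class BilayerMetrics:
    """Per-frame A and Δz series plus block-averaged summaries."""

    table: pd.DataFrame          # columns: frame, time, area_per_lipid, thickness
    apl_mean: float
    apl_err: float
    thickness_mean: float
    thickness_err: float
    n_blocks: int


def analysis_window(n_frames: int, fraction: float = 0.5) -> slice:
    """Index slice selecting the final ``fraction`` of a trajectory.

    The default mirrors the common practice of analysing only the second,
    equilibrated half of a production run.
    """
    if not 0 < fraction <= 1:
        raise DomainError("window fraction must be in (0, 1]")
    start = int(np.ceil(n_frames * (1.0 - fraction)))
    return slice(min(start, max(n_frames - 1, 0)), n_frames)


def compute_bilayer_series(frames, lipid_P: np.ndarray,
                           amphiphile: np.ndarray | None = None,
                           n_blocks: int = 10) -> BilayerMetrics:
    """Per-frame (A, Δz) over a frame sequence with block-averaged summaries."""
    rows = []
    for k, fr in enumerate(frames):
        mf = assign_leaflets(fr, lipid_P, amphiphile)
        rows.append((k, fr.time, area_per_lipid(fr, mf), thickness(fr, mf)))
    if not rows:
        raise DomainError("no frames to analyse")
    table = pd.DataFrame(rows, columns=["frame", "time", "area_per_lipid",
                                        "thickness"])
    if len(rows) >= 2 * n_blocks:
        apl_mean, apl_err = summarize_metrics(table["area_per_lipid"].values,
                                              n_blocks)
        th_mean, th_err = summarize_metrics(table["thickness"].values, n_blocks)
    else:  # too short for block statistics: report plain mean, no error bar
        apl_mean = float(table["area_per_lipid"].mean())
        th_mean = float(table["thickness"].mean())
        apl_err = th_err = float("nan")
    return BilayerMetrics(table=table, apl_mean=apl_mean, apl_err=apl_err,
                          thickness_mean=th_mean, thickness_err=th_err,
                          n_blocks=n_blocks)
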