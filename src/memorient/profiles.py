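"""Depth profiles of anchored moieties, HVR-motif RMSD, and pair correlations.

Depth of a moiety (farnesyl anchor, GTP ligand, ...) is the signed distance of
its geometric centre from the bilayer centre along the membrane normal, with
the positive direction toward the protein-bearing leaflet.  Its 1D histogram
modes are the "preferred localisations" of the moiety.

The HVR-motif RMSD series measures the internal conformational fluctuation of
the 5-residue anchor-proximal motif: each frame's motif atoms are optimally
superposed (proper rotations only) onto a reference frame's and the residual
RMSD is reported, so rigid tumbling of the whole protein contributes nothing.

g(r) is the standard radial distribution function under minimum-image
periodicity, normalised by ideal-gas shell counts so an uncorrelated system
gives g = 1 at all r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, SelectionError
from .geometry import kabsch_superpose, minimum_image
from .io_core import Frame
from .membrane import MembraneFrame

__all__ = ["DepthSeries", "RMSDSeries", "RDFResult",
           "depth_series", "hvr_rmsd_series", "compute_rdf",
           "histogram_modes"]


@dataclass
class DepthSeries:
    moiety: str
    values: np.ndarray           # signed depth per frame, nm
    times: np.ndarray            # ps
    mean: float
    modes: tuple[float, ...]     # preferred localisations (histogram modes)
    bin_width: float


@dataclass
class RMSDSeries:
    values: np.ndarray           # nm, >= 0
    times: np.ndarray
    reference_index: int


@dataclass
class RDFResult:
    r: np.ndarray                # bin centres, nm
    g: np.ndarray                # dimensionless
    counts: np.ndarray           # raw pair counts per bin (all frames)
    r_max: float
    dr: float
    n_frames: int


def histogram_modes(values: np.ndarray, bin_width: float = 0.1,
                    min_prominence: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima of a 1D histogram, as (mode bin centres, bin probabilities).

    A bin is a mode when it is a strict-or-equal local maximum and holds at
    least ``min_prominence`` times the probability of the global maximum;
    the threshold suppresses noise bumps while keeping genuinely bimodal
    structure visible.  Modes are returned sorted by position.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("empty series")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width
    n = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(v, bins=n, range=(lo, lo + n * bin_width))
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    padded = np.concatenate([[-1.0], prob, [-1.0]])
    is_peak = (prob >= padded[:-2]) & (prob > padded[2:])
    keep = is_peak & (prob >= min_prominence * prob.max())
    return centers[keep], prob[keep]


def depth_series(frames, moiety_indices: np.ndarray,
                 membrane_frames, moiety: str = "moiety",
                 bin_width: float = 0.1,
                 orient_reference: np.ndarray | None = None) -> DepthSeries:
    """Signed depth of a moiety's geometric centre from the bilayer centre.

    Parameters
    ----------
    moiety_indices
        Atom indices of the moiety (unweighted geometric centre is used).
    membrane_frames
        One :class:`MembraneFrame` per frame (provides centre z0).
    orient_reference
        Atom indices defining which leaflet the protein occupies; the sign
        convention points toward that leaflet.  Defaults to the moiety itself,
        judged on the first frame.
    """
    frames = list(frames)
    if not frames:
        raise DomainError("empty trajectory")
    idx = np.asarray(moiety_indices, dtype=int)
    if idx.size == 0:
        raise SelectionError(f"moiety {moiety!r} selection is empty")
    ref_idx = idx if orient_reference is None else np.asarray(orient_reference, int)
    first_mf = membrane_frames[0]
    side = np.sign(frames[0].coordinates[ref_idx, 2].mean() - first_mf.center_z)
    side = 1.0 if side == 0 else float(side)
    values, times = [], []
    for fr, mf in zip(frames, membrane_frames):
        center = fr.coordinates[idx].mean(axis=0)
        values.append(side * (center[2] - mf.center_z))
        times.append(fr.time)
    values = np.asarray(values)
    modes, _ = histogram_modes(values, bin_width=bin_width)
    return DepthSeries(moiety=moiety, values=values, times=np.asarray(times),
                       mean=float(values.mean()), modes=tuple(modes),
                       bin_width=bin_width)


def hvr_rmsd_series(frames, hvr_indices: np.ndarray,
                    reference: Frame | int = 0) -> RMSDSeries:
    """Per-frame superposed RMSD of the HVR motif atoms vs a reference.

    ``reference`` is either a frame index into ``frames`` (default: the first
    frame of the analysed window) or an explicit reference :class:`Frame`.
    """
    frames = list(frames)
    if not frames:
        raise DomainError("empty trajectory")
    idx = np.asarray(hvr_indices, dtype=int)
    if idx.size == 0:
        raise SelectionError("HVR motif selection is empty")
    if isinstance(reference, Frame):
        ref_coords = reference.coordinates[idx]
        ref_index = -1
    else:
        ref_index = int(reference)
        ref_coords = frames[ref_index].coordinates[idx]
    values = []
    for fr in frames:
        if fr.n_atoms <= idx.max():
            raise DomainError("HVR atom indices out of range for frame")
        _, value = kabsch_superpose(fr.coordinates[idx], ref_coords)
        values.append(value)
    return RMSDSeries(values=np.asarray(values),
                      times=np.asarray([fr.time for fr in frames]),
                      reference_index=ref_index)


def compute_rdf(frames, sel_a: np.ndarray, sel_b: np.ndarray,
                r_max: float = 2.0, dr: float = 0.05) -> RDFResult:
    """Radial distribution function g(r) between two selections.

    Minimum-image distances are histogrammed in shells of width ``dr`` up to
    ``r_max`` and normalised per frame by the ideal-gas expectation
    ``N_A * rho_B * V_shell`` with exact shell volumes.  Self-pairs are
    excluded when the selections are identical.  ``r_max`` may not exceed
    half the smallest box edge.
    """
    frames = list(frames)
    if not frames:
        raise DomainError("empty trajectory")
    a = np.asarray(sel_a, dtype=int)
    b = np.asarray(sel_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise SelectionError("RDF selections must be non-empty")
    if r_max <= 0 or dr <= 0:
        raise DomainError("r_max and dr must be positive")
    same = a.size == b.size and np.array_equal(np.sort(a), np.sort(b))
    n_bins = int(round(r_max / dr))
    edges = np.linspace(0.0, n_bins * dr, n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    counts = np.zeros(n_bins)
    g_acc = np.zeros(n_bins)
    for fr in frames:
        if r_max > fr.box.min() / 2 + 1e-9:
            raise DomainError(
                f"r_max={r_max} exceeds half the smallest box edge "
                f"({fr.box.min() / 2:.3f} nm)")
        xa = fr.coordinates[a]
        xb = fr.coordinates[b]
        vol = float(np.prod(fr.box))
        rho_b = (b.size - (1 if same else 0)) / vol
        frame_counts = np.zeros(n_bins)
        chunk = max(1, int(2e6 // max(b.size, 1)))
        for s in range(0, a.size, chunk):
            d = xa[s:s + chunk, None, :] - xb[None, :, :]
            d = minimum_image(d, fr.box)
            dist = np.sqrt((d ** 2).sum(axis=-1)).ravel()
            if same:
                dist = dist[dist > 1e-9]
            dist = dist[dist < n_bins * dr]
            frame_counts += np.histogram(dist, bins=edges)[0]
        counts += frame_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            g_acc += frame_counts / (a.size * rho_b * shell_vol)
    g = g_acc / len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centers, g=g, counts=counts, r_max=r_max, dr=dr,
                     n_frames=len(frames))
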