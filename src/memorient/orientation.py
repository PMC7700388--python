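"""Orientation order parameters and orientation-state classification.

A peripheral protein's pose on a planar membrane is summarised per frame by

* ``z``   — the Cα132–Cα183 distance (nm), separating the catalytic domain
  lobe 2 from the membrane-anchored tail.  By default this is the literal 3D
  Euclidean distance; a projection-onto-the-normal mode is available.
* ``Θ``   — the angle between the membrane normal and the β1-strand vector
  Cα5→Cα9 (degrees; its cosine is also carried).
* ``Φ``   — the angle between the membrane normal and the α5-helix vector
  Cα156→Cα163 (degrees).

Frames are classified into three orientation states by nearest centre in the
(z, cosΘ) plane: OS1 (active, effector-binding loop exposed), OS2 (inactive,
loop occluded by the membrane) and OS0 (intermediate).  The literature centres
are (1.86, −0.5), (4.97, 1) and (3.33, 0.9) respectively; only centres, not
boundaries, are published, so classification uses a normalised Euclidean
distance with configurable per-axis scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SelectionError
from .geometry import angle_to_normal
from .io_core import Frame, ca_marker, resolve_selection
from .membrane import NORMAL

__all__ = ["OrientationRecord", "OSRegionModel", "DensityMap2D",
           "order_parameter_z", "order_parameter_theta", "order_parameter_phi",
           "classify_os", "density_map", "os_occupancy",
           "compute_orientation_records", "DEFAULT_OS_MODEL",
           "DEFAULT_MARKERS"]

#: Marker residues: β1 strand endpoints, lobe-2 reference, α5 helix endpoints,
#: HVR anchor-side residue.
DEFAULT_MARKERS = {"beta1": (5, 9), "z_pair": (132, 183), "alpha5": (156, 163)}


@dataclass(frozen=True)
class OrientationRecord:
    time: float          # ps
    z: float             # nm
    theta: float         # degrees in [0, 180]
    cos_theta: float
    phi: float           # degrees in [0, 180]
    os_label: str        # "OS0" | "OS1" | "OS2"


@dataclass(frozen=True)
class OSRegionModel:
    """Nearest-centre classifier in the (z, cosΘ) plane.

    ``z_scale`` (nm) and ``cos_scale`` normalise the two axes so a distance
    of 1 corresponds to the plausible full range of each coordinate.
    """

    centers: dict = field(default_factory=lambda: {
        "OS1": (1.86, -0.5),
        "OS2": (4.97, 1.0),
        "OS0": (3.33, 0.9),
    })
    z_scale: float = 5.0
    cos_scale: float = 2.0
    #: deterministic tie-break priority
    tie_order: tuple[str, ...] = ("OS1", "OS0", "OS2")

    def __post_init__(self):
        if self.z_scale <= 0 or self.cos_scale <= 0:
            raise DomainError("axis scales must be positive")
        if len({tuple(c) for c in self.centers.values()}) != len(self.centers):
            raise DomainError("OS centres must be distinct")


DEFAULT_OS_MODEL = OSRegionModel()


def order_parameter_z(frame: Frame, ca132: int, ca183: int,
                      mode: str = "euclidean") -> float:
    """Cα132–Cα183 separation, nm.

    ``mode="euclidean"`` (default) is the 3D distance; ``mode="projection"``
    is the absolute separation along the membrane normal.  The protein must
    be whole (unwrapped): no minimum-image convention is applied to an
    intramolecular vector.
    """
    d = frame.coordinates[ca132] - frame.coordinates[ca183]
    if mode == "euclidean":
        return float(np.linalg.norm(d))
    if mode == "projection":
        return float(abs(d[2]))
    raise DomainError(f"unknown z mode {mode!r}")


def order_parameter_theta(frame: Frame, ca5: int, ca9: int,
                          normal: np.ndarray = NORMAL) -> tuple[float, float]:
    """Tilt angle Θ of the β1 strand (Cα5→Cα9) against the normal."""
    v = frame.coordinates[ca9] - frame.coordinates[ca5]
    if np.linalg.norm(v) < 1e-12:
        raise DomainError("β1 marker atoms coincide")
    return angle_to_normal(v, normal)


def order_parameter_phi(frame: Frame, ca156: int, ca163: int,
                        normal: np.ndarray = NORMAL) -> float:
    """Angle Φ of the α5 helix (Cα156→Cα163, N→C direction) vs the normal."""
    v = frame.coordinates[ca163] - frame.coordinates[ca156]
    if np.linalg.norm(v) < 1e-12:
        raise DomainError("α5 marker atoms coincide")
    deg, _ = angle_to_normal(v, normal)
    return deg


def classify_os(z: float, cos_theta: float,
                model: OSRegionModel = DEFAULT_OS_MODEL) -> str:
    """Label a (z, cosΘ) point by nearest OS centre (normalised distance).

    Ties are broken deterministically in the order OS1, OS0, OS2.
    """
    if not (np.isfinite(z) and np.isfinite(cos_theta)):
        raise DomainError("z and cosΘ must be finite")
    best_label, best_d = None, np.inf
    for label in model.tie_order:
        cz, cc = model.centers[label]
        d = ((z - cz) / model.z_scale) ** 2 + ((cos_theta - cc) / model.cos_scale) ** 2
        if d < best_d - 0.0:  # strict improvement keeps the tie order
            best_label, best_d = label, d
    return best_label


@dataclass
class DensityMap2D:
    """Normalised 2D histogram over two orientation coordinates."""

    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    probabilities: np.ndarray      # (nx, ny), sums to 1
    mode: tuple[float, float]      # bin-centre coordinates of the argmax bin
    x_marginal: np.ndarray
    y_marginal: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (x, y, probability) for CSV output."""
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame({self.x_name: xc.ravel(), self.y_name: yc.ravel(),
                             "probability": self.probabilities.ravel()})


_AXIS_GETTERS = {
    "z": lambda r: r.z,
    "cos_theta": lambda r: r.cos_theta,
    "theta": lambda r: r.theta,
    "phi": lambda r: r.phi,
}


def _axis_values(records, name):
    if name not in _AXIS_GETTERS:
        raise DomainError(f"unknown density axis {name!r}; "
                          f"choose from {sorted(_AXIS_GETTERS)}")
    return np.array([_AXIS_GETTERS[name](r) for r in records], dtype=float)


def density_map(records: Sequence[OrientationRecord], x_axis: str, y_axis: str,
                n_bins: int = 50, pad_fraction: float = 0.05) -> DensityMap2D:
    """Probability-normalised 2D histogram over two orientation coordinates.

    Axes are chosen from ``{"z", "cos_theta", "theta", "phi"}``.  The binning
    range is the data range padded by ``pad_fraction`` on each side (a
    degenerate range is widened symmetrically so a constant series still
    occupies a single well-defined bin).  The mode is the centre of the
    highest-probability bin; ties resolve to the lowest bin indices.
    """
    if len(records) == 0:
        raise DomainError("cannot build a density map from zero records")
    x = _axis_values(records, x_axis)
    y = _axis_values(records, y_axis)

    def _edges(v):
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        if span <= 0:
            span = max(abs(lo), 1.0) * 1e-3
            lo, hi = lo - span / 2, hi + span / 2
        else:
            lo -= pad_fraction * span
            hi += pad_fraction * span
        return np.linspace(lo, hi, n_bins + 1)

    x_edges, y_edges = _edges(x), _edges(y)
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    prob = counts / counts.sum()
    flat = int(np.argmax(prob))  # first occurrence → lowest indices on ties
    ix, iy = np.unravel_index(flat, prob.shape)
    xc = 0.5 * (x_edges[ix] + x_edges[ix + 1])
    yc = 0.5 * (y_edges[iy] + y_edges[iy + 1])
    return DensityMap2D(x_name=x_axis, y_name=y_axis, x_edges=x_edges,
                        y_edges=y_edges, probabilities=prob, mode=(xc, yc),
                        x_marginal=prob.sum(axis=1), y_marginal=prob.sum(axis=0))


def os_occupancy(records: Sequence[OrientationRecord]) -> dict[str, float]:
    """Fraction of frames in each orientation state (sums to 1)."""
    if len(records) == 0:
        raise DomainError("cannot compute occupancy of zero records")
    out = {"OS0": 0.0, "OS1": 0.0, "OS2": 0.0}
    for r in records:
        out[r.os_label] += 1.0
    n = float(len(records))
    return {k: v / n for k, v in out.items()}


def compute_orientation_records(frames: Iterable[Frame],
                                markers: dict = DEFAULT_MARKERS,
                                model: OSRegionModel = DEFAULT_OS_MODEL,
                                z_mode: str = "euclidean",
                                normal: np.ndarray = NORMAL
                                ) -> list[OrientationRecord]:
    """Per-frame (z, Θ, cosΘ, Φ) plus OS labels for a trajectory.

    Marker atoms are resolved once on the first frame (atom order is constant
    across a trajectory) as the single Cα of each marker residue.
    """
    frames = list(frames)
    if not frames:
        raise DomainError("empty trajectory")
    first = frames[0]
    try:
        ca = {num: int(resolve_selection(first, ca_marker(num))[0])
              for pair in markers.values() for num in pair}
    except SelectionError as exc:
        raise SelectionError(f"orientation markers unresolved: {exc}") from exc
    r5, r9 = markers["beta1"]
    r132, r183 = markers["z_pair"]
    r156, r163 = markers["alpha5"]
    records = []
    for fr in frames:
        z = order_parameter_z(fr, ca[r132], ca[r183], mode=z_mode)
        theta, cos_t = order_parameter_theta(fr, ca[r5], ca[r9], normal)
        phi = order_parameter_phi(fr, ca[r156], ca[r163], normal)
        records.append(OrientationRecord(
            time=fr.time, z=z, theta=theta, cos_theta=cos_t, phi=phi,
            os_label=classify_os(z, cos_t, model)))
    return records


def records_to_frame(records: Sequence[OrientationRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "time": r.time, "z": r.z, "theta": r.theta, "cos_theta": r.cos_theta,
        "phi": r.phi, "os_label": r.os_label} for r in records])
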