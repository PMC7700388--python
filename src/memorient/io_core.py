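"""Trajectory input/output and named atom selections.

The in-memory model is deliberately small: a trajectory is an ordered list of
:class:`Frame` objects, each holding parallel numpy arrays of atom metadata
plus an ``(N, 3)`` coordinate array in nanometres and an orthorhombic box.

Two on-disk formats are supported natively:

* **GRO** (fixed-column, nm) — including multi-frame concatenated GRO files,
  read and written by an exact fixed-column codec so that atom names, residue
  names/numbers and 3-decimal coordinates round-trip bit-for-bit.  Velocity
  columns are ignored on read and never written.
* **multi-model PDB** (MODEL/ENDMDL, Å) — read through :mod:`mdtraj`;
  coordinates are converted to nm.

Compressed trajectory formats (XTC/DCD) are also accepted through mdtraj when
a topology file is supplied.

Only orthorhombic boxes are supported; triclinic input raises an explicit
error rather than silently mangling periodic distances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, ParseError, SelectionError, StructuralError

__all__ = [
    "AtomRecord",
    "Frame",
    "SelectionSpec",
    "ca_marker",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "load_selection_config",
    "DEFAULT_SELECTION_CONFIG",
]


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: metadata plus a coordinate in nm."""

    index: int
    name: str
    residue_number: int
    residue_name: str
    segment: str
    coordinates: tuple[float, float, float]


class Frame:
    """One time point of a trajectory.

    Parameters
    ----------
    names, residue_numbers, residue_names, segments
        Parallel per-atom metadata arrays (length N).
    coordinates
        ``(N, 3)`` array, nm.
    box
        Orthorhombic edge lengths ``(lx, ly, lz)``, nm; all > 0.
    time
        Frame time in ps.
    """

    __slots__ = ("names", "residue_numbers", "residue_names", "segments",
                 "coordinates", "box", "time")

    def __init__(self, names, residue_numbers, residue_names, coordinates, box,
                 time=0.0, segments=None):
        self.names = np.asarray(names, dtype=object)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        n = len(self.names)
        if segments is None:
            segments = [""] * n
        self.segments = np.asarray(segments, dtype=object)
        self.coordinates = np.asarray(coordinates, dtype=float).reshape(n, 3)
        self.box = np.asarray(box, dtype=float).reshape(3)
        self.time = float(time)
        if not np.all(np.isfinite(self.coordinates)):
            raise DomainError("frame contains non-finite coordinates")
        if np.any(self.box <= 0):
            raise DomainError(f"box edge lengths must be positive, got {self.box}")
        if not (len(self.residue_numbers) == len(self.residue_names)
                == len(self.segments) == n):
            raise DomainError("per-atom metadata arrays have mismatched lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            index=i,
            name=str(self.names[i]),
            residue_number=int(self.residue_numbers[i]),
            residue_name=str(self.residue_names[i]),
            segment=str(self.segments[i]),
            coordinates=tuple(self.coordinates[i]),
        )

    def copy(self) -> "Frame":
        return Frame(self.names.copy(), self.residue_numbers.copy(),
                     self.residue_names.copy(), self.coordinates.copy(),
                     self.box.copy(), self.time, self.segments.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Frame n_atoms={self.n_atoms} box={tuple(self.box)} t={self.time} ps>"


def _validate_constant_atoms(frames: Sequence[Frame], path: str | None = None) -> None:
    if not frames:
        return
    n0 = frames[0].n_atoms
    for k, fr in enumerate(frames):
        if fr.n_atoms != n0:
            where = f" in {path}" if path else ""
            raise StructuralError(
                f"inconsistent atom count across frames{where}: frame 0 has "
                f"{n0} atoms, frame {k} has {fr.n_atoms}")


# ---------------------------------------------------------------------------
# GRO codec
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"t=\s*([-+0-9.eE]+)")


def _read_gro(path: str | Path) -> list[Frame]:
    path = Path(path)
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    nline = len(lines)
    while i < nline:
        if lines[i].strip() == "":
            i += 1
            continue
        title = lines[i]
        m = _TIME_RE.search(title)
        time = float(m.group(1)) if m else float(len(frames))
        if i + 1 >= nline:
            raise ParseError("truncated GRO file: missing atom count",
                             str(path), i + 2)
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise ParseError(
                f"expected atom count, got {lines[i + 1]!r}", str(path), i + 2
            ) from None
        if i + 2 + n_atoms >= nline:
            raise ParseError("truncated GRO frame", str(path), nline)
        names, resnums, resnames, coords = [], [], [], []
        for j in range(n_atoms):
            ln = lines[i + 2 + j]
            lineno = i + 3 + j
            if len(ln) < 44:
                raise ParseError(f"atom record too short ({len(ln)} chars)",
                                 str(path), lineno)
            try:
                resnums.append(int(ln[0:5]))
                resnames.append(ln[5:10].strip())
                names.append(ln[10:15].strip())
                coords.append((float(ln[20:28]), float(ln[28:36]), float(ln[36:44])))
            except ValueError as exc:
                raise ParseError(f"malformed atom record: {exc}",
                                 str(path), lineno) from None
        box_fields = lines[i + 2 + n_atoms].split()
        box_lineno = i + 3 + n_atoms
        try:
            box_vals = [float(x) for x in box_fields]
        except ValueError:
            raise ParseError("malformed box line", str(path), box_lineno) from None
        if len(box_vals) == 3:
            box = box_vals
        elif len(box_vals) == 9:
            if any(abs(v) > 1e-9 for v in box_vals[3:]):
                raise DomainError(
                    f"triclinic box not supported ({path}, line {box_lineno}); "
                    "only orthorhombic boxes are handled")
            box = box_vals[:3]
        else:
            raise ParseError(f"box line must have 3 or 9 fields, got "
                             f"{len(box_vals)}", str(path), box_lineno)
        try:
            frames.append(Frame(names, resnums, resnames, coords, box, time))
        except DomainError as exc:
            raise ParseError(str(exc), str(path), i + 1) from None
        i = i + 3 + n_atoms
    if not frames:
        raise ParseError("no frames found", str(path), 1)
    return frames


def _write_gro(frames: Sequence[Frame], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"memorient frame t= {fr.time:.3f}\n")
            fh.write(f"{fr.n_atoms:5d}\n")
            for i in range(fr.n_atoms):
                x, y, z = fr.coordinates[i]
                fh.write(f"{int(fr.residue_numbers[i]) % 100000:5d}"
                         f"{str(fr.residue_names[i]):<5.5s}"
                         f"{str(fr.names[i]):>5.5s}"
                         f"{(i + 1) % 100000:5d}"
                         f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            lx, ly, lz = fr.box
            fh.write(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB / compressed formats through mdtraj
# ---------------------------------------------------------------------------

def _frames_from_mdtraj(traj) -> list[Frame]:
    top = traj.topology
    names = [a.name for a in top.atoms]
    resnums = [a.residue.resSeq for a in top.atoms]
    resnames = [a.residue.name for a in top.atoms]
    segments = [getattr(a, "segment_id", "") or "" for a in top.atoms]
    if traj.unitcell_angles is not None:
        if not np.allclose(traj.unitcell_angles, 90.0, atol=1e-3):
            raise DomainError("triclinic box not supported; only orthorhombic")
        boxes = traj.unitcell_lengths
    else:
        raise DomainError("trajectory has no box information")
    times = traj.time if traj.time is not None else np.arange(traj.n_frames)
    return [Frame(names, resnums, resnames, traj.xyz[k], boxes[k], times[k],
                  segments) for k in range(traj.n_frames)]


def _read_mdtraj(path: str | Path, top: str | Path | None = None) -> list[Frame]:
    import mdtraj as md

    try:
        traj = md.load(str(path)) if top is None else md.load(str(path), top=str(top))
    except Exception as exc:  # mdtraj raises format-specific exceptions
        raise ParseError(f"failed to parse {path}: {exc}", str(path)) from exc
    return _frames_from_mdtraj(traj)


def read_trajectory(path: str | Path, fmt: str = "auto",
                    top: str | Path | None = None) -> list[Frame]:
    """Read a multi-frame coordinate file into a list of :class:`Frame`.

    Parameters
    ----------
    path
        Input file.  ``.gro`` is handled natively (multi-frame concatenated
        GRO); ``.pdb`` (multi-model) and compressed formats go through mdtraj.
    fmt
        ``"gro"``, ``"pdb"`` or ``"auto"`` (by extension).
    top
        Topology file, required only for coordinate-only formats (XTC/DCD).

    Coordinates are returned in nm regardless of the source unit (PDB Å are
    divided by 10 by the reader).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = {"gro": "gro", "pdb": "pdb"}.get(path.suffix.lstrip(".").lower(),
                                               "mdtraj")
    if fmt == "gro":
        frames = _read_gro(path)
    elif fmt in ("pdb", "mdtraj"):
        frames = _read_mdtraj(path, top=top)
    else:
        raise DomainError(f"unknown trajectory format {fmt!r}")
    _validate_constant_atoms(frames, str(path))
    return frames


def write_trajectory(frames: Sequence[Frame], path: str | Path,
                     fmt: str = "auto") -> None:
    """Write frames as multi-frame GRO (native) or multi-model PDB (mdtraj)."""
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower() or "gro"
    _validate_constant_atoms(frames, str(path))
    if not frames:
        raise DomainError("cannot write an empty trajectory")
    if fmt == "gro":
        _write_gro(frames, path)
    elif fmt == "pdb":
        _write_pdb(frames, path)
    else:
        raise DomainError(f"unknown trajectory format {fmt!r}")


def _write_pdb(frames: Sequence[Frame], path: str | Path) -> None:
    # Minimal multi-model PDB writer (Å); mdtraj's writer requires element
    # inference which is meaningless for pseudo-atoms, so records are emitted
    # directly in fixed columns.
    with open(path, "w") as fh:
        fr0 = frames[0]
        lx, ly, lz = fr0.box * 10.0
        fh.write(f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for m, fr in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i in range(fr.n_atoms):
                x, y, z = fr.coordinates[i] * 10.0
                name = str(fr.names[i])
                # PDB atom-name column convention: <4-char names start col 14
                name_field = f" {name:<3.3s}" if len(name) < 4 else f"{name:<4.4s}"
                fh.write(f"ATOM  {(i + 1) % 100000:5d} {name_field} "
                         f"{str(fr.residue_names[i]):<4.4s} "
                         f"{int(fr.residue_numbers[i]) % 10000:4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSpec:
    """A named, declarative atom selection.

    Atoms match when every non-``None`` predicate matches: atom name in
    ``atom_names``, residue name in ``residue_names``, residue number in
    ``residue_numbers``.
    """

    role: str = "generic"
    atom_names: tuple[str, ...] | None = None
    residue_names: tuple[str, ...] | None = None
    residue_numbers: tuple[int, ...] | None = None
    expect: int | None = None  # exact expected atom count, if any

    def __post_init__(self):
        for f in ("atom_names", "residue_names", "residue_numbers"):
            v = getattr(self, f)
            if v is not None and not isinstance(v, tuple):
                object.__setattr__(self, f, tuple(v))


def ca_marker(residue_number: int) -> SelectionSpec:
    """The single Cα atom of one residue (orientation-vector endpoint)."""
    return SelectionSpec(role=f"ca_marker({residue_number})",
                         atom_names=("CA",),
                         residue_numbers=(residue_number,),
                         expect=1)


def resolve_selection(frame: Frame, spec: SelectionSpec) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to an ordered array of atom indices.

    Pure function of ``(frame, spec)``: index order follows atom order in the
    frame.  Raises :class:`SelectionError` for an empty result or when the
    spec's ``expect`` count is violated.
    """
    mask = np.ones(frame.n_atoms, dtype=bool)
    if spec.atom_names is not None:
        mask &= np.isin(frame.names, list(spec.atom_names))
    if spec.residue_names is not None:
        mask &= np.isin(frame.residue_names, list(spec.residue_names))
    if spec.residue_numbers is not None:
        mask &= np.isin(frame.residue_numbers, list(spec.residue_numbers))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection for role {spec.role!r} matched no atoms")
    if spec.expect is not None and idx.size != spec.expect:
        raise SelectionError(
            f"selection for role {spec.role!r} matched {idx.size} atoms, "
            f"expected {spec.expect}")
    return idx


#: Default role definitions.  They resolve both against the synthetic
#: pseudo-system written by :mod:`memorient.synthetic` and against a
#: CHARMM-named DOPC/DOPS(/cholesterol) membrane with a farnesylated,
#: GTP-bound protein.
DEFAULT_SELECTION_CONFIG: dict = {
    "lipid_P": {"atom_names": ["P"],
                "residue_names": ["DOPC", "DOPS"]},
    "amphiphile": {"residue_names": ["DOPC", "DOPS", "CHOL", "CHL1"]},
    "far_group": {"residue_names": ["FAR"]},
    "gtp_group": {"residue_names": ["GTP"]},
    "hvr_motif": {"residue_numbers": [180, 181, 182, 183, 184],
                  "atom_names": ["N", "CA", "C", "O"]},
}


def selection_from_config(config: dict, role: str,
                          expect: int | None = None) -> SelectionSpec:
    """Build a SelectionSpec for ``role`` from a configuration mapping."""
    if role not in config:
        raise SelectionError(f"role {role!r} not present in selection config")
    entry = config[role]
    return SelectionSpec(
        role=role,
        atom_names=tuple(entry["atom_names"]) if "atom_names" in entry else None,
        residue_names=tuple(entry["residue_names"]) if "residue_names" in entry else None,
        residue_numbers=tuple(entry["residue_numbers"]) if "residue_numbers" in entry else None,
        expect=expect,
    )


def load_selection_config(path: str | Path) -> dict:
    """Load a role → predicate mapping from a YAML file.

    Schema: top-level mapping of role name to a mapping with any of
    ``atom_names``, ``residue_names``, ``residue_numbers`` (lists).
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SelectionError(f"selection config {path} must be a mapping")
    for role, entry in cfg.items():
        if not isinstance(entry, dict):
            raise SelectionError(f"selection config entry {role!r} must be a mapping")
        unknown = set(entry) - {"atom_names", "residue_names", "residue_numbers"}
        if unknown:
            raise SelectionError(f"unknown keys {unknown} in selection role {role!r}")
    return cfg
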