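"""Ground-truthed synthetic membrane + protein trajectories.

The generator emulates the statistical structure that the analysis pipeline
assumes, with every quantity of interest known exactly:

* a two-leaflet slab of single-particle pseudo-lipids (one phosphate-like
  particle per phospholipid, one sterol-like particle per cholesterol
  analogue) on a square lattice, with the lateral box constructed so the
  target area per lipid holds exactly and leaflets at ±thickness/2;
* a rigid pseudo-protein scaffold carrying one Cα per marker residue
  (5, 9, 132, 156, 163), a 5-residue HVR motif (backbone N/CA/C/O of
  residues 180–184), and 5-atom farnesyl (FAR) and GTP clusters;
* exact rigid-body placement of the scaffold at requested tilt angles
  (Θ for the β1 strand, Φ for the α5 helix) and anchor depth, via a
  deterministic two-stage rotation construction;
* stochastic schedules: mean-reverting Gaussian drift of (Θ, Φ) and a
  two-state Markov switch of the anchor depth between an inserted and a
  solvated level, emulating anchoring/release dynamics.

Identical spec + seed produce bitwise-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, FeasibilityError
from .geometry import angle_to_normal
from .io_core import Frame

__all__ = ["SyntheticSpec", "ProteinTemplate", "PRESETS",
           "build_slab", "build_protein_template", "place_protein",
           "feasible_phi_interval", "generate_trajectory"]


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Full parameterisation of a synthetic trajectory.

    Lengths nm, angles degrees, times ps.  ``target_apl`` is rescaled by
    ``condensation_factor`` when cholesterol analogues are present
    (``chol_fraction > 0``), emulating the sterol condensation effect.
    ``depth_levels`` switches the FAR anchor depth between two levels with
    per-frame probability ``switch_prob`` (anchored/solvated dynamics);
    when ``None`` the depth stays at ``depth_far``.  ``sigma_angle > 0``
    turns on mean-reverting orientational drift with stationary standard
    deviation ``sigma_angle`` about (theta, phi).
    """

    n_lipids_per_leaflet: int = 152
    target_apl: float = 0.679          # nm^2 (cholesterol-free membrane)
    target_thickness: float = 3.84     # nm
    chol_fraction: float = 0.0
    condensation_factor: float = 1.0
    positional_jitter_sigma: float = 0.0   # nm, lipid particles
    marker_noise_sigma: float = 0.0        # nm, protein atoms
    theta: float = 80.0                # degrees
    phi: float = 105.0                 # degrees
    sigma_angle: float = 0.0           # degrees; 0 = fixed orientation
    angle_rho: float = 0.95            # AR(1) memory of the drift process
    depth_far: float = 1.73            # nm from bilayer centre
    depth_gtp: float = 4.38            # nm
    depth_levels: tuple[float, float] | None = None
    switch_prob: float = 0.02
    n_frames: int = 500
    frame_dt: float = 1000.0           # ps
    seed: int = 0
    water_margin: float = 9.0          # nm of box height above/below leaflets

    @property
    def effective_apl(self) -> float:
        return self.target_apl * (self.condensation_factor
                                  if self.chol_fraction > 0 else 1.0)

    def validate(self) -> None:
        if self.n_lipids_per_leaflet < 2:
            raise ConfigError("need at least 2 lipids per leaflet")
        if self.target_apl <= 0 or self.target_thickness <= 0:
            raise ConfigError("target_apl and target_thickness must be positive")
        if not 0 <= self.chol_fraction < 1:
            raise ConfigError("chol_fraction must lie in [0, 1)")
        if self.condensation_factor <= 0:
            raise ConfigError("condensation_factor must be positive")
        if not 0 <= self.switch_prob <= 1:
            raise ConfigError("switch_prob must lie in [0, 1]")
        if self.positional_jitter_sigma < 0 or self.marker_noise_sigma < 0:
            raise ConfigError("noise sigmas must be non-negative")
        if self.positional_jitter_sigma >= self.target_thickness / 2:
            raise ConfigError(
                "positional jitter must stay below half the leaflet spacing "
                "to keep leaflets identifiable")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if not (0 < self.theta < 180):
            raise ConfigError("theta must lie strictly inside (0, 180)")
        if not (0 <= self.phi <= 180):
            raise ConfigError("phi must lie in [0, 180]")
        if self.depth_levels is not None and len(self.depth_levels) != 2:
            raise ConfigError("depth_levels must be a (low, high) pair")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["depth_levels"] is not None:
            d["depth_levels"] = list(d["depth_levels"])
        return d


#: Study-condition presets.  Membrane targets are the reported bilayer
#: structure of the four wild-type/oncogenic × chol-0%/chol-30% systems;
#: orientation centres and anchor depths are the corresponding reported
#: modal values.  The oncogenic chol-0% anchor depth is set 0.17 nm shallower
#: than the chol-30% one (only the difference is reported).
PRESETS: dict[str, dict] = {
    "wt_chol0": dict(target_apl=0.679, target_thickness=3.84,
                     chol_fraction=0.0, theta=59.0, phi=52.5, sigma_angle=6.0,
                     depth_far=1.30, depth_gtp=4.38,
                     positional_jitter_sigma=0.05),
    "wt_chol30": dict(target_apl=0.679, condensation_factor=0.523 / 0.679,
                      target_thickness=4.35, chol_fraction=0.3,
                      theta=53.0, phi=37.0, sigma_angle=6.0,
                      depth_levels=(1.73, 3.90), switch_prob=0.02,
                      depth_gtp=2.39, positional_jitter_sigma=0.05),
    "onc_chol0": dict(target_apl=0.679, target_thickness=3.89,
                      chol_fraction=0.0, theta=99.0, phi=83.0, sigma_angle=6.0,
                      depth_far=1.47, depth_gtp=2.78,
                      positional_jitter_sigma=0.05),
    "onc_chol30": dict(target_apl=0.679, condensation_factor=0.525 / 0.679,
                       target_thickness=4.23, chol_fraction=0.3,
                       theta=80.0, phi=105.0, sigma_angle=8.0,
                       depth_far=1.30, depth_gtp=4.38,
                       positional_jitter_sigma=0.05),
}


def preset_spec(name: str, **overrides) -> SyntheticSpec:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    spec = SyntheticSpec(**params)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Membrane slab
# ---------------------------------------------------------------------------

@dataclass
class _SlabBase:
    coords: np.ndarray
    names: list
    resnums: list
    resnames: list
    box: np.ndarray
    center_z: float


def _slab_base(spec: SyntheticSpec, rng: np.random.Generator) -> _SlabBase:
    n = spec.n_lipids_per_leaflet
    apl = spec.effective_apl
    box_xy = float(np.sqrt(n * apl))
    m = int(np.ceil(np.sqrt(n)))
    spacing = box_xy / m
    jj, ii = np.meshgrid(np.arange(m), np.arange(m))
    lattice = np.column_stack([(ii.ravel() + 0.5) * spacing,
                               (jj.ravel() + 0.5) * spacing])[:n]
    box_z = spec.target_thickness + spec.water_margin
    center_z = box_z / 2.0
    z_up = center_z + spec.target_thickness / 2.0
    z_lo = center_z - spec.target_thickness / 2.0
    coords = np.vstack([
        np.column_stack([lattice, np.full(n, z_up)]),
        np.column_stack([lattice, np.full(n, z_lo)]),
    ])
    n_chol = int(round(spec.chol_fraction * n))
    is_chol = np.zeros(2 * n, dtype=bool)
    for leaflet in range(2):
        pick = rng.permutation(n)[:n_chol] + leaflet * n
        is_chol[pick] = True
    names, resnames = [], []
    for i in range(2 * n):
        if is_chol[i]:
            names.append("C3")
            resnames.append("CHOL")
        else:
            names.append("P")
            # 4:1 zwitterionic/anionic composition among phospholipids
            resnames.append("DOPS" if i % 5 == 4 else "DOPC")
    return _SlabBase(coords=coords, names=names,
                     resnums=list(range(1, 2 * n + 1)), resnames=resnames,
                     box=np.array([box_xy, box_xy, box_z]), center_z=center_z)


def build_slab(spec: SyntheticSpec, rng: np.random.Generator | None = None
               ) -> Frame:
    """One frame of the bare membrane slab (no protein).

    Leaflet particles sit at ±thickness/2 about the box-centre plane on a
    square lattice whose lateral box realises the effective area per lipid
    exactly; Gaussian jitter of width ``positional_jitter_sigma`` is applied
    to every coordinate.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    base = _slab_base(spec, rng)
    coords = base.coords.copy()
    if spec.positional_jitter_sigma > 0:
        coords += rng.normal(0.0, spec.positional_jitter_sigma, coords.shape)
    return Frame(base.names, base.resnums, base.resnames, coords, base.box, 0.0)


# ---------------------------------------------------------------------------
# Protein template
# ---------------------------------------------------------------------------

@dataclass
class ProteinTemplate:
    """Rigid pseudo-protein scaffold, centroid at the origin."""

    names: list
    resnums: list
    resnames: list
    coords: np.ndarray            # (N, 3), nm
    marker_index: dict            # residue number -> atom row
    far_index: np.ndarray
    gtp_index: np.ndarray
    hvr_index: np.ndarray

    @property
    def beta1(self) -> np.ndarray:
        """Body-fixed β1 vector Cα5→Cα9."""
        return self.coords[self.marker_index[9]] - self.coords[self.marker_index[5]]

    @property
    def alpha5(self) -> np.ndarray:
        """Body-fixed α5 vector Cα156→Cα163."""
        return self.coords[self.marker_index[163]] - self.coords[self.marker_index[156]]

    @property
    def gamma(self) -> float:
        """Fixed inter-vector angle between β1 and α5, degrees."""
        return angle_to_normal(self.beta1, self.alpha5)[0]

    @property
    def z_marker_distance(self) -> float:
        """Rigid Cα132–Cα183 separation, nm."""
        d = self.coords[self.marker_index[132]] - self.coords[self.marker_index[183]]
        return float(np.linalg.norm(d))


# Internal scaffold geometry (nm), fixed constants.  The β1 direction is +z
# and the α5 direction makes a 60° angle with it, so requested (Θ, Φ) pairs
# with |Θ − Φ| up to 60° are realisable.  The Cα132–Cα183 arm is 1.86 nm,
# matching the z coordinate of the active-state centre.
_BETA1_LEN = 1.2
_ALPHA5_LEN = 1.05
_GAMMA_DEG = 60.0
_Z_ARM = 1.86
_HVR_RISE = 0.35  # nm per residue along the tail direction


def build_protein_template(scale: float = 1.0) -> ProteinTemplate:
    """Build the fixed rigid scaffold (optionally scaled about its centroid).

    Atoms: Cα markers for residues 5, 9, 132, 156, 163; backbone N/CA/C/O of
    HVR residues 180–184 (sequence K-S-K-T-K, the Cα of 183 doubling as the
    sixth marker); a 5-atom FAR cluster (residue 185) beyond the tail; and a
    5-atom GTP cluster (residue 500) near the catalytic domain.
    """
    g = np.radians(_GAMMA_DEG)
    u_dir = np.array([0.0, 0.0, 1.0])
    w_dir = np.array([np.sin(g), 0.0, np.cos(g)])
    t_dir = np.array([-0.3, -0.2, -1.0])
    t_dir = t_dir / np.linalg.norm(t_dir)

    ca = {5: np.array([0.0, 0.0, 0.0])}
    ca[9] = ca[5] + _BETA1_LEN * u_dir
    ca[156] = np.array([0.5, 0.5, 0.2])
    ca[163] = ca[156] + _ALPHA5_LEN * w_dir
    ca[132] = np.array([0.8, 0.2, 1.0])
    ca[183] = ca[132] + _Z_ARM * t_dir

    names, resnums, resnames, coords = [], [], [], []

    def add(name, resnum, resname, xyz):
        names.append(name)
        resnums.append(resnum)
        resnames.append(resname)
        coords.append(np.asarray(xyz, dtype=float))

    for num, rn in [(5, "GLY"), (9, "VAL"), (132, "ASP"),
                    (156, "GLU"), (163, "ARG")]:
        add("CA", num, rn, ca[num])

    hvr_resnames = {180: "LYS", 181: "SER", 182: "LYS", 183: "THR", 184: "LYS"}
    hvr_rows = []
    for num in range(180, 185):
        c = ca[183] + (num - 183) * _HVR_RISE * t_dir
        for name, off in [("N", (-0.12, 0.06, 0.02)), ("CA", (0.0, 0.0, 0.0)),
                          ("C", (0.12, -0.05, 0.05)), ("O", (0.14, 0.05, 0.16))]:
            hvr_rows.append(len(coords))
            add(name, num, hvr_resnames[num], c + np.array(off))

    # FAR cluster centred 0.9 nm beyond the tail end; offsets sum to zero so
    # the geometric centre is exact.
    far_center = ca[183] + (2 * _HVR_RISE + 0.2) * t_dir
    cluster_offsets = np.array([[0.1, 0.0, 0.0], [-0.1, 0.0, 0.0],
                                [0.0, 0.1, 0.0], [0.0, -0.1, 0.05],
                                [0.0, 0.0, -0.05]])
    far_rows = []
    for k, off in enumerate(cluster_offsets, start=1):
        far_rows.append(len(coords))
        add(f"F{k}", 185, "FAR", far_center + off)

    gtp_center = np.array([1.0, 0.9, 1.6])
    gtp_rows = []
    for k, off in enumerate(cluster_offsets, start=1):
        gtp_rows.append(len(coords))
        add(f"G{k}", 500, "GTP", gtp_center + off)

    coords = np.array(coords)
    coords -= coords.mean(axis=0)           # centroid at the origin
    coords *= scale
    marker_index = {num: i for i, num in enumerate([5, 9, 132, 156, 163])}
    marker_index[183] = hvr_rows[3 * 4 + 1]  # CA of residue 183
    return ProteinTemplate(names=names, resnums=resnums, resnames=resnames,
                           coords=coords, marker_index=marker_index,
                           far_index=np.array(far_rows),
                           gtp_index=np.array(gtp_rows),
                           hvr_index=np.array(hvr_rows))


# ---------------------------------------------------------------------------
# Rigid placement
# ---------------------------------------------------------------------------

def feasible_phi_interval(theta_deg: float, gamma_deg: float
                          ) -> tuple[float, float]:
    """Attainable Φ range for a given Θ and body-fixed angle γ (degrees)."""
    lo = abs(theta_deg - gamma_deg)
    hi = min(theta_deg + gamma_deg, 360.0 - theta_deg - gamma_deg)
    return lo, hi


def _placement_rotation(u: np.ndarray, w: np.ndarray, theta_deg: float,
                        phi_deg: float) -> np.ndarray:
    """Proper rotation taking body axes (u, w) to lab tilts (Θ, Φ).

    Two-stage construction: put u on the Θ-cone in the xz-plane, then rotate
    about u so w meets the Φ-cone; of the two solutions the one with a
    non-negative out-of-plane component is chosen (the smaller rotation).
    """
    u = np.asarray(u, float) / np.linalg.norm(u)
    w = np.asarray(w, float) / np.linalg.norm(w)
    cg = float(np.clip(np.dot(u, w), -1.0, 1.0))
    gamma = np.degrees(np.arccos(cg))
    sg = np.sqrt(max(1.0 - cg * cg, 0.0))
    th = np.radians(theta_deg)
    ph = np.radians(phi_deg)
    st, ct = np.sin(th), np.cos(th)
    lo, hi = feasible_phi_interval(theta_deg, gamma)
    tol = 1e-9
    if not (lo - tol <= phi_deg <= hi + tol):
        raise FeasibilityError(
            f"requested (Θ={theta_deg:g}°, Φ={phi_deg:g}°) is unattainable for "
            f"a body-fixed angle γ={gamma:.3f}°; attainable Φ interval at this "
            f"Θ is [{lo:.3f}°, {hi:.3f}°]")
    a = np.array([st, 0.0, ct])
    if st < 1e-12 or sg < 1e-12:
        # u along the normal (or w parallel to u): Φ is forced; any
        # transverse basis works.
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 = (np.array([0.0, 0.0, 1.0]) - ct * a) / st
    e2 = np.cross(a, e1)
    if st < 1e-12 or sg < 1e-12:
        cpsi = 1.0
    else:
        cpsi = float(np.clip((np.cos(ph) - cg * ct) / (sg * st), -1.0, 1.0))
    spsi = np.sqrt(max(1.0 - cpsi * cpsi, 0.0))
    b = cpsi * e1 + spsi * e2
    # orthonormal body basis (u, u_perp, u × u_perp) with w in the (u, u_perp)
    # plane on the +u_perp side
    if sg < 1e-12:
        u_perp = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u_perp = u_perp - np.dot(u_perp, u) * u
        u_perp /= np.linalg.norm(u_perp)
    else:
        u_perp = (w - cg * u) / sg
    body = np.column_stack([u, u_perp, np.cross(u, u_perp)])
    lab = np.column_stack([a, b, np.cross(a, b)])
    return lab @ body.T


def place_protein(template: ProteinTemplate, theta_deg: float, phi_deg: float,
                  depth_far: float, center_z: float,
                  xy: tuple[float, float] = (0.0, 0.0),
                  depth_gtp: float | None = None
                  ) -> tuple[np.ndarray, float, float]:
    """Rigidly place the scaffold at requested tilts and anchor depth.

    Returns ``(coords, realized_theta, realized_phi)``.  The FAR cluster
    centre is put at ``(xy, center_z + depth_far)``; if ``depth_gtp`` is
    given, the GTP cluster (an independently bound ligand, not part of the
    rigid body) is additionally shifted along z so its centre sits at that
    depth.  An unattainable (Θ, Φ) pair raises
    :class:`~memorient.errors.FeasibilityError` naming the feasible interval;
    accepted requests are realised to ≈1e-6 degree.
    """
    R = _placement_rotation(template.beta1, template.alpha5,
                            theta_deg, phi_deg)
    coords = template.coords @ R.T
    far_c = coords[template.far_index].mean(axis=0)
    shift = np.array([xy[0] - far_c[0], xy[1] - far_c[1],
                      center_z + depth_far - far_c[2]])
    coords = coords + shift
    if depth_gtp is not None:
        gtp_c_z = coords[template.gtp_index, 2].mean()
        coords[template.gtp_index, 2] += (center_z + depth_gtp) - gtp_c_z
    i = template.marker_index
    th, _ = angle_to_normal(coords[i[9]] - coords[i[5]])
    ph, _ = angle_to_normal(coords[i[163]] - coords[i[156]])
    return coords, th, ph


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at the boundaries."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def _angle_schedules(spec: SyntheticSpec, gamma: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = spec.n_frames
    if spec.sigma_angle <= 0:
        theta = np.full(n, spec.theta)
        phi = np.full(n, spec.phi)
    else:
        sig = spec.sigma_angle
        rho = spec.angle_rho
        innov = sig * np.sqrt(1.0 - rho * rho)
        theta = np.empty(n)
        phi = np.empty(n)
        t, p = spec.theta, spec.phi
        for k in range(n):
            theta[k], phi[k] = t, p
            t = spec.theta + rho * (t - spec.theta) + innov * rng.normal()
            p = spec.phi + rho * (p - spec.phi) + innov * rng.normal()
        theta = _reflect(theta, 1.0, 179.0)
        phi = _reflect(phi, 0.0, 180.0)
    # keep requested pairs strictly feasible for the scaffold: Φ is projected
    # into the attainable interval (with a 1° margin) before placement, so
    # placement itself never needs to clamp
    margin = 1.0
    for k in range(n):
        lo, hi = feasible_phi_interval(theta[k], gamma)
        phi[k] = float(np.clip(phi[k], lo + margin, hi - margin))
    return theta, phi


def _depth_schedule(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_frames
    if spec.depth_levels is None:
        return np.full(n, spec.depth_far)
    levels = np.asarray(spec.depth_levels, dtype=float)
    state = np.empty(n, dtype=int)
    s = 0  # start anchored (lower level)
    for k in range(n):
        state[k] = s
        if rng.random() < spec.switch_prob:
            s = 1 - s
    return levels[state]


def generate_trajectory(spec: SyntheticSpec
                        ) -> tuple[list[Frame], pd.DataFrame]:
    """Generate frames plus a per-frame ground-truth table.

    The truth table holds, per frame, the requested and realised (Θ, Φ), the
    FAR/GTP depths, the rigid Cα132–Cα183 separation, and the slab targets
    (effective area per lipid, thickness, box edges).  Deterministic under
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = _slab_base(spec, rng)
    template = build_protein_template()
    gamma = template.gamma
    theta_s, phi_s = _angle_schedules(spec, gamma, rng)
    dfar_s = _depth_schedule(spec, rng)
    xy = (base.box[0] / 2.0, base.box[1] / 2.0)

    frames: list[Frame] = []
    rows = []
    all_names = base.names + template.names
    all_resnums = base.resnums + template.resnums
    all_resnames = base.resnames + template.resnames
    n_lip = base.coords.shape[0]
    for k in range(spec.n_frames):
        lip = base.coords.copy()
        if spec.positional_jitter_sigma > 0:
            lip += rng.normal(0.0, spec.positional_jitter_sigma, lip.shape)
        prot, th_real, ph_real = place_protein(
            template, theta_s[k], phi_s[k], dfar_s[k], base.center_z,
            xy=xy, depth_gtp=spec.depth_gtp)
        if spec.marker_noise_sigma > 0:
            prot = prot + rng.normal(0.0, spec.marker_noise_sigma, prot.shape)
        coords = np.vstack([lip, prot])
        frames.append(Frame(all_names, all_resnums, all_resnames, coords,
                            base.box, time=k * spec.frame_dt))
        rows.append(dict(frame=k, time=k * spec.frame_dt,
                         theta_req=theta_s[k], phi_req=phi_s[k],
                         theta_realized=th_real, phi_realized=ph_real,
                         depth_far=dfar_s[k], depth_gtp=spec.depth_gtp,
                         z_marker=template.z_marker_distance,
                         apl_true=spec.effective_apl,
                         thickness_true=spec.target_thickness,
                         box_x=base.box[0], box_y=base.box[1],
                         box_z=base.box[2], center_z=base.center_z))
    truth = pd.DataFrame(rows)
    return frames, truth
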