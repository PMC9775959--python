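"""Ligand binding free energies by a simplified PDLD/S-LRA/beta scheme.

The electrostatic part averages the ligand-receptor Coulomb interaction over
the configuration relaxed with full ligand charges and the configuration
relaxed with the charges switched off (linear response approximation, here
with single relaxed configurations rather than MD ensembles), plus a
Langevin-dipole-inspired grid correction for the solvation the ligand loses
on leaving bulk water.  The non-electrostatic part is a beta-scaled
ligand-receptor van der Waals energy (linear interaction energy form):

    dG_bind = 1/2 [ <U_elec>_charged + <U_elec>_uncharged ]
              + (dG_solv^bound - dG_solv^free) + beta * U_vdw

Docking is out of scope: poses are authored inputs or come from the
synthetic pocket constructor, and ligand partial charges are inputs.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .cg_model import CGStructure
from .energetics import EnergyParams, COULOMB_K, _vdw_86, _cutoff_switch
from .morphing import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "Ligand", "BindingParams", "Pose", "lra_electrostatic",
    "binding_free_energy", "bind_along_path", "write_ligand_table",
    "read_ligand_table",
]


@dataclass
class Ligand:
    """Small-molecule ligand as named particles with authored charges."""

    name: str
    atom_names: list
    positions: np.ndarray   # (A, 3)
    charges: np.ndarray     # (A,) e
    radii: np.ndarray       # (A,) vdW r0/2 contribution
    depths: np.ndarray      # (A,) kcal/mol

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        a = len(self.atom_names)
        if a == 0:
            raise ValueError("ligand needs at least one atom")
        if not (len(self.charges) == len(self.radii) == len(self.depths) == a
                and self.positions.shape == (a, 3)):
            raise ValueError("ligand field lengths disagree")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("non-finite ligand charges")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def moved(self, rotation=None, translation=None) -> "Ligand":
        pos = self.positions
        if rotation is not None:
            c = pos.mean(axis=0)
            pos = (pos - c) @ np.asarray(rotation).T + c
        if translation is not None:
            pos = pos + np.asarray(translation)
        return Ligand(self.name, list(self.atom_names), pos,
                      self.charges.copy(), self.radii.copy(),
                      self.depths.copy())


@dataclass
class BindingParams:
    beta: float = 0.25              # vdW scale of the LIE term
    dielectric_in: float = 6.0      # effective pocket dielectric
    dielectric_out: float = 80.0    # bulk dielectric
    grid_spacing: float = 1.5       # A, solvent-dipole grid
    include_solvation: bool = True
    # rigid single-configuration evaluation by default; the optional 6-dof
    # pose relaxation realises the charged/uncharged LRA endpoints but can
    # hop between pocket minima from frame to frame
    relax_poses: bool = False
    solv_shell: tuple = (2.5, 6.0)  # A, dipole shell around ligand atoms
    solv_scale: float = 10.0        # kcal/mol per (e/A^2)^2/A^3, grid weight
    solv_saturation: float = 0.15   # e/A^2, Langevin-type field saturation
    clash_distance: float = 1.0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class Pose:
    """A ligand placed in the receptor frame."""

    ligand: Ligand
    receptor_frame_index: int = 0
    anchor_residues: list = field(default_factory=list)  # (chain, resnum)


# --- receptor bead views -----------------------------------------------------

def _receptor_arrays(receptor: CGStructure,
                     charges: np.ndarray | None,
                     params: EnergyParams):
    from .energetics import build_bead_system
    system = build_bead_system(receptor, charges, None, params)
    return system.pos, system.charge, system.radius, system.depth


def _check_clash(lig_pos, rec_pos, limit) -> float:
    d = np.linalg.norm(lig_pos[:, None, :] - rec_pos[None, :, :], axis=-1)
    dmin = float(d.min()) if d.size else np.inf
    if dmin < limit:
        raise ValueError(f"ligand clashes with receptor "
                         f"(min distance {dmin:.2f} A)")
    return dmin


def _coulomb(lig: Ligand, rec_pos, rec_q, params: BindingParams) -> float:
    d = np.linalg.norm(lig.positions[:, None, :] - rec_pos[None, :, :], axis=-1)
    with np.errstate(divide="ignore"):
        e = COULOMB_K * lig.charges[:, None] * rec_q[None, :] \
            / (params.dielectric_in * d)
    return float(np.sum(np.where(d > 1e-9, e, 0.0)))


def _vdw(lig: Ligand, rec_pos, rec_r, rec_eps, eparams: EnergyParams) -> float:
    d = np.linalg.norm(lig.positions[:, None, :] - rec_pos[None, :, :], axis=-1)
    r0 = lig.radii[:, None] + rec_r[None, :]
    eps = np.sqrt(lig.depths[:, None] * rec_eps[None, :])
    e, _ = _vdw_86(np.maximum(d, 0.2), r0, eps)
    sw, _ = _cutoff_switch(d, eparams)
    return float(np.sum(np.where(d < eparams.cutoff, e * sw, 0.0)))


def _solvation(lig: Ligand, params: BindingParams,
               rec_pos: np.ndarray | None = None,
               rec_r: np.ndarray | None = None) -> float:
    """Langevin-dipole-inspired grid estimate of the ligand's solvation.

    Dipole sites on a cubic grid within a shell around the ligand; sites
    occluded by receptor beads (bound state) are removed.  Each site
    contributes a saturating quadratic response to the ligand field."""
    if np.all(lig.charges == 0):
        return 0.0
    s = params.grid_spacing
    lo = lig.positions.min(axis=0) - params.solv_shell[1]
    hi = lig.positions.max(axis=0) + params.solv_shell[1]
    axes = [np.arange(lo[k], hi[k] + s, s) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d = np.linalg.norm(pts[:, None, :] - lig.positions[None, :, :], axis=-1)
    dmin = d.min(axis=1)
    keep = (dmin >= params.solv_shell[0]) & (dmin <= params.solv_shell[1])
    pts, d = pts[keep], d[keep]
    if rec_pos is not None and len(rec_pos):
        # smooth occlusion: a site buried by a receptor bead contributes
        # nothing, with a 1.5 A taper so re-anchored poses vary continuously
        dr = np.linalg.norm(pts[:, None, :] - rec_pos[None, :, :], axis=-1)
        gap = np.min(dr - rec_r[None, :], axis=1)
        t = np.clip(gap / 1.5, 0.0, 1.0)
        occ = t * t * (3.0 - 2.0 * t)
    else:
        occ = np.ones(len(pts))
    if len(pts) == 0:
        return 0.0
    vec = pts[:, None, :] - lig.positions[None, :, :]
    field = np.sum(lig.charges[None, :, None] * vec / d[:, :, None] ** 3,
                   axis=1)
    fmag2 = np.sum(field * field, axis=1)
    fmag = np.sqrt(fmag2)
    resp = fmag2 / (1.0 + fmag / params.solv_saturation)
    scale = params.solv_scale * (1.0 - 1.0 / params.dielectric_out) * s ** 3
    return float(-scale * np.sum(occ * resp))


# --- pose relaxation ---------------------------------------------------------

def _relax_pose(lig: Ligand, rec_pos, rec_q, rec_r, rec_eps,
                params: BindingParams, eparams: EnergyParams,
                with_charges: bool) -> Ligand:
    """Rigid-body (6-dof) relaxation of the ligand in the pocket."""
    x0 = np.zeros(6)

    def place(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        return lig.moved(rotation=rot, translation=x[3:])

    def obj(x):
        trial = place(x)
        d = np.linalg.norm(trial.positions[:, None, :] - rec_pos[None, :, :],
                           axis=-1)
        if d.min() < params.clash_distance:
            return 1e6 * (params.clash_distance - d.min() + 1.0)
        e = _vdw(trial, rec_pos, rec_r, rec_eps, eparams)
        if with_charges:
            e += _coulomb(trial, rec_pos, rec_q, params)
        return e

    res = minimize(obj, x0, method="Powell",
                   options={"maxiter": 60, "xtol": 1e-3, "ftol": 1e-4})
    return place(res.x)


# --- the binding operations --------------------------------------------------

def lra_electrostatic(pose: Pose, receptor: CGStructure,
                      charges: np.ndarray | None = None,
                      params: BindingParams | None = None,
                      energy_params: EnergyParams | None = None) -> float:
    """LRA electrostatic binding energy.

    Returns 0.5*(U_charged + U_uncharged) where the two interaction energies
    are evaluated in the configurations relaxed with full and with zeroed
    ligand charges, plus the solvation the ligand loses on burial
    (bound-state minus free-state dipole-grid solvation) when
    ``include_solvation`` is on.  Exactly zero for an apolar ligand.
    """
    params = params or BindingParams()
    eparams = energy_params or EnergyParams()
    lig = pose.ligand
    rec_pos, rec_q, rec_r, rec_eps = _receptor_arrays(receptor, charges, eparams)
    _check_clash(lig.positions, rec_pos, params.clash_distance)
    if np.all(lig.charges == 0):
        return 0.0

    if params.relax_poses:
        lig_c = _relax_pose(lig, rec_pos, rec_q, rec_r, rec_eps, params,
                            eparams, with_charges=True)
        lig_u = _relax_pose(lig, rec_pos, rec_q, rec_r, rec_eps, params,
                            eparams, with_charges=False)
    else:
        lig_c = lig_u = lig
    u_charged = _coulomb(lig_c, rec_pos, rec_q, params)
    u_uncharged = _coulomb(lig_u, rec_pos, rec_q, params)
    e = 0.5 * (u_charged + u_uncharged)
    if params.include_solvation:
        e += _solvation(lig_c, params, rec_pos, rec_r) \
            - _solvation(lig_c, params)
    return float(e)


def binding_free_energy(pose: Pose, receptor: CGStructure,
                        charges: np.ndarray | None = None,
                        params: BindingParams | None = None,
                        energy_params: EnergyParams | None = None) -> float:
    """Full PDLD/S-LRA/beta-style estimate: LRA electrostatics plus the
    beta-scaled ligand-receptor van der Waals term."""
    params = params or BindingParams()
    eparams = energy_params or EnergyParams()
    lig = pose.ligand
    rec_pos, rec_q, rec_r, rec_eps = _receptor_arrays(receptor, charges, eparams)
    _check_clash(lig.positions, rec_pos, params.clash_distance)
    if params.relax_poses:
        lig_c = _relax_pose(lig, rec_pos, rec_q, rec_r, rec_eps, params,
                            eparams, with_charges=bool(np.any(lig.charges)))
    else:
        lig_c = lig
    elec = lra_electrostatic(pose, receptor, charges, params, eparams)
    vdw = _vdw(lig_c, rec_pos, rec_r, rec_eps, eparams)
    return float(elec + params.beta * vdw)


def _anchor_positions(structure: CGStructure, anchors) -> np.ndarray:
    pts = []
    for chain, resnum in anchors:
        i = structure.residue_id(chain, resnum)
        pts.append(structure.sc_pos[i] if structure.has_sc[i]
                   else structure.bb_pos[i])
    return np.array(pts)


def bind_along_path(frames, pose_template: Pose,
                    charges_per_frame=None,
                    params: BindingParams | None = None,
                    energy_params: EnergyParams | None = None) -> np.ndarray:
    """Binding energy of the ligand re-anchored to each frame of a path.

    The pose is carried from the template's frame to every other frame by a
    rigid fit on the anchor (pocket) residues' beads.  Frames where the
    re-anchored ligand clashes irrecoverably get energy 0 with a warning.
    """
    params = params or BindingParams()
    eparams = energy_params or EnergyParams()
    frame_list = frames.frames if isinstance(frames, Trajectory) else list(frames)
    anchors = pose_template.anchor_residues
    if not anchors:
        raise ValueError("pose template needs anchor residues")
    ref = frame_list[pose_template.receptor_frame_index]
    for chain, resnum in anchors:
        ref.residue_id(chain, resnum)  # raises if the pocket is absent
    ref_pts = _anchor_positions(ref, anchors)

    energies = np.zeros(len(frame_list))
    for k, frame in enumerate(frame_list):
        pts = _anchor_positions(frame, anchors)
        rc, fc = ref_pts.mean(axis=0), pts.mean(axis=0)
        rot, _ = Rotation.align_vectors(pts - fc, ref_pts - rc)
        lig_pos = (pose_template.ligand.positions - rc) @ rot.as_matrix().T + fc
        lig = pose_template.ligand.moved()
        lig.positions = lig_pos
        ch = None if charges_per_frame is None else charges_per_frame[k]
        try:
            energies[k] = binding_free_energy(
                Pose(lig, k, anchors), frame, ch, params, eparams)
        except ValueError as exc:
            logger.warning("frame %d: pose anchoring failed (%s); "
                           "binding energy set to 0", k, exc)
            energies[k] = 0.0
    return energies


# --- ligand tabular text format ---------------------------------------------

LIGAND_COLUMNS = ["atom", "charge", "radius", "depth", "x", "y", "z"]


def write_ligand_table(lig: Ligand) -> str:
    df = pd.DataFrame({
        "atom": lig.atom_names, "charge": lig.charges,
        "radius": lig.radii, "depth": lig.depths,
        "x": lig.positions[:, 0], "y": lig.positions[:, 1],
        "z": lig.positions[:, 2],
    })
    buf = io.StringIO()
    buf.write(f"# ligand {lig.name}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.6f")
    return buf.getvalue()


def read_ligand_table(text: str) -> Ligand:
    lines = text.splitlines()
    name = "ligand"
    body = []
    for ln in lines:
        if ln.startswith("# ligand"):
            name = ln.split("# ligand", 1)[1].strip()
        elif ln.strip():
            body.append(ln)
    df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
    return Ligand(name, df["atom"].tolist(),
                  df[["x", "y", "z"]].to_numpy(),
                  df["charge"].to_numpy(), df["radius"].to_numpy(),
                  df["depth"].to_numpy())
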