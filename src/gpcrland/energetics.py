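"""Coarse-grained folding free energy in an implicit membrane.

The landscape energy of one conformation is a weighted sum of eight terms,

    dG_fold = c1*dG_side_vdw + c2*dG_solv + c3*dG_hb
              + dG_side_elec + dG_side_polar + dG_side_hyd
              + dG_mainside_elec + dG_mainside_vdw

with c1 = 0.10, c2 = 0.25, c3 = 0.15.  Functional forms:

* van der Waals terms use a soft 8-6 potential with a 10-12 A switch;
  membrane lattice particles contribute repulsive exclusion only.
* electrostatics use Coulomb 332*q_i*q_j/(eps(r)*r) with the
  distance-dependent dielectric eps(r) = 6r, scaled by 0.25 when both beads
  sit inside the membrane slab (stronger interactions in the low-dielectric
  core).
* solvation / polar / hydrophobic terms are per-bead burial energies: a
  smooth neighbour count mapped through a saturating function, weighted by
  the bead's environment (water / interface / membrane).
* the helical hydrogen-bond surrogate rewards each i,i+4 backbone pair whose
  distance falls in a smooth 5.0-6.5 A window.

All energies in kcal/mol, lengths in A, charges in elementary charge units.
Every tunable lives on :class:`EnergyParams` so recalibration never touches
code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .cg_model import (
    CGStructure, BACKBONE_RADIUS, BACKBONE_DEPTH, HYDROPHOBIC, POLAR,
)

logger = logging.getLogger(__name__)

COULOMB_K = 332.0     # kcal*A/(mol*e^2)
KB = 0.0019872        # kcal/mol/K

TERM_NAMES = (
    "side_vdw", "main_solv", "main_hb", "side_elec",
    "side_polar", "side_hyd", "main_side_elec", "main_side_vdw",
)

ENV_WATER, ENV_INTERFACE, ENV_MEMBRANE = 0, 1, 2


class EnergyError(RuntimeError):
    pass


@dataclass
class EnergyParams:
    """All force-field constants of the CG energy, in one editable table."""

    c1: float = 0.10
    c2: float = 0.25
    c3: float = 0.15
    # nonbonded range
    cutoff_on: float = 10.0
    cutoff: float = 12.0
    # electrostatics: eps(r) = eps_slope * r in water
    eps_slope: float = 6.0
    membrane_eps_factor: float = 0.25
    backbone_charge: float = 0.05  # alternating +/- dipolar partial charge
    # burial (smooth neighbour count); sequence-local neighbours within
    # burial_seq_exclusion residues on the same chain never count, so an
    # isolated helix reads as exposed
    burial_on: float = 6.0
    burial_off: float = 8.0
    burial_nsat: float = 8.0
    burial_seq_exclusion: int = 4
    # per-bead term weights
    w_solv: float = 0.5
    e_hb: float = 1.0
    hb_window: tuple = (5.0, 5.3, 6.2, 6.5)
    w_polar: float = 1.0
    w_hyd: float = 0.8
    # membrane slab / lattice
    slab_half_thickness: float = 15.0
    interface_halfwidth: float = 3.0
    mem_spacing: float = 5.0
    mem_margin: float = 8.0
    mem_exclusion: float = 4.0
    mem_radius: float = 2.2
    mem_depth: float = 0.2
    # safety
    clash_distance: float = 0.1
    # relaxation restraints: strong on backbone beads (frames must keep
    # their place on the reaction coordinate), weak on side-chain beads so
    # relaxation relieves strain without hopping between packing basins
    restraint_k: float = 2.0       # kcal/mol/A^2 on backbone beads
    side_restraint_k: float = 0.3  # kcal/mol/A^2 on side-chain beads

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hb_window"] = list(self.hb_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyParams":
        d = dict(d)
        if "hb_window" in d:
            d["hb_window"] = tuple(d["hb_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "EnergyParams":
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


@dataclass
class EnergyBreakdown:
    """The eight folding-energy terms plus their weighted total."""

    side_vdw: float
    main_solv: float
    main_hb: float
    side_elec: float
    side_polar: float
    side_hyd: float
    main_side_elec: float
    main_side_vdw: float
    total: float

    def terms(self) -> dict:
        return {name: getattr(self, name) for name in TERM_NAMES}

    def as_dict(self) -> dict:
        d = self.terms()
        d["total"] = self.total
        return d


@dataclass
class Membrane:
    """Implicit membrane slab with optional neutral lattice particles."""

    z_low: float
    z_high: float
    particles: np.ndarray  # (M, 3), may be empty

    def __post_init__(self):
        if not self.z_low < self.z_high:
            raise ValueError("membrane slab requires z_low < z_high")
        self.particles = np.asarray(self.particles, dtype=float).reshape(-1, 3)

    def environment(self, z: np.ndarray, halfwidth: float = 3.0) -> np.ndarray:
        """Per-position environment code: water / interface / membrane."""
        z = np.asarray(z, dtype=float)
        env = np.full(z.shape, ENV_WATER, dtype=int)
        near_edge = (np.abs(z - self.z_low) <= halfwidth) | \
                    (np.abs(z - self.z_high) <= halfwidth)
        inside = (z > self.z_low + halfwidth) & (z < self.z_high - halfwidth)
        env[near_edge] = ENV_INTERFACE
        env[inside] = ENV_MEMBRANE
        return env


def build_membrane(structure: CGStructure, slab_half_thickness: float | None = None,
                   params: EnergyParams | None = None,
                   exclude_positions: np.ndarray | None = None,
                   with_particles: bool = True) -> Membrane:
    """Centre a slab on the transmembrane centroid and fill it with a
    hexagonal lattice of neutral particles, leaving a cavity around the
    protein.

    ``exclude_positions`` may supply extra coordinates (e.g. every frame of a
    trajectory) so a single membrane serves a whole path without lattice
    particles overlapping any frame.
    """
    params = params or EnergyParams()
    half = slab_half_thickness if slab_half_thickness is not None \
        else params.slab_half_thickness
    zc = float(structure.bb_pos[:, 2].mean())
    z_low, z_high = zc - half, zc + half

    beads = _protein_positions(structure)
    inside = (beads[:, 2] >= z_low) & (beads[:, 2] <= z_high)
    if not inside.any():
        warnings.warn("no beads inside membrane slab; membrane left empty")
        return Membrane(z_low, z_high, np.empty((0, 3)))
    if not with_particles:
        return Membrane(z_low, z_high, np.empty((0, 3)))

    excl = beads if exclude_positions is None else np.vstack(
        [beads, np.asarray(exclude_positions, dtype=float).reshape(-1, 3)])

    s = params.mem_spacing
    m = params.mem_margin
    x0, y0 = beads[:, 0].mean(), beads[:, 1].mean()
    ext_x = beads[:, 0].max() - beads[:, 0].min()
    ext_y = beads[:, 1].max() - beads[:, 1].min()
    nx = int(np.ceil((ext_x / 2 + m) / s)) + 1
    ny = int(np.ceil((ext_y / 2 + m) / (s * np.sqrt(3) / 2))) + 1
    pts = []
    z_layers = np.arange(z_low + s / 2, z_high, s)
    for k in range(-ny, ny + 1):
        y = y0 + k * s * np.sqrt(3) / 2
        # half-offset rows use a symmetric {..,-1.5,-0.5,0.5,1.5,..}*s pattern
        # so the lattice is invariant under 180-degree rotation about centre
        offs = 0.5 if (k % 2) else 0.0
        xs = x0 + (np.arange(-nx, nx + 1) + offs) * s
        for x in xs:
            for z in z_layers:
                pts.append((x, y, z))
    pts = np.array(pts) if pts else np.empty((0, 3))
    if len(pts) and len(excl):
        tree = cKDTree(excl)
        dmin, _ = tree.query(pts, k=1)
        pts = pts[dmin >= params.mem_exclusion]
    return Membrane(z_low, z_high, pts)


# --- internal flat bead system ---------------------------------------------

@dataclass
class BeadSystem:
    """Flat array view of a CG structure for vectorised energy kernels."""

    pos: np.ndarray        # (N, 3)
    is_bb: np.ndarray      # (N,)
    res: np.ndarray        # (N,) residue index
    radius: np.ndarray     # (N,)
    depth: np.ndarray      # (N,)
    charge: np.ndarray     # (N,)
    restype: np.ndarray    # (N,)
    env: np.ndarray        # (N,) environment codes
    hb_pairs: np.ndarray   # (P, 2) backbone i,i+4 bead indices
    chain_code: np.ndarray  # (N,) integer chain id per bead
    resnum: np.ndarray     # (N,) residue number per bead
    mem_pos: np.ndarray    # (M, 3) membrane particles
    n_res: int
    has_sc: np.ndarray     # (R,) from structure
    sc_bead_index: np.ndarray  # (R,) flat index of side bead or -1

    @property
    def n(self) -> int:
        return len(self.pos)


def _protein_positions(structure: CGStructure) -> np.ndarray:
    return np.vstack([structure.bb_pos, structure.sc_pos[structure.has_sc]])


def build_bead_system(structure: CGStructure,
                      charges: np.ndarray | None = None,
                      membrane: Membrane | None = None,
                      params: EnergyParams | None = None) -> BeadSystem:
    """Assemble flat bead arrays.  ``charges`` is per-residue side-chain
    charge (e); backbone beads get small alternating dipolar charges."""
    params = params or EnergyParams()
    R = structure.n_residues
    n_sc = int(structure.has_sc.sum())
    N = R + n_sc

    pos = np.vstack([structure.bb_pos, structure.sc_pos[structure.has_sc]])
    is_bb = np.zeros(N, dtype=bool)
    is_bb[:R] = True
    res = np.concatenate([np.arange(R), np.arange(R)[structure.has_sc]])
    radius = np.concatenate([np.full(R, BACKBONE_RADIUS),
                             structure.side_radii()[structure.has_sc]])
    depth = np.concatenate([np.full(R, BACKBONE_DEPTH),
                            structure.side_depths()[structure.has_sc]])
    restype = np.concatenate([structure.restype, structure.restype[structure.has_sc]])

    charge = np.zeros(N)
    # alternating backbone dipolar partial charges (net ~0 per chain)
    charge[:R] = params.backbone_charge * np.where(np.arange(R) % 2 == 0, 1.0, -1.0)
    if charges is not None:
        charges = np.asarray(charges, dtype=float)
        if charges.shape != (R,):
            raise ValueError("charges must be per-residue, shape (R,)")
        charge[R:] = charges[structure.has_sc]

    sc_bead_index = np.full(R, -1, dtype=int)
    sc_bead_index[structure.has_sc] = R + np.arange(n_sc)

    # i,i+4 backbone pairs within a chain with contiguous numbering
    hb = []
    for i in range(R - 4):
        j = i + 4
        if structure.chain[i] == structure.chain[j] and \
                structure.resnum[j] - structure.resnum[i] == 4:
            hb.append((i, j))
    hb_pairs = np.array(hb, dtype=int).reshape(-1, 2)

    if membrane is not None:
        env = membrane.environment(pos[:, 2], params.interface_halfwidth)
        mem_pos = membrane.particles
    else:
        env = np.full(N, ENV_WATER, dtype=int)
        mem_pos = np.empty((0, 3))
    _, chain_int = np.unique(structure.chain, return_inverse=True)
    chain_code = np.concatenate([chain_int, chain_int[structure.has_sc]])
    resnum = np.concatenate([structure.resnum,
                             structure.resnum[structure.has_sc]])
    return BeadSystem(pos, is_bb, res, radius, depth, charge, restype, env,
                      hb_pairs, chain_code, resnum, mem_pos, R,
                      structure.has_sc.copy(), sc_bead_index)


# --- switching functions ----------------------------------------------------

def _smoothstep(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamped cubic smoothstep and its derivative wrt t."""
    tc = np.clip(t, 0.0, 1.0)
    s = tc * tc * (3.0 - 2.0 * tc)
    ds = np.where((t > 0.0) & (t < 1.0), 6.0 * tc * (1.0 - tc), 0.0)
    return s, ds


def _cutoff_switch(r, params):
    """1 below cutoff_on, smooth to 0 at cutoff."""
    w = params.cutoff - params.cutoff_on
    s, ds = _smoothstep((params.cutoff - r) / w)
    return s, -ds / w


def _burial_kernel(r, params):
    w = params.burial_off - params.burial_on
    s, ds = _smoothstep((params.burial_off - r) / w)
    return s, -ds / w


def _hb_window(r, params):
    a, b, c, d = params.hb_window
    s1, ds1 = _smoothstep((r - a) / (b - a))
    s2, ds2 = _smoothstep((d - r) / (d - c))
    w = s1 * s2
    dw = ds1 / (b - a) * s2 - s1 * ds2 / (d - c)
    return w, dw


def _vdw_86(r, r0, eps):
    """Soft 8-6 potential with minimum -eps at r0, and d/dr."""
    x = r0 / r
    x2 = x * x
    x6 = x2 * x2 * x2
    x8 = x6 * x2
    e = eps * (3.0 * x8 - 4.0 * x6)
    de = eps * 24.0 * (x6 - x8) / r
    return e, de


# --- the eight terms --------------------------------------------------------

def _evaluate(system: BeadSystem, params: EnergyParams,
              compute_grad: bool = False):
    """Compute all eight terms (and optionally the gradient of the weighted
    total wrt bead positions).  A single neighbour-list pass covers every
    pair term; beads further apart than the cutoff never interact.

    Term values are unweighted; the gradient, when requested, carries the
    c1/c2/c3 weights so it is exactly the gradient of ``combine_terms``."""
    pos = system.pos
    N = system.n
    grad = np.zeros_like(pos) if compute_grad else None
    wt = {name: 1.0 for name in TERM_NAMES}
    wt["side_vdw"], wt["main_solv"], wt["main_hb"] = params.c1, params.c2, params.c3
    terms = dict.fromkeys(TERM_NAMES, 0.0)

    tree = cKDTree(pos)
    pairs = tree.query_pairs(params.cutoff, output_type="ndarray")
    if len(pairs):
        ii, jj = pairs[:, 0], pairs[:, 1]
        keep = system.res[ii] != system.res[jj]
        ii, jj = ii[keep], jj[keep]
    else:
        ii = jj = np.empty(0, dtype=int)
    diff_pair = pos[ii] - pos[jj]
    pair_r = np.sqrt(np.einsum("ij,ij->i", diff_pair, diff_pair))

    if len(pair_r) and pair_r.min() < params.clash_distance:
        k = int(np.argmin(pair_r))
        raise EnergyError(
            f"overlapping beads: residues {system.res[ii[k]]} and "
            f"{system.res[jj[k]]} at distance {pair_r[k]:.3f} A")

    grad_dEdr = np.zeros_like(pair_r) if compute_grad else None

    sw, dsw = _cutoff_switch(pair_r, params)
    bb_i, bb_j = system.is_bb[ii], system.is_bb[jj]
    both_sc = (~bb_i) & (~bb_j)
    bb_sc = bb_i ^ bb_j

    # van der Waals (8-6) on side-side and main-side pairs
    vdw_mask = both_sc | bb_sc
    vsel = np.where(vdw_mask)[0]
    if len(vsel):
        r = pair_r[vsel]
        r0 = system.radius[ii[vsel]] + system.radius[jj[vsel]]
        eps = np.sqrt(system.depth[ii[vsel]] * system.depth[jj[vsel]])
        e, de = _vdw_86(r, r0, eps)
        esw = e * sw[vsel]
        ss = both_sc[vsel]
        terms["side_vdw"] += float(esw[ss].sum())
        terms["main_side_vdw"] += float(esw[~ss].sum())
        if compute_grad:
            w = np.where(ss, wt["side_vdw"], 1.0)
            grad_dEdr[vsel] += w * (de * sw[vsel] + e * dsw[vsel])

    # electrostatics with eps(r) = eps_slope*r (0.25x inside the membrane)
    qq = system.charge[ii] * system.charge[jj]
    csel = np.where(np.abs(qq) > 1e-12)[0]
    if len(csel):
        r = pair_r[csel]
        mem_pair = (system.env[ii[csel]] == ENV_MEMBRANE) & \
                   (system.env[jj[csel]] == ENV_MEMBRANE)
        eps_factor = np.where(mem_pair, params.membrane_eps_factor, 1.0)
        e = COULOMB_K * qq[csel] / (params.eps_slope * eps_factor * r ** 2)
        de = -2.0 * e / r
        esw = e * sw[csel]
        ss = both_sc[csel]
        ms = bb_sc[csel]
        terms["side_elec"] += float(esw[ss].sum())
        terms["main_side_elec"] += float(esw[ms].sum())
        if compute_grad:
            used = ss | ms
            grad_dEdr[csel[used]] += (de * sw[csel] + e * dsw[csel])[used]

    # hydrogen-bond surrogate on i,i+4 backbone pairs
    if len(system.hb_pairs):
        hi, hj = system.hb_pairs[:, 0], system.hb_pairs[:, 1]
        dv = pos[hi] - pos[hj]
        r = np.sqrt(np.einsum("ij,ij->i", dv, dv))
        w, dw = _hb_window(r, params)
        terms["main_hb"] += float(-params.e_hb * np.sum(w))
        if compute_grad:
            f = (wt["main_hb"] * -params.e_hb * dw / r)[:, None] * dv
            np.add.at(grad, hi, f)
            np.add.at(grad, hj, -f)

    # burial: smooth neighbour count over protein beads of other residues
    kern, dkern = _burial_kernel(pair_r, params)
    b = np.zeros(N)
    seq_local = (system.chain_code[ii] == system.chain_code[jj]) & \
        (np.abs(system.resnum[ii] - system.resnum[jj])
         <= params.burial_seq_exclusion)
    bsel = np.where((pair_r < params.burial_off) & ~seq_local)[0]
    np.add.at(b, ii[bsel], kern[bsel])
    np.add.at(b, jj[bsel], kern[bsel])
    expb = np.exp(-b / params.burial_nsat)
    B = 1.0 - expb
    dBdb = expb / params.burial_nsat

    env = system.env
    is_mem = env == ENV_MEMBRANE
    is_water = env == ENV_WATER
    coef = np.zeros(N)  # per-bead (weighted) dE/dB
    solv_w = np.where(is_water, 1.0, np.where(is_mem, -1.0, 0.0))
    bb_sel = system.is_bb
    terms["main_solv"] += float(params.w_solv * np.sum(solv_w[bb_sel] * B[bb_sel]))
    coef[bb_sel] += wt["main_solv"] * params.w_solv * solv_w[bb_sel]
    polar_sc = (~system.is_bb) & np.isin(system.restype, list(POLAR))
    mult = np.where(is_mem, 2.0, 1.0)
    terms["side_polar"] += float(params.w_polar * np.sum(mult[polar_sc] * B[polar_sc]))
    coef[polar_sc] += params.w_polar * mult[polar_sc]
    hyd_sc = (~system.is_bb) & np.isin(system.restype, list(HYDROPHOBIC))
    hw = hyd_sc & ~is_mem
    hm = hyd_sc & is_mem
    terms["side_hyd"] += float(-params.w_hyd * np.sum(B[hw]))
    terms["side_hyd"] += float(-params.w_hyd * np.sum(1.0 - B[hm]))
    coef[hw] += -params.w_hyd
    coef[hm] += params.w_hyd
    if compute_grad and len(bsel):
        ci = coef[ii[bsel]] * dBdb[ii[bsel]] + coef[jj[bsel]] * dBdb[jj[bsel]]
        grad_dEdr[bsel] += ci * dkern[bsel]

    if compute_grad and len(pair_r):
        f = (grad_dEdr / pair_r)[:, None] * diff_pair
        np.add.at(grad, ii, f)
        np.add.at(grad, jj, -f)

    # membrane lattice particles: repulsive vdW exclusion only
    if len(system.mem_pos):
        mtree = cKDTree(system.mem_pos)
        rmax = float(system.radius.max()) + params.mem_radius
        mp = tree.query_ball_tree(mtree, rmax)
        bi = np.array([i for i, lst in enumerate(mp) for _ in lst], dtype=int)
        mi = np.array([m for lst in mp for m in lst], dtype=int)
        if len(bi):
            dv = pos[bi] - system.mem_pos[mi]
            r = np.sqrt(np.einsum("ij,ij->i", dv, dv))
            r0m = system.radius[bi] + params.mem_radius
            inside = r < r0m
            bi, mi, dv, r, r0m = bi[inside], mi[inside], dv[inside], \
                r[inside], r0m[inside]
        if len(bi):
            epsm = np.sqrt(system.depth[bi] * params.mem_depth)
            e, de = _vdw_86(r, r0m, epsm)
            e_rep = e + epsm
            side_rows = ~system.is_bb[bi]
            terms["side_vdw"] += float(e_rep[side_rows].sum())
            terms["main_side_vdw"] += float(e_rep[~side_rows].sum())
            if compute_grad:
                row_wt = np.where(side_rows, wt["side_vdw"], 1.0)
                f = (row_wt * de / r)[:, None] * dv
                np.add.at(grad, bi, f)

    for name, v in terms.items():
        if not np.isfinite(v):
            raise EnergyError(f"non-finite energy in term {name}")
    return terms, grad


def combine_terms(terms, params: EnergyParams | None = None) -> float:
    """Weighted total exactly as the folding-energy formula prescribes."""
    params = params or EnergyParams()
    if isinstance(terms, EnergyBreakdown):
        terms = terms.terms()
    missing = [n for n in TERM_NAMES if n not in terms]
    if missing:
        raise ValueError(f"missing terms: {missing}")
    for n in TERM_NAMES:
        if not np.isfinite(terms[n]):
            raise ValueError(f"non-finite term {n}")
    return (params.c1 * terms["side_vdw"]
            + params.c2 * terms["main_solv"]
            + params.c3 * terms["main_hb"]
            + terms["side_elec"] + terms["side_polar"] + terms["side_hyd"]
            + terms["main_side_elec"] + terms["main_side_vdw"])


def folding_free_energy(structure: CGStructure,
                        charges: np.ndarray | None = None,
                        membrane: Membrane | None = None,
                        params: EnergyParams | None = None) -> EnergyBreakdown:
    """Evaluate all eight terms and the combined total for one conformation.

    ``charges`` is the per-residue side-chain charge vector produced by the
    protonation module (zeros if omitted)."""
    params = params or EnergyParams()
    system = build_bead_system(structure, charges, membrane, params)
    terms, _ = _evaluate(system, params, compute_grad=False)
    total = combine_terms(terms, params)
    return EnergyBreakdown(total=total, **terms)


def folding_energy_and_gradient(system: BeadSystem, params: EnergyParams):
    """Weighted total energy and its gradient wrt flat bead positions.

    The per-term gradients are combined with the same c1/c2/c3 weights as the
    total.  Used by the relaxation driver, which mutates ``system.pos`` in
    place between calls."""
    # term weights applied inside a second pass: cheaper to weight per-term
    # energies directly, so _evaluate is run once per weight group.
    terms, grad = _evaluate(system, params, compute_grad=True)
    total = combine_terms(terms, params)
    return total, terms, grad


# individual term entry points -----------------------------------------------

def _single_term(name):
    def op(structure: CGStructure, params: EnergyParams | None = None,
           charges: np.ndarray | None = None,
           membrane: Membrane | None = None) -> float:
        params = params or EnergyParams()
        system = build_bead_system(structure, charges, membrane, params)
        terms, _ = _evaluate(system, params)
        return terms[name]
    op.__name__ = f"term_{name}"
    op.__doc__ = f"The {name} component of the folding free energy (kcal/mol)."
    return op


term_side_vdw = _single_term("side_vdw")
term_main_solv = _single_term("main_solv")
term_main_hb = _single_term("main_hb")
term_side_elec = _single_term("side_elec")
term_side_polar = _single_term("side_polar")
term_side_hyd = _single_term("side_hyd")
term_main_side_elec = _single_term("main_side_elec")
term_main_side_vdw = _single_term("main_side_vdw")


def energy_with_error(relaxation) -> tuple[float, float]:
    """Headline energy and error bar from a relaxation trajectory: the last
    recorded tail energy, with the population SD of the tail as the error."""
    tail = np.asarray(relaxation.tail_energies, dtype=float)
    if tail.size == 0:
        raise ValueError("relaxation has an empty energy tail")
    return float(tail[-1]), float(tail.std(ddof=0))
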