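"""Synthetic transmembrane helical bundles, activation pairs, dimers,
pockets and ligands.

The generators emulate the geometric and statistical structure of the real
systems the analysis targets: a seven-helix bundle crossing a membrane slab,
an activation motion in which the cytoplasmic half of one helix (the TM6
analogue) swings outward about a hinge, an obligate dimer whose subunits
rotate so that the contact interface migrates from one helix to another, and
a small polar ligand seated in a pocket whose contacts tighten as the
receptor activates.  Residue placement follows membrane-protein logic:
hydrophobic side chains face the lipid, polar side chains line the lumen,
and ionizable residues ring the slab interfaces (basic at the cytoplasmic
end, acidic at the extracellular end), so the proton-transfer and
electrostatic machinery has realistic work to do.

Everything is deterministic per seed, and every generator output is a valid
input for the downstream modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .cg_model import AtomRecord, CGStructure, AA1_TO_3, coarse_grain
from .binding import Ligand, Pose

__all__ = [
    "BundleSpec", "ActivationSpec", "InterfaceSpec", "LigandSpec",
    "make_bundle", "make_activation_pair", "make_activation_series",
    "make_dimer", "make_dimer_frames", "make_pocket_and_ligand",
    "make_gprotein_surrogate",
]

HELIX_RISE = 1.5          # A per residue
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # A, C-alpha circle
SIDE_OFFSET = 1.8         # A, side pseudo-atom beyond the C-alpha circle


@dataclass
class BundleSpec:
    n_helices: int = 7
    helix_length: int = 24
    radius: float = 11.5            # bundle placement circle, A
    sequence_scheme: str = "membrane"
    seed: int = 0
    interface_band: tuple = (11.0, 18.5)  # |z| range of the ionizable rings
    # helix whose cytoplasmic ionizable ring is acidic instead of basic.
    # Putting it on the swing helix forms ionic-lock salt bridges with the
    # neighbouring basic rings that must break during activation; None
    # disables the motif
    lock_acid_helix: int | None = 5
    # fraction of interface-band outward positions that actually carry an
    # ionizable residue; thinning keeps ring charges from crowding each
    # other into titration flips
    ionizable_fraction: float = 0.6

    def __post_init__(self):
        if self.n_helices < 2:
            raise ValueError("need at least 2 helices")
        if self.helix_length < 8:
            raise ValueError("helix_length must be >= 8")
        min_radius = 7.0 / (2 * np.sin(np.pi / self.n_helices)) if \
            self.n_helices > 2 else 4.0
        if self.radius < min_radius:
            raise ValueError(
                f"radius {self.radius} too small to pack {self.n_helices} "
                f"helices (need >= {min_radius:.1f} A)")


@dataclass
class ActivationSpec:
    swing_helix: int = 5            # the TM6 analogue (0-based helix index)
    swing_distance: float = 14.0    # cytoplasmic-end C-alpha displacement, A
    kink_fraction: float = 0.5      # hinge position along the helix
    swing_angle: float | None = None  # derived from distance when None

    def __post_init__(self):
        if self.swing_distance < 0:
            raise ValueError("swing_distance must be >= 0")


@dataclass
class InterfaceSpec:
    """Dimer interface: which helix faces the partner in each state."""

    inactive_helix: int = 2        # "helix III"
    active_helix: int = 5          # "helix VI"
    gap: float = 4.5               # A between facing side beads
    patch_types: dict = field(default_factory=lambda: {2: "L", 4: "W", 5: "L"})
    patch_rows: dict = field(default_factory=lambda: {2: 2, 4: 4, 5: 2})


@dataclass
class LigandSpec:
    name: str = "agonist"
    net_charge: float = 1.0
    n_atoms: int = 4


# --- helix geometry ----------------------------------------------------------

def _helix_coords(length: int, up: bool) -> tuple[np.ndarray, np.ndarray]:
    """Ideal alpha-helix C-alpha and side pseudo-atom coordinates in the
    helix frame (axis = z, centred on z = 0)."""
    i = np.arange(length)
    theta = np.deg2rad(HELIX_TWIST * i)
    z = (i - (length - 1) / 2) * HELIX_RISE
    if not up:
        z = -z
    ca = np.column_stack([HELIX_RADIUS * np.cos(theta),
                          HELIX_RADIUS * np.sin(theta), z])
    sc = np.column_stack([(HELIX_RADIUS + SIDE_OFFSET) * np.cos(theta),
                          (HELIX_RADIUS + SIDE_OFFSET) * np.sin(theta), z])
    return ca, sc


def helix_angle(spec: BundleSpec, h: int) -> float:
    return 2 * np.pi * h / spec.n_helices


def _assign_sequence(spec: BundleSpec, ca: np.ndarray, sc: np.ndarray,
                     helix_of: np.ndarray, rng) -> list[str]:
    """Membrane-logic residue types from geometry."""
    types = []
    lo, hi = spec.interface_band
    for k in range(len(ca)):
        h = helix_of[k]
        centre = spec.radius * np.array([np.cos(helix_angle(spec, h)),
                                         np.sin(helix_angle(spec, h)), 0.0])
        outward = (sc[k] - ca[k])[:2] @ centre[:2] > 0
        z = ca[k, 2]
        if lo <= abs(z) <= hi and outward and \
                rng.random() < spec.ionizable_fraction:
            if z < 0:   # cytoplasmic: basic ring (positive-inside rule)
                if spec.lock_acid_helix is not None and h == spec.lock_acid_helix:
                    types.append(rng.choice(["E", "D"], p=[0.7, 0.3]))
                else:
                    types.append(rng.choice(["K", "R"], p=[0.7, 0.3]))
            else:       # extracellular: acidic ring
                types.append(rng.choice(["D", "E"], p=[0.5, 0.5]))
        elif outward:
            types.append(rng.choice(["L", "I", "V", "F", "A"],
                                    p=[0.35, 0.2, 0.2, 0.15, 0.1]))
        else:
            types.append(rng.choice(["S", "T", "N", "G"],
                                    p=[0.4, 0.3, 0.2, 0.1]))
    return types


def make_bundle(spec: BundleSpec) -> list[AtomRecord]:
    """Ideal helical bundle on a circle, axes along z, as pseudo-atoms
    (CA + one side-chain particle named CB).  Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    ca_all, sc_all, helix_of = [], [], []
    for h in range(spec.n_helices):
        up = h % 2 == 0   # antiparallel bundle
        ca, sc = _helix_coords(spec.helix_length, up)
        ang = helix_angle(spec, h)
        centre = spec.radius * np.array([np.cos(ang), np.sin(ang), 0.0])
        # rotate the helix about its own axis so side chains vary in facing
        phase = Rotation.from_euler("z", np.rad2deg(ang) + 40.0 * h,
                                    degrees=True).as_matrix()
        ca_all.append(ca @ phase.T + centre)
        sc_all.append(sc @ phase.T + centre)
        helix_of.extend([h] * spec.helix_length)
    ca_all = np.vstack(ca_all)
    sc_all = np.vstack(sc_all)
    helix_of = np.array(helix_of)
    types = _assign_sequence(spec, ca_all, sc_all, helix_of, rng)

    atoms = []
    for k in range(len(ca_all)):
        name3 = AA1_TO_3[types[k]]
        atoms.append(AtomRecord("A", k + 1, name3, "CA", ca_all[k]))
        if types[k] != "G":
            atoms.append(AtomRecord("A", k + 1, name3, "CB", sc_all[k]))
    return atoms


def helix_residue_numbers(spec: BundleSpec, h: int) -> np.ndarray:
    """PDB residue numbers belonging to helix ``h`` of a generated bundle."""
    start = h * spec.helix_length + 1
    return np.arange(start, start + spec.helix_length)


# --- activation swing --------------------------------------------------------

def _swing_atoms(atoms: list[AtomRecord], spec: BundleSpec,
                 act: ActivationSpec, fraction: float) -> list[AtomRecord]:
    """Rotate the cytoplasmic half of the swing helix about its hinge by
    ``fraction`` of the full activation angle."""
    if act.swing_distance == 0 or fraction == 0:
        return [AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                           a.atom_name, a.position.copy(), a.icode, a.hetero)
                for a in atoms]
    resnums = set(helix_residue_numbers(spec, act.swing_helix).tolist())
    helix_ca = {a.residue_number: a.position for a in atoms
                if a.residue_number in resnums and a.atom_name == "CA"}
    nums = sorted(helix_ca, key=lambda n: helix_ca[n][2])  # by z
    # hinge at kink_fraction along the helix (z-ordered)
    hinge_num = nums[int(round(act.kink_fraction * (len(nums) - 1)))]
    hinge = helix_ca[hinge_num]
    # cytoplasmic = low-z side
    moving = {n for n in nums if helix_ca[n][2] < hinge[2]}
    terminal = helix_ca[nums[0]]
    arm = float(np.linalg.norm(terminal - hinge))
    if act.swing_angle is not None:
        full_angle = np.deg2rad(act.swing_angle)
    else:
        if act.swing_distance > 2 * arm:
            raise ValueError("swing_distance exceeds twice the lever arm; "
                             "use a longer helix or smaller swing")
        full_angle = 2 * np.arcsin(act.swing_distance / (2 * arm))
    ang = helix_angle(spec, act.swing_helix)
    radial = np.array([np.cos(ang), np.sin(ang), 0.0])
    axis = np.cross([0.0, 0.0, 1.0], radial)  # tangent: swings the end outward
    rot = Rotation.from_rotvec(axis * full_angle * fraction).as_matrix()
    # pick the rotation sign that moves the terminal outward
    new_term = rot @ (terminal - hinge) + hinge
    if np.linalg.norm(new_term[:2]) < np.linalg.norm(terminal[:2]):
        rot = Rotation.from_rotvec(-axis * full_angle * fraction).as_matrix()

    out = []
    for a in atoms:
        pos = a.position
        if a.residue_number in moving:
            pos = rot @ (pos - hinge) + hinge
        out.append(AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                              a.atom_name, pos.copy(), a.icode, a.hetero))
    return out


def make_activation_pair(spec: BundleSpec, act: ActivationSpec
                         ) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Inactive and active bundle conformations differing by the rigid
    outward swing of the chosen helix's cytoplasmic half.  The terminal
    C-alpha moves by exactly ``act.swing_distance`` and sequences are
    identical by construction."""
    inactive = make_bundle(spec)
    active = _swing_atoms(inactive, spec, act, 1.0)
    return inactive, active


def make_activation_series(spec: BundleSpec, act: ActivationSpec,
                           fractions) -> list[list[AtomRecord]]:
    """Conformational states at the given fractions of the full swing angle
    (e.g. [0, 0.5, 1] for inactive / intermediate / active)."""
    base = make_bundle(spec)
    return [_swing_atoms(base, spec, act, f) for f in fractions]


# --- dimers ------------------------------------------------------------------

def _apply_patches(structure: CGStructure, spec: BundleSpec,
                   iface: InterfaceSpec) -> CGStructure:
    """Type the interface patches: outward mid-membrane residues of the
    interface helices become a hydrophobic contact patch; the mid-path helix
    gets the largest patch so the landscape develops a stable intermediate."""
    from .cg_model import mutate_residue
    out = structure
    for h, t in iface.patch_types.items():
        nums = helix_residue_numbers(spec, h)
        mid = []
        for n in nums:
            i = out.residue_id("A", int(n))
            z = out.bb_pos[i, 2]
            if abs(z) > 9.0 or not out.has_sc[i]:
                continue
            centre_ang = helix_angle(spec, h)
            centre = spec.radius * np.array([np.cos(centre_ang),
                                             np.sin(centre_ang), 0.0])
            if (out.sc_pos[i] - out.bb_pos[i])[:2] @ centre[:2] > 0:
                mid.append((abs(z), int(n)))
        mid.sort()
        for _, n in mid[:iface.patch_rows.get(h, 2)]:
            out = mutate_residue(out, "A", n, t)
    return out


def _orient_for_interface(structure: CGStructure, spec: BundleSpec,
                          facing_helix: float) -> CGStructure:
    """Rotate the monomer about z so (possibly fractional) helix index
    ``facing_helix`` points along +x."""
    ang = 2 * np.pi * facing_helix / spec.n_helices
    rot = Rotation.from_euler("z", -np.rad2deg(ang), degrees=True).as_matrix()
    return structure.transformed(rotation=rot)


def _c2_image(structure: CGStructure, new_chain: str) -> CGStructure:
    """180-degree rotation about the z axis through the origin."""
    rot = np.diag([-1.0, -1.0, 1.0])
    out = structure.transformed(rotation=rot)
    out.chain = np.full_like(out.chain, new_chain)
    return out


def _auto_separation(monomer: CGStructure, gap: float) -> float:
    pts = np.vstack([monomer.bb_pos, monomer.sc_pos[monomer.has_sc]])
    return 2 * float(pts[:, 0].max()) + gap


def _place_dimer(monomer: CGStructure, separation: float
                 ) -> tuple[CGStructure, CGStructure]:
    left = monomer.transformed(translation=np.array([-separation / 2, 0, 0]))
    left.chain = np.full_like(left.chain, "L")
    right = _c2_image(left, "R")
    return left, right


def make_dimer(monomer_cg: CGStructure, spec: BundleSpec,
               iface: InterfaceSpec | None = None
               ) -> tuple[CGStructure, CGStructure]:
    """Inactive and active dimers of one monomer: two copies side by side
    with exact C2 symmetry, contacting through ``inactive_helix`` in the
    inactive state and through ``active_helix`` in the active state
    (the subunits rotate about their own axes between the two)."""
    iface = iface or InterfaceSpec()
    if iface.inactive_helix == iface.active_helix:
        raise ValueError("inactive and active interface helices must differ")
    mono = _apply_patches(monomer_cg, spec, iface)
    # one separation for every orientation so no facing state overlaps
    sep = max(
        _auto_separation(_orient_for_interface(mono, spec, h), iface.gap)
        for h in (iface.inactive_helix, iface.active_helix))
    dimers = []
    for h in (iface.inactive_helix, iface.active_helix):
        oriented = _orient_for_interface(mono, spec, h)
        left, right = _place_dimer(oriented, sep)
        dimers.append(CGStructure.concatenate([left, right]))
    return dimers[0], dimers[1]


def make_dimer_frames(monomer_frames: list[CGStructure], spec: BundleSpec,
                      iface: InterfaceSpec | None = None
                      ) -> tuple[list[CGStructure], list[CGStructure], float]:
    """Per-subunit conformation series for the dimer grid.

    Frame k of the L subunit is monomer frame k (internal conformation)
    rotated about its own axis so the facing helix interpolates from the
    inactive to the active interface, then placed at the L position; R
    frames are exact C2 images, so the apo grid is symmetric by
    construction.  Returns (L_frames, R_frames, separation)."""
    iface = iface or InterfaceSpec()
    k = len(monomer_frames)
    if k < 2:
        raise ValueError("need at least 2 monomer frames")
    patched = [_apply_patches(m, spec, iface) for m in monomer_frames]
    oriented_frames = []
    for i, mono in enumerate(patched):
        f = i / (k - 1)
        facing = iface.inactive_helix + f * (iface.active_helix
                                             - iface.inactive_helix)
        oriented_frames.append(_orient_for_interface(mono, spec, facing))
    # one separation for the whole grid: sized to the widest orientation so
    # no (i, j) cell overlaps, while facing patches stay near contact
    sep = max(_auto_separation(o, iface.gap) for o in oriented_frames)
    lframes, rframes = [], []
    for oriented in oriented_frames:
        left, right = _place_dimer(oriented, sep)
        lframes.append(left)
        rframes.append(right)
    return lframes, rframes, sep


# --- pockets and ligands -----------------------------------------------------

def _author_ligand(spec: LigandSpec, rng) -> Ligand:
    """Small polar ligand: 3-6 particles, authored charges summing to the
    requested net charge."""
    n = int(np.clip(spec.n_atoms, 3, 6))
    # compact tetrahedral-ish cluster, 1.4 A bonds
    base = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [0.5, 1.3, 0.0],
                     [0.5, 0.45, 1.3], [-0.9, 0.9, 0.4], [1.9, 1.2, 0.6]])[:n]
    q = np.zeros(n)
    # one dominant charged centre plus alternating partial charges
    q[0] = 0.8 * np.sign(spec.net_charge) if spec.net_charge else 0.3
    q[1] = -0.2 if spec.net_charge >= 0 else 0.2
    q[2:] = 0.1 * (-1.0) ** np.arange(n - 2)
    q += (spec.net_charge - q.sum()) / n
    radii = np.full(n, 1.7)
    depths = np.full(n, 0.15)
    names = [f"X{i+1}" for i in range(n)]
    return Ligand(spec.name, names, base, q, radii, depths)


def make_pocket_and_ligand(structure: CGStructure,
                           pocket_residues: list,
                           ligand_spec: LigandSpec | None = None,
                           seed: int = 0,
                           centre_override: np.ndarray | None = None,
                           clearance: float = 3.5,
                           check_structures: list | None = None,
                           nudge_direction: np.ndarray | None = None,
                           orient_toward: np.ndarray | None = None
                           ) -> tuple[CGStructure, Pose]:
    """Place a small polar ligand at the centroid of the named pocket
    residues (or ``centre_override``), nudging it away from contacts until
    every ligand particle keeps ``clearance`` angstroms from every receptor
    bead — of this structure and of every structure in ``check_structures``
    (e.g. all frames of a path, so a moving helix never sweeps through the
    pose).  The hard validity floor of 1 A always holds."""
    ligand_spec = ligand_spec or LigandSpec()
    rng = np.random.default_rng(seed)
    for chain, resnum in pocket_residues:
        structure.residue_id(chain, resnum)
    pts = []
    for chain, resnum in pocket_residues:
        i = structure.residue_id(chain, resnum)
        pts.append(structure.sc_pos[i] if structure.has_sc[i]
                   else structure.bb_pos[i])
    centre = np.mean(pts, axis=0) if centre_override is None \
        else np.asarray(centre_override, dtype=float)

    lig = _author_ligand(ligand_spec, rng)
    lig = lig.moved(translation=centre - lig.positions.mean(axis=0))
    if orient_toward is not None:
        # rotate about the centroid so the dominant charged atom (atom 0)
        # faces the given point, e.g. the key binding residue
        want = np.asarray(orient_toward, dtype=float) - centre
        have = lig.positions[0] - centre
        wn, hn = np.linalg.norm(want), np.linalg.norm(have)
        if wn > 1e-9 and hn > 1e-9:
            rot, _ = Rotation.align_vectors((want / wn)[None, :],
                                            (have / hn)[None, :])
            lig = lig.moved(rotation=rot.as_matrix())

    check = [structure] + list(check_structures or [])
    beads = np.vstack([np.vstack([s.bb_pos, s.sc_pos[s.has_sc]])
                       for s in check])
    floor = max(clearance, 1.0)
    fixed_dir = None
    if nudge_direction is not None:
        fixed_dir = np.asarray(nudge_direction, dtype=float)
        fixed_dir = fixed_dir / np.linalg.norm(fixed_dir)
    for _ in range(300):
        d = np.linalg.norm(lig.positions[:, None, :] - beads[None, :, :],
                           axis=-1)
        if d.min() >= floor:
            break
        if fixed_dir is not None:
            away = fixed_dir
        else:
            ai, bi = np.unravel_index(np.argmin(d), d.shape)
            away = lig.positions.mean(axis=0) - beads[bi]
            nrm = np.linalg.norm(away)
            away = away / nrm if nrm > 1e-9 else rng.standard_normal(3)
        lig = lig.moved(translation=0.3 * away)
    else:
        raise ValueError("could not place ligand without clashes")
    return structure, Pose(lig, 0, list(pocket_residues))


# --- G-protein surrogate -----------------------------------------------------

def make_gprotein_surrogate(n_ring: int = 6, radius: float = 3.5,
                            charge_residue: str = "E") -> CGStructure:
    """Compact rigid bead cluster standing in for the G protein.

    A ring of hydrophobic residues plus one acidic residue, centred on the
    origin with side beads pointing up (+z, toward the receptor's
    cytoplasmic cavity when approaching from below)."""
    n = n_ring + 1
    chains = np.full(n, "G")
    resnums = np.arange(1, n + 1)
    icodes = np.full(n, "")
    types = np.array(["L"] * n_ring + [charge_residue])
    theta = 2 * np.pi * np.arange(n_ring) / n_ring
    bb = np.zeros((n, 3))
    bb[:n_ring, 0] = radius * np.cos(theta)
    bb[:n_ring, 1] = radius * np.sin(theta)
    bb[n_ring] = [0.0, 0.0, 1.0]
    sc = bb + np.array([0.0, 0.0, 1.6])
    return CGStructure(chains, resnums, icodes, types, bb, sc,
                       np.ones(n, dtype=bool))
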