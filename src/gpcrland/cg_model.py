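"""Coarse-grained two-bead protein model and PDB ingestion.

Structures are reduced to two interaction sites per residue: a backbone bead
at the C-alpha position and a side-chain bead at the centroid of the
side-chain heavy atoms (glycine has no side-chain bead).  This mapping
preserves the main-chain / side-chain split that the folding energy function
is organised around while keeping systems of hundreds of residues cheap to
evaluate.

All coordinates are in angstroms.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "CGBead",
    "CGStructure",
    "PDBParseError",
    "read_structure",
    "write_pdb",
    "trim_to_common",
    "coarse_grain",
    "mutate_residue",
    "write_cg_table",
    "read_cg_table",
]

# --- residue taxonomy -------------------------------------------------------

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# common modified residues mapped onto the parent standard residue
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "MLY": "LYS", "CSO": "CYS", "HYP": "PRO", "KCX": "LYS", "PCA": "GLU",
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS", "HID": "HIS", "HIE": "HIS",
}

IONIZABLE = frozenset("DEKRH")
HYDROPHOBIC = frozenset("AVLIMFWCPG")
POLAR = frozenset("STNQY")
CHARGED = frozenset("DEKRH")

# side-chain bead van der Waals radii (A), loosely tracking side-chain size
SIDE_RADIUS = {
    "A": 1.8, "C": 2.1, "D": 2.2, "E": 2.5, "F": 2.9, "G": 0.0, "H": 2.6,
    "I": 2.5, "K": 2.7, "L": 2.5, "M": 2.6, "N": 2.3, "P": 2.2, "Q": 2.5,
    "R": 2.9, "S": 1.9, "T": 2.1, "V": 2.3, "W": 3.2, "Y": 2.9,
}
SIDE_DEPTH_HYDROPHOBIC = 0.20  # kcal/mol
SIDE_DEPTH_OTHER = 0.15
BACKBONE_RADIUS = 2.3
BACKBONE_DEPTH = 0.15

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def hydrophobicity_class(restype: str) -> str:
    if restype in CHARGED:
        return "charged"
    if restype in POLAR:
        return "polar"
    return "hydrophobic"


def side_chain_depth(restype: str) -> float:
    return SIDE_DEPTH_HYDROPHOBIC if restype in HYDROPHOBIC else SIDE_DEPTH_OTHER


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record (first model, resolved altlocs)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray  # (3,) A
    icode: str = ""
    hetero: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"bad position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)

    @property
    def residue_key(self):
        return (self.chain_id, self.residue_number, self.icode)

    @property
    def standard(self) -> bool:
        return self.residue_name in AA3_TO_1


@dataclass(frozen=True)
class CGBead:
    """One coarse-grained interaction site."""

    role: str  # "backbone" | "side-chain"
    position: np.ndarray
    residue_index: int
    residue_type: str
    ionizable: bool
    vdw_radius: float
    hydrophobicity_class: str


@dataclass
class CGStructure:
    """Two-bead-per-residue coarse-grained structure.

    Residue-major arrays; ``sc_pos`` rows are NaN where ``has_sc`` is False
    (glycine).  All conformational states of one system must share the same
    residue layout, which :func:`trim_to_common` enforces upstream.
    """

    chain: np.ndarray       # (R,) unicode chain ids
    resnum: np.ndarray      # (R,) int PDB residue numbers
    icode: np.ndarray       # (R,) unicode insertion codes
    restype: np.ndarray     # (R,) unicode 1-letter codes
    bb_pos: np.ndarray      # (R, 3)
    sc_pos: np.ndarray      # (R, 3), NaN for glycine
    has_sc: np.ndarray = field(default=None)  # (R,) bool

    def __post_init__(self):
        self.chain = np.asarray(self.chain)
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.icode = np.asarray(self.icode)
        self.restype = np.asarray(self.restype)
        self.bb_pos = np.asarray(self.bb_pos, dtype=float).reshape(-1, 3)
        self.sc_pos = np.asarray(self.sc_pos, dtype=float).reshape(-1, 3)
        if self.has_sc is None:
            self.has_sc = self.restype != "G"
        self.has_sc = np.asarray(self.has_sc, dtype=bool)
        n = len(self.resnum)
        for name in ("chain", "icode", "restype", "has_sc"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} length mismatch")
        if self.bb_pos.shape != (n, 3) or self.sc_pos.shape != (n, 3):
            raise ValueError("coordinate array shape mismatch")

    # -- basic queries ------------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.resnum)

    @property
    def n_beads(self) -> int:
        return self.n_residues + int(self.has_sc.sum())

    @property
    def ionizable(self) -> np.ndarray:
        return np.isin(self.restype, list(IONIZABLE))

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for c in self.chain:
            if c not in seen:
                seen.append(str(c))
        return seen

    def sequence(self, chain: str | None = None) -> str:
        if chain is None:
            return "".join(self.restype)
        return "".join(self.restype[self.chain == chain])

    def residue_id(self, chain: str, resnum: int, icode: str = "") -> int:
        hits = np.where(
            (self.chain == chain) & (self.resnum == resnum) & (self.icode == icode)
        )[0]
        if len(hits) == 0:
            raise KeyError(f"residue {chain}{resnum}{icode} not found")
        return int(hits[0])

    def copy(self) -> "CGStructure":
        return CGStructure(
            self.chain.copy(), self.resnum.copy(), self.icode.copy(),
            self.restype.copy(), self.bb_pos.copy(), self.sc_pos.copy(),
            self.has_sc.copy(),
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "CGStructure":
        out = self.copy()
        if rotation is not None:
            out.bb_pos = out.bb_pos @ rotation.T
            out.sc_pos = out.sc_pos @ rotation.T
        if translation is not None:
            out.bb_pos = out.bb_pos + translation
            out.sc_pos = out.sc_pos + translation
        return out

    @property
    def beads(self) -> list[CGBead]:
        """Bead list in chain-then-residue order, backbone before side chain."""
        out = []
        for i in range(self.n_residues):
            t = str(self.restype[i])
            out.append(CGBead("backbone", self.bb_pos[i].copy(), i, t,
                              False, BACKBONE_RADIUS, hydrophobicity_class(t)))
            if self.has_sc[i]:
                out.append(CGBead("side-chain", self.sc_pos[i].copy(), i, t,
                                  t in IONIZABLE, SIDE_RADIUS[t],
                                  hydrophobicity_class(t)))
        return out

    def side_radii(self) -> np.ndarray:
        return np.array([SIDE_RADIUS[t] for t in self.restype])

    def side_depths(self) -> np.ndarray:
        return np.array([side_chain_depth(t) for t in self.restype])

    @staticmethod
    def concatenate(parts: list["CGStructure"]) -> "CGStructure":
        return CGStructure(
            np.concatenate([p.chain for p in parts]),
            np.concatenate([p.resnum for p in parts]),
            np.concatenate([p.icode for p in parts]),
            np.concatenate([p.restype for p in parts]),
            np.vstack([p.bb_pos for p in parts]),
            np.vstack([p.sc_pos for p in parts]),
            np.concatenate([p.has_sc for p in parts]),
        )


# --- PDB input --------------------------------------------------------------

def _prescan_pdb(pdb_text: str) -> None:
    """Line-level validation so coordinate errors carry a line number."""
    n_atoms = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            n_atoms += 1
            if len(line) < 54:
                raise PDBParseError(f"line {lineno}: truncated {rec} record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi]
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed {what} coordinate {fieldtxt!r}"
                    ) from None
    if n_atoms == 0:
        raise PDBParseError("no ATOM/HETATM records found (empty structure)")


def read_structure(pdb_text: str) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Parse PDB text into protein atoms and ligand HETATM atoms.

    Only the first MODEL is read; alternate locations are resolved to the
    highest-occupancy (then first-encountered) conformer; waters are dropped.
    Returns ``(atoms, het_atoms)``.
    """
    _prescan_pdb(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - prescan catches most
        raise PDBParseError(f"PDB parse failure: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("no models in structure")
    model = st[0]

    atoms: list[AtomRecord] = []
    het: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if res.name in WATER_NAMES:
                continue
            # altloc resolution: per atom name keep highest occupancy, first wins ties
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or (atom.occ or 0.0) > (prev.occ or 0.0):
                    best[atom.name] = atom
            is_het = res.het_flag == "H" and res.name not in AA3_TO_1 \
                and res.name not in NONSTANDARD_PARENT
            for name, atom in best.items():
                if atom.element.is_hydrogen:
                    continue
                rec = AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    atom_name=name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    icode=(res.seqid.icode or "").strip(),
                    hetero=is_het,
                )
                (het if is_het else atoms).append(rec)
    if not atoms and not het:
        raise PDBParseError("structure contains no usable atoms")
    return atoms, het


def write_pdb(atoms: list[AtomRecord]) -> str:
    """Serialise atom records back to PDB text (single model)."""
    lines = []
    for i, a in enumerate(atoms, start=1):
        rec = "HETATM" if a.hetero else "ATOM"
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"{rec:<6s}{i:>5d} {name:<4s}{a.residue_name:>4s} {a.chain_id[:1]:1s}"
            f"{a.residue_number:>4d}{a.icode[:1]:1s}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- trimming to a common residue set --------------------------------------

def trim_to_common(states: list[list[AtomRecord]]) -> list[list[AtomRecord]]:
    """Restrict every conformational state to the shared residue set.

    The matching key is ``(chain, residue number, insertion code)``; residues
    missing from any state are removed from all, so every returned state
    carries the identical ordered residue list.
    """
    if len(states) < 2:
        raise ValueError("need at least two states to trim")
    keys_per_state = []
    name_per_key: dict[tuple, str] = {}
    for si, atoms in enumerate(states):
        keys = {}
        for a in atoms:
            keys.setdefault(a.residue_key, a.residue_name)
        for k, nm in keys.items():
            prev = name_per_key.setdefault(k, nm)
            if prev != nm:
                raise ValueError(
                    f"residue name conflict at {k}: {prev} vs {nm} "
                    "(states are not the same protein)"
                )
        keys_per_state.append(set(keys))
    common = set.intersection(*keys_per_state)
    if not common:
        raise ValueError("states share no residues")
    return [[a for a in atoms if a.residue_key in common] for atoms in states]


# --- coarse graining --------------------------------------------------------

def coarse_grain(atoms: list[AtomRecord]) -> CGStructure:
    """Map all-atom records onto the two-bead representation.

    Backbone bead at C-alpha, side-chain bead at the arithmetic centroid of
    the side-chain heavy atoms.  Nonstandard residues with a known parent are
    remapped; unknown residues are dropped with a warning.
    """
    groups: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    for a in atoms:
        if a.residue_key not in groups:
            groups[a.residue_key] = []
            order.append(a.residue_key)
        groups[a.residue_key].append(a)
    # chain then residue-number order
    order.sort(key=lambda k: (k[0], k[1], k[2]))

    chains, resnums, icodes, types = [], [], [], []
    bb, sc, has = [], [], []
    for key in order:
        res_atoms = groups[key]
        name = res_atoms[0].residue_name
        if name not in AA3_TO_1:
            parent = NONSTANDARD_PARENT.get(name)
            if parent is None:
                logger.warning("dropping unknown residue %s at %s", name, key)
                continue
            name = parent
        t = AA3_TO_1[name]
        ca = next((a for a in res_atoms if a.atom_name == "CA"), None)
        if ca is None:
            raise ValueError(f"missing CA for residue {key[0]}{key[1]}{key[2]}")
        side = [a.position for a in res_atoms
                if a.atom_name not in BACKBONE_ATOMS
                and not a.atom_name.startswith("H")]
        chains.append(key[0]); resnums.append(key[1]); icodes.append(key[2])
        types.append(t); bb.append(ca.position)
        if t == "G" or not side:
            if t != "G" and not side:
                logger.warning("residue %s has no side-chain atoms; bead placed "
                               "1.5 A off backbone", key)
                # degenerate input: synthesise a stub so the bead count invariant holds
                sc.append(ca.position + np.array([1.5, 0.0, 0.0]))
                has.append(True)
            else:
                sc.append(np.full(3, np.nan)); has.append(False)
        else:
            sc.append(np.mean(side, axis=0)); has.append(True)
    if not chains:
        raise ValueError("no standard residues to coarse-grain")
    return CGStructure(np.array(chains), np.array(resnums), np.array(icodes),
                       np.array(types), np.array(bb), np.array(sc),
                       np.array(has))


def mutate_residue(structure: CGStructure, chain: str, residue_number: int,
                   new_type: str, icode: str = "") -> CGStructure:
    """Point mutation: swap the residue type and its derived bead properties.

    The side-chain bead keeps its position (dropped for a mutation to glycine;
    synthesised 2.4 A off the backbone, away from the structure centroid, when
    mutating glycine to a side-chain-bearing type).
    """
    if new_type not in AA1_TO_3:
        raise ValueError(f"unknown residue type {new_type!r}")
    out = structure.copy()
    i = out.residue_id(chain, residue_number, icode)
    out.restype[i] = new_type
    if new_type == "G":
        out.has_sc[i] = False
        out.sc_pos[i] = np.nan
    elif not out.has_sc[i]:
        centroid = out.bb_pos.mean(axis=0)
        direction = out.bb_pos[i] - centroid
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        out.sc_pos[i] = out.bb_pos[i] + 2.4 * direction
        out.has_sc[i] = True
    return out


# --- tabular CG text format -------------------------------------------------

CG_COLUMNS = ["chain", "resnum", "icode", "role", "restype", "x", "y", "z"]


def write_cg_table(structure: CGStructure) -> str:
    """One bead per row, tab separated: chain, residue, role, type, x, y, z."""
    rows = []
    for i in range(structure.n_residues):
        rows.append((structure.chain[i], structure.resnum[i], structure.icode[i],
                     "backbone", structure.restype[i], *structure.bb_pos[i]))
        if structure.has_sc[i]:
            rows.append((structure.chain[i], structure.resnum[i],
                         structure.icode[i], "side-chain", structure.restype[i],
                         *structure.sc_pos[i]))
    df = pd.DataFrame(rows, columns=CG_COLUMNS)
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.6f")
    return buf.getvalue()


def read_cg_table(text: str) -> CGStructure:
    df = pd.read_csv(io.StringIO(text), sep="\t",
                     dtype={"chain": str, "icode": str}, keep_default_na=False)
    bb = df[df.role == "backbone"].reset_index(drop=True)
    sc = df[df.role == "side-chain"].set_index(["chain", "resnum", "icode"])
    chains = bb.chain.to_numpy(dtype=str)
    resnums = bb.resnum.to_numpy(dtype=int)
    icodes = bb.icode.to_numpy(dtype=str)
    types = bb.restype.to_numpy(dtype=str)
    bb_pos = bb[["x", "y", "z"]].to_numpy(dtype=float)
    sc_pos = np.full((len(bb), 3), np.nan)
    has = np.zeros(len(bb), dtype=bool)
    for i in range(len(bb)):
        key = (chains[i], resnums[i], icodes[i])
        if key in sc.index:
            sc_pos[i] = sc.loc[key, ["x", "y", "z"]].to_numpy(dtype=float)
            has[i] = True
    return CGStructure(chains, resnums, np.array(icodes), types, bb_pos,
                       sc_pos, has)


def structure_to_atoms(structure: CGStructure) -> list[AtomRecord]:
    """Pseudo-atom view (CA + CB) of a CG structure, for PDB export."""
    out = []
    for i in range(structure.n_residues):
        name3 = AA1_TO_3[str(structure.restype[i])]
        out.append(AtomRecord(str(structure.chain[i]), int(structure.resnum[i]),
                              name3, "CA", structure.bb_pos[i],
                              str(structure.icode[i])))
        if structure.has_sc[i]:
            out.append(AtomRecord(str(structure.chain[i]),
                                  int(structure.resnum[i]), name3, "CB",
                                  structure.sc_pos[i], str(structure.icode[i])))
    return out
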