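"""Charge-state assignment by Monte Carlo proton transfer (MCPT).

Before every folding-energy evaluation the ionizable residues (D, E, K, R, H)
are assigned charge states for the given conformation.  An initial titration
pre-step ionizes each site independently whenever that lowers its intrinsic
energy at the working pH, fixing the total proton count; protons then "jump"
between ionizable residues under a standard Metropolis criterion, conserving
the proton count, and the lowest-energy state visited is returned.

The state energy is

    E = sum_ionized 2.303 kT (pKa - pH) * gamma   (gamma = +1 acids, -1 bases)
        + sum_pairs 332 q_i q_j / (eps(r) r)

with the same distance-dependent screening (and membrane scaling) as the
folding energy, so proton placement and folding electrostatics are mutually
consistent.  The intrinsic term makes ionization favourable for acids above
their pKa and for bases below it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import io
import numpy as np
import pandas as pd

from .cg_model import CGStructure
from .energetics import (
    EnergyParams, Membrane, COULOMB_K, KB, ENV_MEMBRANE, _cutoff_switch,
)

__all__ = [
    "ProtonationState", "MCPTParams", "metropolis_accept_probability",
    "site_energy", "run_mcpt", "run_mcpt_detailed", "greedy_proton_descent",
    "write_protonation_table", "read_protonation_table",
]

DEFAULT_PKA = {"D": 3.9, "E": 4.1, "H": 6.5, "K": 10.5, "R": 12.5}
ACIDS = frozenset("DE")
BASES = frozenset("KRH")


@dataclass
class MCPTParams:
    temperature: float = 300.0      # K
    n_steps: int | None = None      # default 50 x number of sites
    seed: int = 0
    model_pka: dict = field(default_factory=lambda: dict(DEFAULT_PKA))
    ph: float = 7.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_steps is not None and self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class ProtonationState:
    """Charges over the ionizable sites of one structure.

    ``site_residues`` are residue indices into the parent structure;
    ``ionized`` marks which sites carry their charged form; ``charges`` is the
    per-site charge in e (D/E: 0 or -1; K/R/H: 0 or +1)."""

    site_residues: np.ndarray
    site_types: np.ndarray
    ionized: np.ndarray

    def __post_init__(self):
        self.site_residues = np.asarray(self.site_residues, dtype=int)
        self.site_types = np.asarray(self.site_types)
        self.ionized = np.asarray(self.ionized, dtype=bool)

    @property
    def charges(self) -> np.ndarray:
        sign = np.where(np.isin(self.site_types, list(ACIDS)), -1.0, 1.0)
        return sign * self.ionized

    @property
    def n_protons(self) -> int:
        acid = np.isin(self.site_types, list(ACIDS))
        return int(np.sum(acid & ~self.ionized) + np.sum(~acid & self.ionized))

    def per_residue_charges(self, structure: CGStructure) -> np.ndarray:
        out = np.zeros(structure.n_residues)
        out[self.site_residues] = self.charges
        return out

    def copy(self) -> "ProtonationState":
        return ProtonationState(self.site_residues.copy(),
                                self.site_types.copy(), self.ionized.copy())


def metropolis_accept_probability(delta_e: float, temperature: float) -> float:
    """min(1, exp(-dE/kT)) with k_B = 0.0019872 kcal/mol/K."""
    if not np.isfinite(delta_e):
        raise ValueError("non-finite energy difference")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return 1.0
    return float(np.exp(-delta_e / (KB * temperature)))


# --- site-energy machinery --------------------------------------------------

def _site_arrays(structure: CGStructure, params: MCPTParams):
    sites = np.where(structure.ionizable & structure.has_sc)[0]
    types = structure.restype[sites]
    for t in set(types.tolist()):
        if t not in params.model_pka:
            raise ValueError(f"no model pKa for residue type {t}")
    pka = np.array([params.model_pka[t] for t in types])
    gamma = np.where(np.isin(types, list(ACIDS)), 1.0, -1.0)
    intrinsic = 2.303 * KB * params.temperature * gamma * (pka - params.ph)
    sign = np.where(gamma > 0, -1.0, 1.0)  # charge when ionized
    return sites, types, intrinsic, sign


def _pair_matrix(structure: CGStructure, sites: np.ndarray,
                 membrane: Membrane | None,
                 energy_params: EnergyParams | None) -> np.ndarray:
    """M[a,b] = Coulomb energy per unit (q_a * q_b) between site side beads,
    with the folding model's screening, membrane scaling and range switch."""
    ep = energy_params or EnergyParams()
    pos = structure.sc_pos[sites]
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(r, np.inf)
    if membrane is not None:
        env = membrane.environment(pos[:, 2], ep.interface_halfwidth)
        mem_pair = (env[:, None] == ENV_MEMBRANE) & (env[None, :] == ENV_MEMBRANE)
    else:
        mem_pair = np.zeros_like(r, dtype=bool)
    eps_factor = np.where(mem_pair, ep.membrane_eps_factor, 1.0)
    sw, _ = _cutoff_switch(r, ep)
    with np.errstate(divide="ignore"):
        m = COULOMB_K / (ep.eps_slope * eps_factor * r ** 2) * sw
    m[r >= ep.cutoff] = 0.0
    np.fill_diagonal(m, 0.0)
    return m


def _state_energy(ionized, intrinsic, sign, pairm) -> float:
    q = sign * ionized
    return float(np.sum(intrinsic * ionized) + 0.5 * q @ pairm @ q)


def site_energy(state: ProtonationState, structure: CGStructure,
                params: MCPTParams, membrane: Membrane | None = None,
                energy_params: EnergyParams | None = None) -> float:
    """Total protonation energy (intrinsic + pairwise Coulomb) of a state."""
    sites, types, intrinsic, sign = _site_arrays(structure, params)
    if not np.array_equal(sites, state.site_residues):
        raise ValueError("state sites do not match structure's ionizable sites")
    pairm = _pair_matrix(structure, sites, membrane, energy_params)
    return _state_energy(state.ionized.astype(float), intrinsic, sign, pairm)


# --- MC driver ---------------------------------------------------------------

def _titrate(intrinsic) -> np.ndarray:
    """Independent-site pre-step: ionize wherever that lowers the intrinsic
    energy.  Fixes the proton count for the jump phase."""
    return intrinsic < 0.0


def _delta_jump(ionized, q, donor, acceptor, intrinsic, sign, pairm):
    """Energy change for moving one proton donor -> acceptor (flip both).

    With E = sum intrinsic*ion + 0.5 q^T M q the change is
    dq_d (Mq)_d + dq_a (Mq)_a + dq_d dq_a M_da plus the intrinsic flips."""
    flip_d = 1.0 - 2.0 * float(ionized[donor])
    flip_a = 1.0 - 2.0 * float(ionized[acceptor])
    d_int = intrinsic[donor] * flip_d + intrinsic[acceptor] * flip_a
    dq_d = sign[donor] * flip_d
    dq_a = sign[acceptor] * flip_a
    d_pair = dq_d * float(pairm[donor] @ q) + dq_a * float(pairm[acceptor] @ q) \
        + dq_d * dq_a * pairm[donor, acceptor]
    return float(d_int + d_pair)


def _mcpt_core(structure: CGStructure, params: MCPTParams,
               membrane: Membrane | None, energy_params: EnergyParams | None,
               record_visits: bool):
    sites, types, intrinsic, sign = _site_arrays(structure, params)
    if len(sites) == 0:
        warnings.warn("no ionizable sites; returning empty protonation state")
        empty = ProtonationState(np.array([], int), np.array([]), np.array([], bool))
        return empty, {}, []
    pairm = _pair_matrix(structure, sites, membrane, energy_params)
    rng = np.random.default_rng(params.seed)
    n = len(sites)
    n_steps = params.n_steps if params.n_steps is not None else 50 * n

    ionized = _titrate(intrinsic)
    acid = np.isin(types, list(ACIDS))
    energy = _state_energy(ionized.astype(float), intrinsic, sign, pairm)
    best_ion, best_e = ionized.copy(), energy
    visits: dict[tuple, int] = {}
    energies = [energy]
    kt = KB * params.temperature

    def protonated(ion):
        # proton sits on neutral acids and on ionized (charged) bases
        return (acid & ~ion) | (~acid & ion)

    for _ in range(n_steps):
        if record_visits:
            key = tuple(ionized.tolist())
            visits[key] = visits.get(key, 0) + 1
        has_p = np.where(protonated(ionized))[0]
        no_p = np.where(~protonated(ionized))[0]
        if len(has_p) == 0 or len(no_p) == 0:
            energies.append(energy)
            continue
        donor = has_p[rng.integers(len(has_p))]
        acceptor = no_p[rng.integers(len(no_p))]
        q = sign * ionized
        de = _delta_jump(ionized, q, donor, acceptor, intrinsic, sign, pairm)
        if de <= 0 or rng.random() < np.exp(-de / kt):
            ionized = ionized.copy()
            ionized[donor] = not ionized[donor]
            ionized[acceptor] = not ionized[acceptor]
            energy += de
            if energy < best_e - 1e-12:
                best_e, best_ion = energy, ionized.copy()
        energies.append(energy)
    if record_visits:
        key = tuple(ionized.tolist())
        visits[key] = visits.get(key, 0) + 1
    state = ProtonationState(sites, types, best_ion)
    return state, visits, energies


def run_mcpt(structure: CGStructure, params: MCPTParams | None = None,
             membrane: Membrane | None = None,
             energy_params: EnergyParams | None = None) -> ProtonationState:
    """Assign charge states by Metropolis proton-jump sampling.

    Returns the lowest-energy state visited; deterministic for a fixed seed.
    """
    params = params or MCPTParams()
    state, _, _ = _mcpt_core(structure, params, membrane, energy_params, False)
    return state


def run_mcpt_detailed(structure: CGStructure, params: MCPTParams | None = None,
                      membrane: Membrane | None = None,
                      energy_params: EnergyParams | None = None):
    """As :func:`run_mcpt` but also returns per-state visit counts (keyed by
    the ionization tuple) and the energy series, for sampling diagnostics."""
    params = params or MCPTParams()
    return _mcpt_core(structure, params, membrane, energy_params, True)


def greedy_proton_descent(structure: CGStructure,
                          params: MCPTParams | None = None,
                          membrane: Membrane | None = None,
                          energy_params: EnergyParams | None = None,
                          initial: ProtonationState | None = None
                          ) -> ProtonationState:
    """Deterministic zero-temperature limit of the proton-jump dynamics.

    Starting from the titration state (or ``initial``), repeatedly applies
    the single donor->acceptor jump with the largest energy decrease until no
    jump improves.  Seed-free and therefore invariant under relabelling of
    equivalent subunits, which the dimer-grid pipeline relies on; also used
    to polish a Monte Carlo result into its local minimum."""
    params = params or MCPTParams()
    sites, types, intrinsic, sign = _site_arrays(structure, params)
    if len(sites) == 0:
        warnings.warn("no ionizable sites; returning empty protonation state")
        return ProtonationState(np.array([], int), np.array([]), np.array([], bool))
    pairm = _pair_matrix(structure, sites, membrane, energy_params)
    if initial is not None:
        if not np.array_equal(initial.site_residues, sites):
            raise ValueError("initial state sites do not match structure")
        ionized = initial.ionized.copy()
    else:
        ionized = _titrate(intrinsic)
    acid = np.isin(types, list(ACIDS))
    for _ in range(16 * len(sites)):
        q = sign * ionized
        has_p = np.where((acid & ~ionized) | (~acid & ionized))[0]
        no_p = np.where(~((acid & ~ionized) | (~acid & ionized)))[0]
        best = (0.0, None)
        for d in has_p:
            for a in no_p:
                de = _delta_jump(ionized, q, d, a, intrinsic, sign, pairm)
                if de < best[0] - 1e-12:
                    best = (de, (d, a))
        if best[1] is None:
            break
        d, a = best[1]
        ionized[d] = not ionized[d]
        ionized[a] = not ionized[a]
    return ProtonationState(sites, types, ionized)


# --- text IO -----------------------------------------------------------------

def write_protonation_table(state: ProtonationState,
                            structure: CGStructure) -> str:
    df = pd.DataFrame({
        "chain": structure.chain[state.site_residues],
        "resnum": structure.resnum[state.site_residues],
        "restype": state.site_types,
        "charge": state.charges,
    })
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.1f")
    return buf.getvalue()


def read_protonation_table(text: str, structure: CGStructure) -> ProtonationState:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"chain": str})
    residues, types, ionized = [], [], []
    for _, row in df.iterrows():
        i = structure.residue_id(row["chain"], int(row["resnum"]))
        residues.append(i)
        types.append(row["restype"])
        ionized.append(abs(float(row["charge"])) > 0.5)
    return ProtonationState(np.array(residues), np.array(types),
                            np.array(ionized))
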