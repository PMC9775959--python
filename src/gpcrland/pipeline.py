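"""End-to-end orchestration of the three landscape scenarios.

Scenario A — class-A-like receptor: 1D three-state activation profile
(inactive -> intermediate -> active, ten frames per transition), with and
without an agonist bound to every conformation, plus point-mutation scans of
the pocket (the T188/D113 analogues).

Scenario B — class-B-like receptor: 2D map coupling the receptor
conformational change with the approach distance of a G-protein surrogate;
compares the coupled least-energy path against activation with the partner
held far away.

Scenario C — class-C-like obligate dimer: L x R grid of per-subunit
conformations (17 each), least-energy pathway, two-sided barriers around the
stable intermediate, and agonist injection to neither/L/R/both subunits
(four landscapes).

All randomness derives from one master seed through per-stage substreams, so
a full run is bit-reproducible.  Charge states are assigned before every
energy evaluation: Metropolis proton-transfer sampling polished to its local
minimum by deterministic steepest-descent jumps ("mcpt" mode), or the
deterministic zero-temperature assignment alone ("greedy" mode, the default
for the dimer grid where it keeps the L/R exchange symmetry of the
construction exact).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cg_model import CGStructure, coarse_grain, mutate_residue, trim_to_common
from .energetics import (
    EnergyParams, Membrane, build_membrane, folding_free_energy,
    energy_with_error,
)
from .protonation import MCPTParams, run_mcpt, greedy_proton_descent
from .morphing import (
    interpolate_endpoints, sample_equal_intervals,
    concatenate_trajectories, relax,
)
from .binding import BindingParams, Pose, bind_along_path
from .landscape import (
    Landscape1D, Landscape2D, Pathway, profile_1d, barrier,
    two_sided_barriers, build_grid_2d, least_energy_path, fixed_row_path,
    compare_pathways,
)
from .synthetic import (
    BundleSpec, ActivationSpec, InterfaceSpec, LigandSpec,
    make_activation_series, make_activation_pair, make_dimer_frames,
    make_pocket_and_ligand, make_gprotein_surrogate, helix_residue_numbers,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScenarioReport", "run_scenario", "mutation_scan"]


@dataclass
class RunConfig:
    """Configuration of one scenario run (YAML-serialisable)."""

    scenario: str = "A"                 # A | B | C
    seed: int = 1                       # canonical synthetic receptor
    input_mode: str = "synthetic"       # synthetic | pdb
    outdir: str | None = None
    # synthetic system
    n_helices: int = 7
    helix_length: int = 24
    swing_helix: int = 5
    swing_distance: float | None = None   # default per scenario (14/18/6)
    # morphing / sampling
    n_raw: int = 65                     # raw interpolation frames per segment
    frames_per_transition: int = 10     # scenarios A and B
    frames_per_subunit: int = 17        # scenario C
    # relaxation
    relax_max_steps: int = 300
    relax_tolerance: float = 0.02       # kcal/mol over the 10-step tail
    relax_method: str = "lbfgs"         # lbfgs | descent
    # protonation
    protonation: str | None = None      # mcpt | greedy (default per scenario)
    mcpt: dict = field(default_factory=dict)
    # energy / membrane
    energy: dict = field(default_factory=dict)
    slab_half_thickness: float = 15.0
    # binding
    binding: dict = field(default_factory=dict)
    with_ligand: bool = True
    ligand_net_charge: float = 1.0
    # scenario A mutations: list of [role_or_chain, resnum_or_type, new_type]
    mutations: list = field(default_factory=lambda: ["t_role", "d_role"])
    # scenario B approach axis
    approach_max: float = 30.0
    approach_points: int = 11
    # scenario C agonist placements
    agonist_placements: tuple = ("none", "L", "R", "both")

    def __post_init__(self):
        if self.scenario not in ("A", "B", "C"):
            raise ValueError("scenario must be A, B or C")
        if self.frames_per_transition < 2 or self.frames_per_subunit < 2:
            raise ValueError("frame counts must be >= 2")
        if self.input_mode != "synthetic":
            raise NotImplementedError(
                "pdb input mode requires pre-oriented structures and a chain "
                "map; only synthetic mode is wired into the scenarios")

    @property
    def effective_swing(self) -> float:
        if self.swing_distance is not None:
            return self.swing_distance
        return {"A": 14.0, "B": 18.0, "C": 6.0}[self.scenario]

    @property
    def effective_protonation(self) -> str:
        """Charge-assignment mode: the deterministic zero-temperature jump
        descent by default (frame-to-frame charge states then respond only
        to geometry, and the dimer grid keeps its L/R exchange symmetry
        exact); 'mcpt' runs the finite-temperature sampler first and
        polishes its best state."""
        if self.protonation is not None:
            return self.protonation
        return "greedy"

    def energy_params(self) -> EnergyParams:
        d = EnergyParams().to_dict()
        d.update(self.energy)
        d["slab_half_thickness"] = self.slab_half_thickness
        return EnergyParams.from_dict(d)

    def binding_params(self) -> BindingParams:
        bp = BindingParams()
        for k, v in self.binding.items():
            setattr(bp, k, v)
        return bp

    def mcpt_params(self, seed: int) -> MCPTParams:
        d = dict(self.mcpt)
        d["seed"] = seed
        return MCPTParams(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "agonist_placements" in d:
            d["agonist_placements"] = tuple(d["agonist_placements"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ScenarioReport:
    """Everything one scenario run produced, plus provenance."""

    scenario: str
    barriers: dict                      # name -> (value, sd) or dict
    profiles: dict = field(default_factory=dict)   # name -> Landscape1D
    grids: dict = field(default_factory=dict)      # name -> Landscape2D
    pathways: dict = field(default_factory=dict)   # name -> Pathway
    binding: dict = field(default_factory=dict)    # name -> np.ndarray
    frame_table: pd.DataFrame | None = None
    pocket: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    # in-memory state for follow-up scans (not serialised)
    _state: dict = field(default_factory=dict, repr=False)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.frame_table is not None:
            self.frame_table.to_csv(out / "frames.tsv", sep="\t",
                                    index=False, float_format="%.6f")
        for name, prof in self.profiles.items():
            (out / f"profile_{name}.tsv").write_text(prof.to_table())
        for name, grid in self.grids.items():
            (out / f"grid_{name}.tsv").write_text(grid.to_table())
        for name, path in self.pathways.items():
            (out / f"path_{name}.tsv").write_text(path.to_table())
        for name, b in self.binding.items():
            pd.DataFrame({"frame": np.arange(len(b)), "binding": b}).to_csv(
                out / f"binding_{name}.tsv", sep="\t", index=False,
                float_format="%.6f")
        manifest = {
            "scenario": self.scenario,
            "barriers": _jsonable(self.barriers),
            "pocket": _jsonable(self.pocket),
            "provenance": self.provenance,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _substream(seed: int, stage: int, k: int = 0) -> int:
    """Derived seed for one stage/frame, kept below 2**31."""
    return (seed * 1000003 + stage * 7919 + k) % (2 ** 31 - 19)


def _assign_charges(structure: CGStructure, config: RunConfig, seed: int,
                    membrane: Membrane, eparams: EnergyParams):
    mode = config.effective_protonation
    mp = config.mcpt_params(seed)
    if mode == "greedy":
        state = greedy_proton_descent(structure, mp, membrane, eparams)
    elif mode == "mcpt":
        state = run_mcpt(structure, mp, membrane, eparams)
        if len(state.site_residues):
            state = greedy_proton_descent(structure, mp, membrane, eparams,
                                          initial=state)
    else:
        raise ValueError(f"unknown protonation mode {mode!r}")
    return state


def _frame_positions(frames) -> np.ndarray:
    return np.vstack([np.vstack([f.bb_pos, f.sc_pos[f.has_sc]])
                      for f in frames])


def _evaluate_frames(frames, config: RunConfig, membrane: Membrane,
                     eparams: EnergyParams, stage: int):
    """Per-frame pipeline: charge assignment, restrained relaxation, energy
    with error bar.  Returns (relaxed frames, charges, values, sds,
    breakdowns)."""
    relaxed, charges, values, sds, breakdowns = [], [], [], [], []
    for k, frame in enumerate(frames):
        state = _assign_charges(frame, config, _substream(config.seed, stage, k),
                                membrane, eparams)
        ch = state.per_residue_charges(frame)
        res = relax(frame, max_steps=config.relax_max_steps,
                    tolerance=config.relax_tolerance,
                    seed=_substream(config.seed, stage + 1, k),
                    charges=ch, membrane=membrane, params=eparams,
                    method=config.relax_method)
        v, sd = energy_with_error(res)
        bd = folding_free_energy(res.final, ch, membrane, eparams)
        relaxed.append(res.final)
        charges.append(ch)
        values.append(v)
        sds.append(sd)
        breakdowns.append(bd)
        logger.info("frame %d: E = %.2f +/- %.2f kcal/mol", k, v, sd)
    return relaxed, charges, np.array(values), np.array(sds), breakdowns


def _barrier_sd(values, sds) -> float:
    k = int(np.argmax(np.asarray(values) - values[0]))
    return float(np.hypot(sds[k], sds[0]))


def _frame_dataframe(coords, breakdowns, sds, extra: dict | None = None
                     ) -> pd.DataFrame:
    from .energetics import TERM_NAMES
    rows = []
    for k, bd in enumerate(breakdowns):
        row = {"frame": k, "coordinate": coords[k]}
        row.update(bd.terms())
        row["total"] = bd.total
        row["sd"] = sds[k]
        rows.append(row)
    df = pd.DataFrame(rows)
    for name, arr in (extra or {}).items():
        df[name] = arr
    return df


# --- scenario A --------------------------------------------------------------

def _bundle_spec(config: RunConfig) -> BundleSpec:
    # A/B: the acidic ring sits on the swing helix (its ionic lock breaks on
    # activation and its acids arrive at the cationic amine ligand).  C: the
    # swing helix keeps the basic ring — the anionic glutamate-like agonist
    # is bound by approaching K/R, as in the real class-C pockets — and the
    # lock acid moves to the neighbouring helix.
    lock = config.swing_helix if config.scenario in ("A", "B") \
        else (config.swing_helix - 1) % config.n_helices
    return BundleSpec(n_helices=config.n_helices,
                      helix_length=config.helix_length, seed=config.seed,
                      lock_acid_helix=lock)


def _build_three_state_path(config: RunConfig):
    spec = _bundle_spec(config)
    act = ActivationSpec(swing_helix=config.swing_helix,
                         swing_distance=config.effective_swing)
    states = make_activation_series(spec, act, [0.0, 0.5, 1.0])
    states = trim_to_common(states)
    cgs = [coarse_grain(s) for s in states]
    k = config.frames_per_transition
    seg1 = sample_equal_intervals(
        interpolate_endpoints(cgs[0], cgs[1], config.n_raw), k)
    seg2 = sample_equal_intervals(
        interpolate_endpoints(seg1.frames[-1], cgs[2], config.n_raw), k)
    traj = concatenate_trajectories([seg1, seg2])
    return spec, act, cgs, traj


def _scenario_a_pocket(spec: BundleSpec, act: ActivationSpec,
                       frames: list[CGStructure], config: RunConfig,
                       chain: str = "A"):
    """Select pocket residues programmatically.

    The ligand is seated beside the point where a moving residue of the
    swing helix arrives in the active state.  Two pocket roles live on the
    moving half so their ligand contacts genuinely change along the path:
    the D-role (mutated to aspartate) is the mover that ends nearest the
    ligand — its salt bridge to the ligand strengthens as the receptor
    activates — and the T-role (mutated to threonine) is the mover that
    starts nearest the ligand — its contact fades during activation.
    Anchor residues for carrying the pose between frames sit on the two
    flanking helices, which do not move."""
    first, last = frames[0], frames[-1]
    swing_nums = helix_residue_numbers(spec, act.swing_helix)
    movers = []   # (resnum, index) of side-chain-bearing residues that move
    for n in swing_nums:
        i = first.residue_id(chain, int(n))
        if not first.has_sc[i]:
            continue
        moved = float(np.linalg.norm(last.sc_pos[i] - first.sc_pos[i]))
        z = first.bb_pos[i, 2]
        if moved >= 1.5 and -10.0 <= z <= -1.0:
            movers.append((int(n), i))
    if len(movers) < 2:
        raise RuntimeError("too few moving pocket candidates on the swing helix")
    # ligand site: arrival point of the mover closest to z = -5, offset outward
    ref = min(movers, key=lambda m: abs(first.bb_pos[m[1], 2] + 5.0))
    target = last.sc_pos[ref[1]]
    axis_xy = first.bb_pos[[i for _, i in movers], :2].mean(axis=0)
    outward = target[:2] - axis_xy
    outward = outward / np.linalg.norm(outward)
    centre = target + np.array([4.0 * outward[0], 4.0 * outward[1], 0.0])
    outward3 = np.array([outward[0], outward[1], 0.0])

    # anchors: the two nearest side-chain residues on each flanking helix
    # (static, so the pose stays put while the movers approach or retreat)
    anchors = []
    for h in ((act.swing_helix - 1) % spec.n_helices,
              (act.swing_helix + 1) % spec.n_helices):
        ranked = []
        for n in helix_residue_numbers(spec, h):
            i = first.residue_id(chain, int(n))
            if not first.has_sc[i]:
                continue
            d = float(np.linalg.norm(first.sc_pos[i] - centre))
            ranked.append((d, int(n)))
        ranked.sort()
        anchors.extend(n for _, n in ranked[:2])
    return {
        "movers": movers,
        "anchors": [(chain, n) for n in anchors],
        "centre": centre,
        "outward": outward3,
        "chain": chain,
    }


def _assign_pocket_roles(pocket: dict, frames: list[CGStructure],
                         ligand_centroid: np.ndarray) -> None:
    """Pick the mutation-scan roles from the placed ligand: the D-role is
    the mover with the largest approach to the ligand over the path (its
    salt bridge strengthens as the receptor activates), the T-role the
    mover with the largest retreat (its contact fades)."""
    first, last = frames[0], frames[-1]
    chain = pocket["chain"]
    approach = []
    for n, i in pocket["movers"]:
        d0 = float(np.linalg.norm(first.sc_pos[i] - ligand_centroid))
        d1 = float(np.linalg.norm(last.sc_pos[i] - ligand_centroid))
        approach.append((d0 - d1, n, d1))
    approach.sort(reverse=True)
    # D-role: biggest approach whose final distance is in interaction range
    d_entry = next((a for a in approach if a[2] <= 9.0), approach[0])
    t_entry = next(a for a in reversed(approach) if a[1] != d_entry[1])
    pocket["d_role"] = (chain, d_entry[1])
    pocket["t_role"] = (chain, t_entry[1])
    pocket["contact"] = (chain, d_entry[1])


def _resolve_mutations(config: RunConfig, pocket: dict) -> list[tuple]:
    """Mutation entries may be the strings 't_role'/'d_role' (mutated to A)
    or explicit [chain, resnum, new_type] triples."""
    out = []
    for m in config.mutations:
        if isinstance(m, str):
            chain, resnum = pocket[m]
            out.append((f"{m}_A", chain, resnum, "A"))
        else:
            chain, resnum, new = m
            out.append((f"{chain}{resnum}{new}", chain, int(resnum), new))
    return out


def scenario_a(config: RunConfig) -> ScenarioReport:
    eparams = config.energy_params()
    spec, act, cgs, traj = _build_three_state_path(config)
    membrane = build_membrane(cgs[0], config.slab_half_thickness, eparams,
                              exclude_positions=_frame_positions(traj.frames))
    relaxed, charges, values, sds, breakdowns = _evaluate_frames(
        traj.frames, config, membrane, eparams, stage=10)
    labels = ["inactive"] + [""] * (len(relaxed) - 2) + ["active"]
    labels[(len(relaxed) - 1) // 2] = "intermediate"
    prof_apo = profile_1d(traj.coordinate, values, sds, labels)
    barriers = {"apo": (barrier(prof_apo), _barrier_sd(values, sds))}
    profiles = {"apo": prof_apo}
    binding_tables: dict = {}
    pocket: dict = {}
    pose = None
    bparams = config.binding_params()

    if config.with_ligand:
        pocket = _scenario_a_pocket(spec, act, relaxed, config)
        _, pose = make_pocket_and_ligand(
            relaxed[-1], pocket["anchors"],
            LigandSpec(net_charge=config.ligand_net_charge),
            seed=_substream(config.seed, 31),
            centre_override=pocket["centre"],
            clearance=4.2, check_structures=relaxed[:-1],
            nudge_direction=pocket["outward"],
            orient_toward=pocket["centre"] - 5.0 * pocket["outward"])
        pose.receptor_frame_index = len(relaxed) - 1
        _assign_pocket_roles(pocket, relaxed,
                             pose.ligand.positions.mean(axis=0))
        # type the pocket roles on every frame so states stay consistent
        for role, new in (("t_role", "T"), ("d_role", "D")):
            chain, resnum = pocket[role]
            relaxed = [mutate_residue(f, chain, resnum, new) for f in relaxed]
        # re-assign charges (the D-role adds an ionizable site)
        charges = []
        for k, f in enumerate(relaxed):
            st = _assign_charges(f, config, _substream(config.seed, 30, k),
                                 membrane, eparams)
            charges.append(st.per_residue_charges(f))
        breakdowns = [folding_free_energy(f, ch, membrane, eparams)
                      for f, ch in zip(relaxed, charges)]
        values = np.array([bd.total for bd in breakdowns])
        prof_apo = profile_1d(traj.coordinate, values, sds, labels)
        profiles["apo"] = prof_apo
        barriers["apo"] = (barrier(prof_apo), _barrier_sd(values, sds))

        b = bind_along_path(relaxed, pose, charges, bparams, eparams)
        binding_tables["holo"] = b
        holo_vals = values + b
        prof_holo = profile_1d(traj.coordinate, holo_vals, sds, labels)
        profiles["holo"] = prof_holo
        barriers["holo"] = (barrier(prof_holo), _barrier_sd(holo_vals, sds))

    report = ScenarioReport(
        scenario="A",
        barriers=barriers,
        profiles=profiles,
        binding=binding_tables,
        frame_table=_frame_dataframe(
            traj.coordinate, breakdowns, sds,
            {"binding_holo": binding_tables.get("holo",
                                                np.zeros(len(relaxed)))}),
        pocket={k: v for k, v in pocket.items()
                if k in ("contact", "t_role", "d_role", "anchors")},
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__},
        _state={"frames": relaxed, "charges": charges, "values": values,
                "sds": sds, "membrane": membrane, "pose": pose,
                "coords": traj.coordinate, "config": config,
                "eparams": eparams, "bparams": bparams},
    )
    if config.with_ligand and config.mutations:
        report.barriers["mutations"] = mutation_scan(config, report)
    return report


def mutation_scan(config: RunConfig, base: ScenarioReport) -> dict:
    """Re-evaluate folding + binding on the base run's frames for each
    mutation (geometry reused) and report barrier deltas vs the base holo
    barrier."""
    st = base._state
    if not st:
        raise ValueError("base report carries no reusable state")
    frames, membrane = st["frames"], st["membrane"]
    eparams, bparams = st["eparams"], st["bparams"]
    pose, coords, sds = st["pose"], st["coords"], st["sds"]
    out = {}
    for name, chain, resnum, new in _resolve_mutations(config, base.pocket):
        try:
            mut_frames = [mutate_residue(f, chain, resnum, new)
                          for f in frames]
        except KeyError as exc:
            raise ValueError(f"mutation site {chain}{resnum} absent") from exc
        mcharges, mvalues = [], []
        for k, f in enumerate(mut_frames):
            state = _assign_charges(f, config, _substream(config.seed, 40, k),
                                    membrane, eparams)
            ch = state.per_residue_charges(f)
            mcharges.append(ch)
            mvalues.append(folding_free_energy(f, ch, membrane, eparams).total)
        mvalues = np.array(mvalues)
        b = bind_along_path(mut_frames, pose, mcharges, bparams, eparams) \
            if pose is not None else np.zeros(len(mut_frames))
        prof = profile_1d(coords, mvalues + b, sds)
        base_holo = base.barriers["holo"][0] if "holo" in base.barriers \
            else base.barriers["apo"][0]
        out[name] = {
            "barrier": (barrier(prof), _barrier_sd(mvalues + b, sds)),
            "delta_vs_holo": barrier(prof) - base_holo,
            "binding": b.tolist(),
        }
        base.profiles[name] = prof
        base.binding[name] = b
    return out


# --- scenario B --------------------------------------------------------------

def scenario_b(config: RunConfig) -> ScenarioReport:
    eparams = config.energy_params()
    spec = _bundle_spec(config)
    act = ActivationSpec(swing_helix=config.swing_helix,
                         swing_distance=config.effective_swing)
    start_atoms, end_atoms = make_activation_pair(spec, act)
    cgi, cga = coarse_grain(start_atoms), coarse_grain(end_atoms)
    traj = sample_equal_intervals(
        interpolate_endpoints(cgi, cga, config.n_raw),
        config.frames_per_transition)

    # partner bound site: under the swing helix's inactive cytoplasmic end
    nums = helix_residue_numbers(spec, act.swing_helix)
    idx = [cgi.residue_id("A", int(n)) for n in nums]
    term = cgi.bb_pos[min(idx, key=lambda i: cgi.bb_pos[i, 2])]
    partner = make_gprotein_surrogate()
    bound_centre = term + np.array([0.0, 0.0, -4.0])
    dists = np.linspace(0.0, config.approach_max, config.approach_points)

    def partner_at(d: float) -> CGStructure:
        return partner.transformed(
            translation=bound_centre - np.array([0.0, 0.0, float(d)]))

    excl = [_frame_positions(traj.frames)]
    for d in dists:
        p = partner_at(d)
        excl.append(np.vstack([p.bb_pos, p.sc_pos]))
    membrane = build_membrane(cgi, config.slab_half_thickness, eparams,
                              exclude_positions=np.vstack(excl))
    relaxed, charges, values, sds, breakdowns = _evaluate_frames(
        traj.frames, config, membrane, eparams, stage=50)

    frame_index = {id(f): i for i, f in enumerate(relaxed)}
    dist_index = {float(d): j for j, d in enumerate(dists)}

    def energy_fn(frame: CGStructure, d: float) -> float:
        cell = frame_index[id(frame)] * len(dists) + dist_index[float(d)]
        cx = CGStructure.concatenate([frame, partner_at(d)])
        state = _assign_charges(cx, config, _substream(config.seed, 60, cell),
                                membrane, eparams)
        return folding_free_energy(cx, state.per_residue_charges(cx),
                                   membrane, eparams).total

    grid = build_grid_2d(relaxed, dists, energy_fn)
    far = len(dists) - 1
    coupled = least_energy_path(grid, (0, far), (len(relaxed) - 1, 0))
    fixed_far = fixed_row_path(grid, far, axis=1)
    delta = compare_pathways(grid, coupled, fixed_far)
    prof_fixed = profile_1d(traj.coordinate,
                            grid.energies[:, far], sds)
    report = ScenarioReport(
        scenario="B",
        barriers={
            "fixed_far": (fixed_far.barrier, _barrier_sd(
                grid.energies[:, far], sds)),
            "coupled": (coupled.barrier, _barrier_sd(
                coupled.energies, np.full(len(coupled.energies),
                                          float(np.mean(sds))))),
            "delta_coupled_minus_fixed": delta,
            "active_basin_bound_minus_far": float(
                grid.energies[-1, 0] - grid.energies[-1, far]),
        },
        profiles={"fixed_far": prof_fixed},
        grids={"conformation_x_distance": grid},
        pathways={"coupled": coupled, "fixed_far": fixed_far},
        frame_table=_frame_dataframe(traj.coordinate, breakdowns, sds),
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__},
        _state={"frames": relaxed, "membrane": membrane, "grid": grid,
                "distances": dists},
    )
    return report


# --- scenario C --------------------------------------------------------------

def scenario_c(config: RunConfig) -> ScenarioReport:
    eparams = config.energy_params()
    spec = _bundle_spec(config)
    act = ActivationSpec(swing_helix=config.swing_helix,
                         swing_distance=config.effective_swing)
    iface = InterfaceSpec()
    start_atoms, end_atoms = make_activation_pair(spec, act)
    cgi, cga = coarse_grain(start_atoms), coarse_grain(end_atoms)
    traj = sample_equal_intervals(
        interpolate_endpoints(cgi, cga, config.n_raw),
        config.frames_per_subunit)

    # relax internal monomer conformations once; the dimer grid reuses them
    mem_mono = build_membrane(cgi, config.slab_half_thickness, eparams,
                              with_particles=False)
    mono, _, _, msds, _ = _evaluate_frames(
        traj.frames, config, mem_mono, eparams, stage=70)
    lframes, rframes, sep = make_dimer_frames(mono, spec, iface)

    cell00 = CGStructure.concatenate([lframes[0], rframes[0]])
    membrane = build_membrane(
        cell00, config.slab_half_thickness, eparams,
        exclude_positions=_frame_positions(lframes + rframes))

    def energy_fn(l: CGStructure, r: CGStructure) -> float:
        cx = CGStructure.concatenate([l, r])
        state = _assign_charges(cx, config, 0, membrane, eparams)
        return folding_free_energy(cx, state.per_residue_charges(cx),
                                   membrane, eparams).total

    grid_apo = build_grid_2d(lframes, rframes, energy_fn)
    n = len(lframes)

    # per-subunit agonist binding, computed on each subunit's own frames
    bl = np.zeros(n)
    br = np.zeros(n)
    pose_info: dict = {}
    if config.with_ligand:
        bparams = config.binding_params()
        pocket = _scenario_c_pocket(spec, act, lframes)
        charges_l = []
        for k, f in enumerate(lframes):
            st = _assign_charges(f, config, 0, membrane, eparams)
            charges_l.append(st.per_residue_charges(f))
        _, pose = make_pocket_and_ligand(
            lframes[-1], pocket["anchors"],
            LigandSpec(name="glutamate-like", net_charge=-1.0),
            seed=_substream(config.seed, 80),
            centre_override=pocket["centre"],
            clearance=5.0, check_structures=lframes[:-1])
        pose.receptor_frame_index = n - 1
        bl = bind_along_path(lframes, pose, charges_l, bparams, eparams)
        # R subunit: the pose is the exact C2 image of the L pose, and the
        # binding energies are recomputed on the R frames
        charges_r = []
        for k, f in enumerate(rframes):
            st = _assign_charges(f, config, 0, membrane, eparams)
            charges_r.append(st.per_residue_charges(f))
        lig_r = pose.ligand.moved()
        lig_r.positions = pose.ligand.positions * np.array([-1.0, -1.0, 1.0])
        pose_r = Pose(lig_r, n - 1,
                      [("R", rn) for _, rn in pose.anchor_residues])
        br = bind_along_path(rframes, pose_r, charges_r, bparams, eparams)
        pose_info = {k: v for k, v in pocket.items() if k != "centre"}

    grids = {"apo": grid_apo}
    if config.with_ligand:
        for placement in config.agonist_placements:
            if placement == "none":
                continue
            add = np.zeros((n, n))
            if placement in ("L", "both"):
                add += bl[:, None]
            if placement in ("R", "both"):
                add += br[None, :]
            grids[placement] = Landscape2D(grid_apo.axis1, grid_apo.axis2,
                                           grid_apo.energies + add)

    pathways, barriers = {}, {}
    for name, grid in grids.items():
        path = least_energy_path(grid, (0, 0), (n - 1, n - 1))
        ts = two_sided_barriers(path.energies)
        pathways[name] = path
        barriers[name] = {
            "barrier": path.barrier,
            "barrier1": ts.barrier1,
            "barrier2": ts.barrier2,
            "has_interior_minimum": ts.has_interior_minimum,
            "sd": float(np.hypot(msds.max(), msds.max())),
        }

    report = ScenarioReport(
        scenario="C",
        barriers=barriers,
        grids=grids,
        pathways=pathways,
        binding={"L": bl, "R": br},
        pocket=pose_info,
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__},
        _state={"lframes": lframes, "rframes": rframes,
                "membrane": membrane, "separation": sep},
    )
    return report


def _scenario_c_pocket(spec: BundleSpec, act: ActivationSpec,
                       lframes: list[CGStructure]):
    """Pocket for the dimer subunit, chosen like the scenario-A pocket but
    on the L subunit's frames (which carry the facing rotation)."""
    first, last = lframes[0], lframes[-1]
    swing_nums = helix_residue_numbers(spec, act.swing_helix)
    cand = []
    for nn in swing_nums:
        i = first.residue_id("L", int(nn))
        if not first.has_sc[i]:
            continue
        moved = float(np.linalg.norm(last.sc_pos[i] - first.sc_pos[i]))
        z = first.bb_pos[i, 2]
        if -16.5 <= z <= -8.0 and moved >= 2.0:
            cand.append((abs(z + 12.0), int(nn), i))
    if not cand:
        raise RuntimeError("no suitable contact residue on the swing helix")
    cand.sort()
    _, contact_num, contact_i = cand[0]
    target = last.sc_pos[contact_i]
    axis_xy = last.bb_pos[[first.residue_id("L", int(nb))
                           for nb in swing_nums], :2].mean(axis=0)
    outward = target[:2] - axis_xy
    outward = outward / np.linalg.norm(outward)
    centre = target + np.array([5.0 * outward[0], 5.0 * outward[1], 0.0])
    anchors = []
    for h in ((act.swing_helix - 1) % spec.n_helices,
              (act.swing_helix + 1) % spec.n_helices):
        ranked = []
        for nn in helix_residue_numbers(spec, h):
            i = first.residue_id("L", int(nn))
            if not first.has_sc[i]:
                continue
            d = float(np.linalg.norm(first.sc_pos[i] - centre))
            ranked.append((d, int(nn)))
        ranked.sort()
        anchors.extend(("L", nn) for _, nn in ranked[:2])
    return {"contact": ("L", contact_num), "anchors": anchors,
            "centre": centre}


# --- entry point -------------------------------------------------------------

def run_scenario(config: RunConfig) -> ScenarioReport:
    """Run one scenario end to end and optionally persist its tables."""
    fn = {"A": scenario_a, "B": scenario_b, "C": scenario_c}[config.scenario]
    logger.info("running scenario %s (seed %d)", config.scenario, config.seed)
    report = fn(config)
    if config.outdir:
        report.write(config.outdir)
    return report
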