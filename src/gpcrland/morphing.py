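"""Conformational morphing between endpoint structures and CG relaxation.

The transition path between two conformations of the same sequence is built
by optimal rigid-body superposition of the end state onto the start state
followed by linear Cartesian interpolation of every bead — a desk-scale
surrogate for targeted molecular dynamics that delivers the same artefact:
an ordered, equally spaced series of conformations along a [0, 1] reaction
coordinate.  Each sampled conformation is then relaxed on the CG energy
surface by damped steepest descent with the backbone harmonically restrained
to its interpolated position, so frames keep their place on the coordinate
while side chains unwind steric strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .cg_model import CGStructure
from .energetics import EnergyParams, Membrane, build_bead_system

__all__ = [
    "Trajectory", "RelaxationResult", "superpose", "interpolate_endpoints",
    "sample_equal_intervals", "concatenate_trajectories", "relax",
]


@dataclass
class Trajectory:
    """Ordered conformation series along a [0, 1] reaction coordinate."""

    frames: list[CGStructure]
    coordinate: np.ndarray

    def __post_init__(self):
        self.coordinate = np.asarray(self.coordinate, dtype=float)
        if len(self.frames) != len(self.coordinate):
            raise ValueError("frames and coordinate must have equal length")
        if len(self.frames) >= 2 and not np.all(np.diff(self.coordinate) > 0):
            raise ValueError("coordinate must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class RelaxationResult:
    final: CGStructure
    tail_energies: np.ndarray   # last <= 10 folding totals
    converged: bool
    steps_used: int
    energy_series: np.ndarray = field(default=None)

    def __post_init__(self):
        self.tail_energies = np.asarray(self.tail_energies, dtype=float)
        if self.energy_series is not None:
            self.energy_series = np.asarray(self.energy_series, dtype=float)


def _check_same_layout(a: CGStructure, b: CGStructure) -> None:
    if not (np.array_equal(a.chain, b.chain)
            and np.array_equal(a.resnum, b.resnum)
            and np.array_equal(a.restype, b.restype)
            and np.array_equal(a.has_sc, b.has_sc)):
        raise ValueError("endpoint structures do not share a residue layout; "
                         "run trim_to_common first")


def superpose(mobile: CGStructure, reference: CGStructure) -> CGStructure:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``
    (Kabsch on backbone beads)."""
    _check_same_layout(mobile, reference)
    mob = mobile.bb_pos
    ref = reference.bb_pos
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    out = mobile.copy()
    out.bb_pos = (mob - mc) @ rot.as_matrix().T + rc
    sc = mobile.sc_pos.copy()
    valid = mobile.has_sc
    sc[valid] = (sc[valid] - mc) @ rot.as_matrix().T + rc
    out.sc_pos = sc
    return out


def interpolate_endpoints(start: CGStructure, end: CGStructure,
                          n_frames: int) -> Trajectory:
    """Linear Cartesian interpolation after superposing ``end`` onto
    ``start``; frame k sits at coordinate k/(n_frames-1)."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    _check_same_layout(start, end)
    end_fit = superpose(end, start)
    fracs = np.linspace(0.0, 1.0, n_frames)
    frames = []
    for k, f in enumerate(fracs):
        if k == 0:
            frames.append(start.copy())
            continue
        if k == n_frames - 1:
            frames.append(end_fit.copy())
            continue
        fr = start.copy()
        fr.bb_pos = (1 - f) * start.bb_pos + f * end_fit.bb_pos
        fr.sc_pos = (1 - f) * start.sc_pos + f * end_fit.sc_pos
        frames.append(fr)
    return Trajectory(frames, fracs)


def sample_equal_intervals(traj: Trajectory, k: int) -> Trajectory:
    """Pick k frames nearest to coordinates j/(k-1); endpoints always kept.

    For k = 17 this yields 15 intermediates plus the 2 endpoints."""
    n = len(traj)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot sample {k} frames from a {n}-frame trajectory")
    targets = np.linspace(0.0, 1.0, k)
    idx = [int(np.argmin(np.abs(traj.coordinate - t))) for t in targets]
    idx[0], idx[-1] = 0, n - 1
    if len(set(idx)) != k:
        # fall back to evenly spaced frame indices when coordinates collide
        idx = [int(round(j * (n - 1) / (k - 1))) for j in range(k)]
    return Trajectory([traj.frames[i] for i in idx],
                      traj.coordinate[idx])


def concatenate_trajectories(segments: list[Trajectory]) -> Trajectory:
    """Chain multi-segment paths (e.g. inactive -> intermediate -> active),
    deduplicating the shared state between consecutive segments and rescaling
    the coordinate to span [0, 1] overall."""
    if not segments:
        raise ValueError("no segments")
    s = len(segments)
    frames: list[CGStructure] = []
    coords: list[float] = []
    for si, seg in enumerate(segments):
        lo, hi = si / s, (si + 1) / s
        segc = lo + seg.coordinate * (hi - lo)
        start_at = 1 if si > 0 else 0
        if si > 0 and not np.allclose(segments[si - 1].frames[-1].bb_pos,
                                      seg.frames[0].bb_pos, atol=1e-6):
            raise ValueError(f"segment {si} does not start where segment "
                             f"{si - 1} ends")
        frames.extend(seg.frames[start_at:])
        coords.extend(segc[start_at:])
    return Trajectory(frames, np.array(coords))


def relax(structure: CGStructure, max_steps: int = 2000,
          tolerance: float = 0.05, seed: int = 0, *,
          charges: np.ndarray | None = None,
          membrane: Membrane | None = None,
          params: EnergyParams | None = None,
          restrain_backbone: bool = True,
          restraint_targets: np.ndarray | None = None,
          method: str = "descent") -> RelaxationResult:
    """Relax a conformation on the CG energy surface.

    ``method='descent'`` (default) is damped steepest descent with
    backtracking — monotone in the objective step over step.
    ``method='lbfgs'`` hands the same analytic gradient to L-BFGS, which
    escapes the shallow plateaus of highly symmetric starting geometries far
    faster; its energy series is not strictly monotone.

    Backbone beads are harmonically restrained (k = ``params.restraint_k``)
    to ``restraint_targets`` (their input positions by default); side-chain
    beads carry a weak restraint (``params.side_restraint_k``) that keeps
    relaxation inside the frame's packing basin.  The procedure is
    deterministic — the seed only
    jitters beads that start closer than 0.5 A to another bead.  Convergence
    is declared when the recorded energy varies by less than ``tolerance``
    over the last ten steps.  ``tail_energies`` holds the folding totals of
    those final steps (without the restraint contribution), which downstream
    code uses for the headline energy and its error bar.
    """
    params = params or EnergyParams()
    system = build_bead_system(structure, charges, membrane, params)
    R = system.n_res

    rng = np.random.default_rng(seed)
    # jitter near-coincident beads so the first gradient is finite
    d = np.linalg.norm(system.pos[:, None, :] - system.pos[None, :, :], axis=-1)
    iu = np.triu_indices(system.n, 1)
    tooclose = (d[iu] < 0.5) & (system.res[iu[0]] != system.res[iu[1]])
    if tooclose.any():
        bad = np.unique(iu[0][tooclose])
        system.pos[bad] += 0.1 * rng.standard_normal((len(bad), 3))

    targets = system.pos.copy()
    if restraint_targets is not None:
        targets[:R] = np.asarray(restraint_targets, dtype=float).reshape(R, 3)
    k_bead = np.zeros(len(system.pos))
    if restrain_backbone:
        k_bead[:R] = params.restraint_k
        k_bead[R:] = params.side_restraint_k

    def objective():
        from .energetics import folding_energy_and_gradient
        total, terms, grad = folding_energy_and_gradient(system, params)
        dr = system.pos - targets
        obj = total + float(np.sum(k_bead * np.sum(dr * dr, axis=1)))
        grad = grad.copy()
        grad += 2.0 * k_bead[:, None] * dr
        return obj, total, grad

    if method == "lbfgs":
        return _relax_lbfgs(structure, system, objective, max_steps,
                            tolerance)
    if method != "descent":
        raise ValueError("method must be 'descent' or 'lbfgs'")

    obj, fold, grad = objective()
    obj_series = [obj]
    fold_series = [fold]
    alpha = 0.05
    steps = 0
    converged = False
    for _ in range(max_steps):
        steps += 1
        gmax = np.abs(grad).max()
        if gmax < 1e-12:
            obj_series.append(obj)
            fold_series.append(fold)
        else:
            direction = -grad / gmax  # max displacement = alpha per step
            moved = False
            a = alpha
            for _try in range(25):
                trial = system.pos + a * direction
                saved = system.pos
                system.pos = trial
                try:
                    t_obj, t_fold, t_grad = objective()
                except Exception:
                    system.pos = saved
                    a *= 0.5
                    continue
                if t_obj <= obj + 1e-12:
                    obj, fold, grad = t_obj, t_fold, t_grad
                    alpha = min(a * 1.25, 0.5)
                    moved = True
                    break
                system.pos = saved
                a *= 0.5
            if not moved:
                alpha = max(alpha * 0.5, 1e-8)
            obj_series.append(obj)
            fold_series.append(fold)
        if len(obj_series) >= 10:
            tail = obj_series[-10:]
            if max(tail) - min(tail) < tolerance:
                converged = True
                break

    final = structure.copy()
    final.bb_pos = system.pos[:R].copy()
    sc = final.sc_pos.copy()
    sc[system.has_sc] = system.pos[R:]
    final.sc_pos = sc
    ntail = min(10, steps) if steps > 0 else 1
    return RelaxationResult(
        final=final,
        tail_energies=np.array(fold_series[-ntail:]),
        converged=converged,
        steps_used=steps,
        energy_series=np.array(fold_series),
    )


def _relax_lbfgs(structure: CGStructure, system, objective,
                 max_steps: int, tolerance: float) -> RelaxationResult:
    from scipy.optimize import minimize
    from .energetics import EnergyError

    R = system.n_res
    shape = system.pos.shape
    last_fold = [np.inf]
    fold_series: list[float] = []

    def fun(x):
        system.pos = x.reshape(shape)
        try:
            obj, fold, grad = objective()
        except EnergyError:
            return np.inf, np.zeros(x.shape)
        last_fold[0] = fold
        return obj, grad.ravel()

    def cb(xk):
        fold_series.append(last_fold[0])

    res = minimize(fun, system.pos.ravel(), jac=True, method="L-BFGS-B",
                   callback=cb,
                   options={"maxiter": max_steps, "ftol": 1e-10,
                            "gtol": 1e-4})
    system.pos = res.x.reshape(shape)
    obj, fold, _ = objective()
    fold_series.append(fold)
    steps = max(len(fold_series), 1)
    tail = np.array(fold_series[-min(10, steps):])
    converged = bool(res.success) or \
        (len(tail) >= 2 and tail.max() - tail.min() < tolerance)
    final = structure.copy()
    final.bb_pos = system.pos[:R].copy()
    sc = final.sc_pos.copy()
    sc[system.has_sc] = system.pos[R:]
    final.sc_pos = sc
    return RelaxationResult(final=final, tail_energies=tail,
                            converged=converged, steps_used=steps,
                            energy_series=np.array(fold_series))
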