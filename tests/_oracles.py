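"""Independent plain-loop oracles used across the test suite.

Everything here is written as scalar Python loops, deliberately sharing no
code with the vectorised kernels it checks.
"""

from __future__ import annotations

import math

import numpy as np

from gpcrland.cg_model import (
    SIDE_RADIUS, BACKBONE_RADIUS, BACKBONE_DEPTH, HYDROPHOBIC, POLAR,
    side_chain_depth,
)

KB = 0.0019872
COULOMB_K = 332.0


def _smoothstep(t):
    t = min(max(t, 0.0), 1.0)
    return t * t * (3.0 - 2.0 * t)


def _switch(r, params):
    if r <= params.cutoff_on:
        return 1.0
    if r >= params.cutoff:
        return 0.0
    return _smoothstep((params.cutoff - r) / (params.cutoff - params.cutoff_on))


def _burial_kernel(r, params):
    if r <= params.burial_on:
        return 1.0
    if r >= params.burial_off:
        return 0.0
    return _smoothstep((params.burial_off - r)
                       / (params.burial_off - params.burial_on))


def _hb_window(r, params):
    a, b, c, d = params.hb_window
    return _smoothstep((r - a) / (b - a)) * _smoothstep((d - r) / (d - c))


def _vdw86(r, r0, eps):
    x = r0 / r
    return eps * (3.0 * x ** 8 - 4.0 * x ** 6)


def _beads(structure, charges, params):
    """Flat bead list mirroring the two-bead mapping, as plain tuples:
    (pos, is_bb, res_index, radius, depth, charge, restype)."""
    beads = []
    R = structure.n_residues
    for i in range(R):
        q_bb = params.backbone_charge * (1.0 if i % 2 == 0 else -1.0)
        beads.append((np.array(structure.bb_pos[i]), True, i,
                      BACKBONE_RADIUS, BACKBONE_DEPTH, q_bb,
                      str(structure.restype[i])))
    for i in range(R):
        if structure.has_sc[i]:
            t = str(structure.restype[i])
            q = float(charges[i]) if charges is not None else 0.0
            beads.append((np.array(structure.sc_pos[i]), False, i,
                          SIDE_RADIUS[t], side_chain_depth(t), q, t))
    return beads


def energy_terms_oracle(structure, charges=None, membrane=None, params=None):
    """All eight folding-energy terms by brute-force double loops."""
    from gpcrland.energetics import EnergyParams
    params = params or EnergyParams()
    beads = _beads(structure, charges, params)
    n = len(beads)

    if membrane is not None:
        env = [int(membrane.environment(np.array([b[0][2]]),
                                        params.interface_halfwidth)[0])
               for b in beads]
        mem_pts = [np.array(p) for p in membrane.particles]
    else:
        env = [0] * n
        mem_pts = []

    terms = {k: 0.0 for k in ("side_vdw", "main_solv", "main_hb", "side_elec",
                              "side_polar", "side_hyd", "main_side_elec",
                              "main_side_vdw")}

    burial = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if beads[i][2] == beads[j][2]:
                continue
            r = float(np.linalg.norm(beads[i][0] - beads[j][0]))
            ri, rj = beads[i][2], beads[j][2]
            seq_local = (str(structure.chain[ri]) == str(structure.chain[rj])
                         and abs(int(structure.resnum[ri])
                                 - int(structure.resnum[rj]))
                         <= params.burial_seq_exclusion)
            if r < params.burial_off and not seq_local:
                k = _burial_kernel(r, params)
                burial[i] += k
                burial[j] += k
            if r >= params.cutoff:
                continue
            sw = _switch(r, params)
            bb_i, bb_j = beads[i][1], beads[j][1]
            # van der Waals
            if not (bb_i and bb_j):
                e = _vdw86(r, beads[i][3] + beads[j][3],
                           math.sqrt(beads[i][4] * beads[j][4])) * sw
                if not bb_i and not bb_j:
                    terms["side_vdw"] += e
                else:
                    terms["main_side_vdw"] += e
            # electrostatics
            qq = beads[i][5] * beads[j][5]
            if abs(qq) > 1e-12:
                f = params.membrane_eps_factor \
                    if (env[i] == 2 and env[j] == 2) else 1.0
                e = COULOMB_K * qq / (params.eps_slope * f * r * r) * sw
                if not bb_i and not bb_j:
                    terms["side_elec"] += e
                elif bb_i != bb_j:
                    terms["main_side_elec"] += e

    # hydrogen bonds: i,i+4 backbone within a chain, contiguous numbering
    R = structure.n_residues
    for i in range(R - 4):
        j = i + 4
        if structure.chain[i] == structure.chain[j] and \
                structure.resnum[j] - structure.resnum[i] == 4:
            r = float(np.linalg.norm(structure.bb_pos[i] - structure.bb_pos[j]))
            terms["main_hb"] -= params.e_hb * _hb_window(r, params)

    # burial-driven terms
    for i in range(n):
        B = 1.0 - math.exp(-burial[i] / params.burial_nsat)
        t = beads[i][6]
        if beads[i][1]:
            w = 1.0 if env[i] == 0 else (-1.0 if env[i] == 2 else 0.0)
            terms["main_solv"] += params.w_solv * w * B
        else:
            if t in POLAR:
                terms["side_polar"] += params.w_polar * \
                    (2.0 if env[i] == 2 else 1.0) * B
            if t in HYDROPHOBIC:
                if env[i] == 2:
                    terms["side_hyd"] -= params.w_hyd * (1.0 - B)
                else:
                    terms["side_hyd"] -= params.w_hyd * B

    # membrane lattice exclusion
    for i in range(n):
        for p in mem_pts:
            r = float(np.linalg.norm(beads[i][0] - p))
            r0 = beads[i][3] + params.mem_radius
            if r < r0:
                eps = math.sqrt(beads[i][4] * params.mem_depth)
                e = _vdw86(r, r0, eps) + eps
                if beads[i][1]:
                    terms["main_side_vdw"] += e
                else:
                    terms["side_vdw"] += e
    return terms


def weighted_total_oracle(terms, c1=0.10, c2=0.25, c3=0.15):
    return (c1 * terms["side_vdw"] + c2 * terms["main_solv"]
            + c3 * terms["main_hb"] + terms["side_elec"]
            + terms["side_polar"] + terms["side_hyd"]
            + terms["main_side_elec"] + terms["main_side_vdw"])


# --- path-search oracles -----------------------------------------------------

def enumerate_simple_path_minimax(grid, start, end):
    """Exhaustive DFS over all simple 8-connected paths; returns the true
    minimax barrier max(E along best path) - E[start]."""
    n1, n2 = grid.shape
    best = [math.inf]

    def neighbours(i, j):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < n1 and 0 <= b < n2:
                    yield a, b

    def dfs(node, visited, high):
        if high >= best[0]:
            return
        if node == end:
            best[0] = min(best[0], high)
            return
        for nb in neighbours(*node):
            if nb in visited:
                continue
            dfs(nb, visited | {nb}, max(high, grid[nb]))

    dfs(start, {start}, grid[start])
    return best[0] - grid[start]


def threshold_minimax(grid, start, end):
    """Independent minimax oracle: the smallest energy level t such that
    start and end are connected within cells of energy <= t (union-find)."""
    n1, n2 = grid.shape
    levels = sorted({float(grid[i, j]) for i in range(n1) for j in range(n2)})
    for t in levels:
        if grid[start] > t or grid[end] > t:
            continue
        # BFS on the subgraph of cells <= t
        seen = {start}
        stack = [start]
        while stack:
            i, j = stack.pop()
            if (i, j) == end:
                return t - grid[start]
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < n1 and 0 <= b < n2 and (a, b) not in seen \
                            and grid[a, b] <= t:
                        seen.add((a, b))
                        stack.append((a, b))
    raise AssertionError("endpoints never connected")


def two_sided_oracle(energies):
    """Plain-loop two-sided-barrier segmentation at the earliest global
    interior minimum."""
    e = list(map(float, energies))
    gmin = min(e)
    m = e.index(gmin)
    if m == 0 or m == len(e) - 1:
        return None
    b1 = max(e[: m + 1]) - e[0]
    b2 = max(e[m:]) - e[m]
    return b1, b2, m
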