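"""1D activation profiles, 2D coupled-coordinate maps and barrier extraction.

Profiles are reported relative to their first point.  The "least energy
pathway" across a 2D map is the path minimising the highest energy
encountered (minimax / bottleneck criterion) over 8-connected grid moves —
every quantity the analysis reports is a barrier, so the bottleneck is the
natural optimality notion; a path-sum criterion is available behind a flag.
Two-sided barriers segment a path at its stable intermediate (the global
interior minimum) and report the climb on each side.
"""

from __future__ import annotations

import heapq
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Landscape1D", "Landscape2D", "Pathway", "profile_1d", "barrier",
    "two_sided_barriers", "TwoSidedBarriers", "build_grid_2d",
    "least_energy_path", "compare_pathways", "fixed_row_path",
]


@dataclass
class Landscape1D:
    coordinates: np.ndarray
    energies: np.ndarray          # kcal/mol, relative to the first point
    errors: np.ndarray = None     # SD per point
    labels: list = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.errors is None:
            self.errors = np.zeros_like(self.energies)
        self.errors = np.asarray(self.errors, dtype=float)
        n = len(self.coordinates)
        if len(self.energies) != n or len(self.errors) != n:
            raise ValueError("coordinate/energy/error length mismatch")
        if n >= 2 and not np.all(np.diff(self.coordinates) > 0):
            raise ValueError("coordinates must be strictly increasing")

    def to_table(self) -> str:
        df = pd.DataFrame({"coordinate": self.coordinates,
                           "energy": self.energies, "sd": self.errors})
        if self.labels is not None:
            df["label"] = self.labels
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False, float_format="%.6f")
        return buf.getvalue()


@dataclass
class Landscape2D:
    axis1: np.ndarray             # conformational coordinate (rows)
    axis2: np.ndarray             # second coordinate (columns)
    energies: np.ndarray          # (|axis1|, |axis2|) kcal/mol

    def __post_init__(self):
        self.axis1 = np.asarray(self.axis1)
        self.axis2 = np.asarray(self.axis2)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (len(self.axis1), len(self.axis2)):
            raise ValueError("grid shape does not match axes")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("grid contains non-finite energies")

    def to_table(self) -> str:
        df = pd.DataFrame(self.energies, index=self.axis1, columns=self.axis2)
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", float_format="%.6f")
        return buf.getvalue()


@dataclass
class Pathway:
    nodes: list                   # ordered (i, j) grid indices
    energies: np.ndarray          # grid energies along the path
    barrier: float                # max(E) - E[start]
    barrier1: float = None        # two-sided, when an interior minimum exists
    barrier2: float = None
    has_interior_minimum: bool = False

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.nodes) != len(self.energies):
            raise ValueError("nodes/energies length mismatch")

    def to_table(self) -> str:
        df = pd.DataFrame({"i": [n[0] for n in self.nodes],
                           "j": [n[1] for n in self.nodes],
                           "energy": self.energies})
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False, float_format="%.6f")
        return buf.getvalue()


# --- 1D ----------------------------------------------------------------------

def profile_1d(coordinates, energies, errors=None, labels=None) -> Landscape1D:
    """Build a relative 1D profile: energies shifted so the first point is 0.

    ``coordinates`` may be a morphing Trajectory (its coordinate is used) or
    an array of reaction-coordinate values."""
    coords = getattr(coordinates, "coordinate", coordinates)
    coords = np.asarray(coords, dtype=float)
    energies = np.asarray(energies, dtype=float)
    if len(coords) != len(energies):
        raise ValueError("one energy per frame required")
    return Landscape1D(coords, energies - energies[0], errors, labels)


def barrier(profile) -> float:
    """Activation barrier: max over points of E_i - E_start (>= 0)."""
    e = profile.energies if isinstance(profile, Landscape1D) \
        else np.asarray(profile, dtype=float)
    if e.size == 0:
        raise ValueError("empty profile")
    return float(np.max(e - e[0]))


@dataclass
class TwoSidedBarriers:
    barrier1: float
    barrier2: float | None
    min_index: int
    has_interior_minimum: bool


def two_sided_barriers(path_energies) -> TwoSidedBarriers:
    """Segment a path at its stable intermediate (the global minimum strictly
    between the endpoints; earliest if tied) and report the barrier on each
    side: barrier1 = max(E[start..min]) - E[start], barrier2 =
    max(E[min..end]) - E[min].

    If the global minimum sits at an endpoint there is no interior
    intermediate; the single overall barrier is returned flagged."""
    e = np.asarray(getattr(path_energies, "energies", path_energies),
                   dtype=float)
    if len(e) < 3:
        raise ValueError("need at least 3 points for two-sided barriers")
    m = int(np.argmin(e))  # earliest global minimum
    if m == 0 or m == len(e) - 1:
        return TwoSidedBarriers(float(np.max(e) - e[0]), None, m, False)
    b1 = float(np.max(e[:m + 1]) - e[0])
    b2 = float(np.max(e[m:]) - e[m])
    return TwoSidedBarriers(b1, b2, m, True)


# --- 2D ----------------------------------------------------------------------

def build_grid_2d(axis1_states, axis2_states, energy_fn) -> Landscape2D:
    """Dense energy grid over the outer product of two state series.

    ``energy_fn(state1, state2)`` must return a finite energy for every cell;
    a failure is re-raised naming the offending cell."""
    n1, n2 = len(axis1_states), len(axis2_states)
    grid = np.empty((n1, n2))
    for i, s1 in enumerate(axis1_states):
        for j, s2 in enumerate(axis2_states):
            try:
                grid[i, j] = energy_fn(s1, s2)
            except Exception as exc:
                raise RuntimeError(f"energy evaluation failed at cell "
                                   f"({i}, {j}): {exc}") from exc
            if not np.isfinite(grid[i, j]):
                raise RuntimeError(f"non-finite energy at cell ({i}, {j})")
    return Landscape2D(np.arange(n1), np.arange(n2), grid)


def _neighbors(i, j, n1, n2, connectivity):
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]
    elif connectivity == 4:
        steps = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    for di, dj in steps:
        a, b = i + di, j + dj
        if 0 <= a < n1 and 0 <= b < n2:
            yield a, b


def least_energy_path(grid: Landscape2D, start, end, *,
                      criterion: str = "minimax",
                      connectivity: int = 8) -> Pathway:
    """Least-energy pathway between two grid cells.

    ``criterion='minimax'`` (default) minimises the highest energy met along
    the path; ties are broken by smaller path-sum, then lexicographic node
    order.  ``criterion='sum'`` minimises the plain path sum.  Moves are
    8-connected by default and may back-track (monotone progress is not
    enforced).
    """
    e = grid.energies
    n1, n2 = e.shape
    start, end = tuple(start), tuple(end)
    for node in (start, end):
        if not (0 <= node[0] < n1 and 0 <= node[1] < n2):
            raise IndexError(f"grid index {node} out of range")
    if start == end:
        raise ValueError("start and end must differ")

    # the cumulative component must be non-negative or revisiting a
    # favourable cell would improve a path without bound; shifting by the
    # grid minimum preserves the ordering of same-length paths and makes
    # longer detours strictly more expensive
    shift = float(e.min())
    if criterion == "minimax":
        init = (float(e[start]), float(e[start]) - shift)
    elif criterion == "sum":
        init = (float(e[start]) - shift,)
    else:
        raise ValueError("criterion must be 'minimax' or 'sum'")

    best: dict[tuple, tuple] = {start: init}
    parent: dict[tuple, tuple | None] = {start: None}
    heap = [(init, start)]
    while heap:
        cost, node = heapq.heappop(heap)
        if cost != best.get(node):
            continue
        if node == end:
            break
        for nb in _neighbors(*node, n1, n2, connectivity):
            ev = float(e[nb])
            if criterion == "minimax":
                cand = (max(cost[0], ev), cost[1] + ev - shift)
            else:
                cand = (cost[0] + ev - shift,)
            known = best.get(nb)
            if known is None or cand < known:
                best[nb] = cand
                parent[nb] = node
                heapq.heappush(heap, (cand, nb))

    path = []
    node = end
    while node is not None:
        path.append(node)
        node = parent[node]
    path.reverse()
    if path[0] != start:
        raise RuntimeError("end cell unreachable")  # cannot happen on a grid
    energies = np.array([e[n] for n in path])
    ts = two_sided_barriers(energies) if len(energies) >= 3 else None
    return Pathway(
        nodes=path, energies=energies,
        barrier=float(np.max(energies) - energies[0]),
        barrier1=None if ts is None else ts.barrier1,
        barrier2=None if ts is None else ts.barrier2,
        has_interior_minimum=False if ts is None else ts.has_interior_minimum,
    )


def fixed_row_path(grid: Landscape2D, row_or_col_index: int, *,
                   axis: int = 1) -> Pathway:
    """The straight path holding one coordinate fixed (e.g. the partner held
    at its far distance while the conformation changes)."""
    e = grid.energies
    if axis == 1:  # fixed column: walk down axis1
        nodes = [(i, row_or_col_index) for i in range(e.shape[0])]
    else:
        nodes = [(row_or_col_index, j) for j in range(e.shape[1])]
    energies = np.array([e[n] for n in nodes])
    ts = two_sided_barriers(energies) if len(energies) >= 3 else None
    return Pathway(nodes, energies,
                   float(np.max(energies) - energies[0]),
                   None if ts is None else ts.barrier1,
                   None if ts is None else ts.barrier2,
                   False if ts is None else ts.has_interior_minimum)


def _validate_path(grid: Landscape2D, path: Pathway) -> None:
    n1, n2 = grid.energies.shape
    for (i, j) in path.nodes:
        if not (0 <= i < n1 and 0 <= j < n2):
            raise ValueError(f"path node ({i}, {j}) not on grid")
    for a, b in zip(path.nodes, path.nodes[1:]):
        if max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 1:
            raise ValueError(f"path nodes {a} -> {b} are not grid neighbours")


def compare_pathways(grid: Landscape2D, path_a: Pathway,
                     path_b: Pathway) -> float:
    """barrier(path_a) - barrier(path_b), each relative to its own start."""
    _validate_path(grid, path_a)
    _validate_path(grid, path_b)
    ea = np.array([grid.energies[n] for n in path_a.nodes])
    eb = np.array([grid.energies[n] for n in path_b.nodes])
    return float((np.max(ea) - ea[0]) - (np.max(eb) - eb[0]))
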