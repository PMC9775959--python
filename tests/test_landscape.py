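import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpcrland import (
    profile_1d, barrier, two_sided_barriers, build_grid_2d,
    least_energy_path, compare_pathways, fixed_row_path,
)
from gpcrland.landscape import Landscape1D, Landscape2D

from _oracles import (
    enumerate_simple_path_minimax, threshold_minimax, two_sided_oracle,
)


class TestProfile:
    def test_shift_to_first_point(self):
        p = profile_1d([0.0, 0.5, 1.0], [3.0, 5.0, 4.0])
        assert np.allclose(p.energies, [0.0, 2.0, 1.0])

    def test_constant_profile_is_zero(self):
        p = profile_1d([0, 0.5, 1], [7.0, 7.0, 7.0])
        assert np.allclose(p.energies, 0.0)

    def test_offset_invariance(self):
        e = np.array([1.0, -2.0, 4.0, 0.5])
        c = np.linspace(0, 1, 4)
        assert np.allclose(profile_1d(c, e).energies,
                           profile_1d(c, e + 100.0).energies)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            profile_1d([0, 1], [1.0, 2.0, 3.0])


class TestBarrier:
    def test_definition_example(self):
        assert barrier(np.array([0, 3.2, 1.1, 4.7, 2.0])) == 4.7

    def test_monotone_decreasing_gives_zero(self):
        assert barrier(np.array([5.0, 4.0, 1.0])) == 0.0

    def test_matches_plain_loop_oracle(self, rng):
        for _ in range(50):
            e = rng.normal(size=rng.integers(2, 30))
            expected = max(x - e[0] for x in e)
            assert barrier(e) == pytest.approx(expected, abs=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            barrier(np.array([]))


class TestTwoSidedBarriers:
    def test_worked_example(self):
        ts = two_sided_barriers([0, 4, -2, 5, 1])
        assert ts.has_interior_minimum and ts.min_index == 2
        assert ts.barrier1 == 4 and ts.barrier2 == 7

    def test_symmetric_well(self):
        ts = two_sided_barriers([0, 3, -1, 3, 0])
        assert (ts.barrier1, ts.barrier2) == (3, 4)

    def test_minimum_at_endpoint_is_flagged(self):
        ts = two_sided_barriers([0, 2, 3, -1])
        assert not ts.has_interior_minimum
        assert ts.barrier2 is None
        assert ts.barrier1 == 3.0

    def test_matches_segmentation_oracle(self, rng):
        for _ in range(60):
            e = rng.normal(size=rng.integers(3, 40))
            ts = two_sided_barriers(e)
            oracle = two_sided_oracle(e)
            if oracle is None:
                assert not ts.has_interior_minimum
            else:
                assert ts.has_interior_minimum
                assert ts.barrier1 == pytest.approx(oracle[0], abs=1e-12)
                assert ts.barrier2 == pytest.approx(oracle[1], abs=1e-12)
                assert ts.min_index == oracle[2]


class TestBuildGrid:
    def test_constant_energy_fn(self):
        g = build_grid_2d([0, 1], [0, 1], lambda a, b: 3.5)
        assert np.all(g.energies == 3.5)

    def test_symmetric_energy_fn_gives_symmetric_grid(self):
        states = [0.0, 1.0, 2.5, 4.0]
        g = build_grid_2d(states, states, lambda a, b: (a - b) ** 2 + a + b)
        assert np.allclose(g.energies, g.energies.T, atol=1e-12)

    def test_failure_names_cell(self):
        def fn(a, b):
            if (a, b) == (1, 0):
                raise ValueError("boom")
            return 0.0
        with pytest.raises(RuntimeError, match=r"\(1, 0\)"):
            build_grid_2d([0, 1], [0, 1], fn)


class TestLeastEnergyPath:
    def test_degenerate_single_row(self, rng):
        e = rng.normal(size=(1, 8))
        grid = Landscape2D(np.arange(1), np.arange(8), e)
        path = least_energy_path(grid, (0, 0), (0, 7))
        assert path.nodes == [(0, j) for j in range(8)]
        assert path.barrier == pytest.approx(barrier(e[0]), abs=1e-12)

    def test_low_channel_is_followed(self):
        e = np.full((5, 5), 10.0)
        e[:, 0] = [0, 1, 1, 1, 1]     # cheap channel along the first column
        e[4, :] = 1.0
        grid = Landscape2D(np.arange(5), np.arange(5), e)
        path = least_energy_path(grid, (0, 0), (4, 4))
        assert all(j == 0 or i == 4 for i, j in path.nodes)
        assert path.barrier == pytest.approx(1.0)

    def test_minimax_equals_exhaustive_enumeration(self, rng):
        for _ in range(40):
            e = rng.integers(0, 3, size=(3, 3)).astype(float)
            grid = Landscape2D(np.arange(3), np.arange(3), e)
            path = least_energy_path(grid, (0, 0), (2, 2))
            expected = enumerate_simple_path_minimax(e, (0, 0), (2, 2))
            assert path.barrier == pytest.approx(expected, abs=1e-12)

    def test_negative_energies_terminate_and_match_oracle(self, rng):
        e = rng.normal(size=(6, 6)) - 5.0
        grid = Landscape2D(np.arange(6), np.arange(6), e)
        path = least_energy_path(grid, (0, 0), (5, 5))
        assert path.barrier == pytest.approx(
            threshold_minimax(e, (0, 0), (5, 5)), abs=1e-9)

    def test_deterministic_tie_breaking(self):
        e = np.zeros((4, 4))
        grid = Landscape2D(np.arange(4), np.arange(4), e)
        p1 = least_energy_path(grid, (0, 0), (3, 3))
        p2 = least_energy_path(grid, (0, 0), (3, 3))
        assert p1.nodes == p2.nodes

    def test_sum_criterion_prefers_short_cheap_route(self):
        e = np.array([[0.0, 100.0], [0.0, 0.0]])
        grid = Landscape2D(np.arange(2), np.arange(2), e)
        p = least_energy_path(grid, (0, 0), (1, 1), criterion="sum")
        assert (0, 1) not in p.nodes

    def test_bad_inputs(self):
        grid = Landscape2D(np.arange(2), np.arange(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            least_energy_path(grid, (0, 0), (0, 0))
        with pytest.raises(IndexError):
            least_energy_path(grid, (0, 0), (5, 5))


class TestPathProperties:
    def test_barrier_invariant_under_constant_shift(self, rng):
        e = rng.normal(size=(5, 5))
        g1 = Landscape2D(np.arange(5), np.arange(5), e)
        g2 = Landscape2D(np.arange(5), np.arange(5), e + 42.0)
        p1 = least_energy_path(g1, (0, 0), (4, 4))
        p2 = least_energy_path(g2, (0, 0), (4, 4))
        assert p1.barrier == pytest.approx(p2.barrier, abs=1e-9)

    def test_minimax_beats_every_simple_path_on_small_grids(self, rng):
        for _ in range(10):
            e = rng.integers(0, 4, size=(4, 4)).astype(float)
            grid = Landscape2D(np.arange(4), np.arange(4), e)
            best = least_energy_path(grid, (0, 0), (3, 3)).barrier
            assert best == pytest.approx(
                threshold_minimax(e, (0, 0), (3, 3)), abs=1e-12)

    def test_separable_grid_coupling_helps(self, rng):
        # E(i,j) = f(i) + g(j), g minimised at the last column: the coupled
        # path cannot beat... must do no worse than the fixed-start-column
        f = rng.normal(size=6)
        g = np.sort(rng.normal(size=5))[::-1]   # minimum at the end column
        e = f[:, None] + g[None, :]
        grid = Landscape2D(np.arange(6), np.arange(5), e)
        coupled = least_energy_path(grid, (0, 0), (5, 4))
        fixed = fixed_row_path(grid, 0, axis=1)
        assert coupled.barrier <= fixed.barrier + 1e-9

    def test_transposed_symmetric_grid_same_barrier(self, rng):
        e = rng.normal(size=(5, 5))
        e = (e + e.T) / 2
        grid = Landscape2D(np.arange(5), np.arange(5), e)
        gridT = Landscape2D(np.arange(5), np.arange(5), e.T)
        p = least_energy_path(grid, (0, 0), (4, 4))
        pT = least_energy_path(gridT, (0, 0), (4, 4))
        assert p.barrier == pytest.approx(pT.barrier, abs=1e-12)


class TestComparePathways:
    def test_identical_paths_give_zero(self, rng):
        e = rng.normal(size=(4, 4))
        grid = Landscape2D(np.arange(4), np.arange(4), e)
        p = least_energy_path(grid, (0, 0), (3, 3))
        assert compare_pathways(grid, p, p) == 0.0

    def test_minimax_never_worse_than_alternative(self, rng):
        for _ in range(10):
            e = rng.normal(size=(4, 4))
            grid = Landscape2D(np.arange(4), np.arange(4), e)
            best = least_energy_path(grid, (0, 0), (3, 3))
            alt = least_energy_path(grid, (0, 0), (3, 3), criterion="sum")
            assert compare_pathways(grid, best, alt) <= 1e-12

    def test_off_grid_path_rejected(self, rng):
        e = rng.normal(size=(3, 3))
        grid = Landscape2D(np.arange(3), np.arange(3), e)
        p = least_energy_path(grid, (0, 0), (2, 2))
        small = Landscape2D(np.arange(2), np.arange(2), e[:2, :2])
        with pytest.raises(ValueError):
            compare_pathways(small, p, p)
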