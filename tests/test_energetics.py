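import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpcrland import (
    EnergyParams, Membrane, build_membrane, combine_terms,
    folding_free_energy, energy_with_error, TERM_NAMES, BundleSpec,
    make_bundle, coarse_grain, greedy_proton_descent, MCPTParams,
)
from gpcrland.cg_model import CGStructure
from gpcrland.energetics import EnergyError, build_bead_system, _evaluate
from gpcrland.morphing import RelaxationResult

from _oracles import energy_terms_oracle, weighted_total_oracle


def _toy(restypes, bb, sc=None):
    n = len(restypes)
    bb = np.asarray(bb, dtype=float)
    sc = bb + np.array([2.0, 0, 0]) if sc is None else np.asarray(sc, float)
    return CGStructure(np.full(n, "A"), np.arange(1, n + 1), np.full(n, ""),
                       np.array(list(restypes)), bb, sc)


class TestCombineTerms:
    def test_unit_terms_reference_value(self):
        # c1 + c2 + c3 + five unweighted terms = 0.10 + 0.25 + 0.15 + 5
        terms = {n: 1.0 for n in TERM_NAMES}
        assert combine_terms(terms) == pytest.approx(5.50, abs=1e-12)

    def test_zero_terms(self):
        assert combine_terms({n: 0.0 for n in TERM_NAMES}) == 0.0

    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_matches_hand_weighted_sum(self, vals):
        terms = dict(zip(TERM_NAMES, vals))
        assert combine_terms(terms) == pytest.approx(
            weighted_total_oracle(terms), abs=1e-12)

    def test_missing_term_errors(self):
        with pytest.raises(ValueError, match="missing"):
            combine_terms({"side_vdw": 1.0})


class TestMembrane:
    def test_all_beads_in_slab(self):
        s = _toy("AL", [[0, 0, 0], [4, 0, 0]])
        mem = build_membrane(s, 15.0, with_particles=False)
        assert mem.z_low == pytest.approx(-15) and \
            mem.z_high == pytest.approx(15)
        assert all(mem.environment(np.array([0.0])) == 2)

    def test_far_bead_is_water(self):
        s = _toy("AL", [[0, 0, 0], [4, 0, 0]])
        mem = build_membrane(s, 15.0, with_particles=False)
        assert mem.environment(np.array([40.0]))[0] == 0

    def test_lattice_count_matches_enumeration(self):
        spec = BundleSpec(n_helices=3, helix_length=12, radius=7.5, seed=5)
        cg = coarse_grain(make_bundle(spec))
        params = EnergyParams()
        mem = build_membrane(cg, 15.0, params)
        # direct enumeration: hex nodes inside the slab minus those within
        # the exclusion radius of any bead
        beads = np.vstack([cg.bb_pos, cg.sc_pos[cg.has_sc]])
        s, m = params.mem_spacing, params.mem_margin
        zc = cg.bb_pos[:, 2].mean()
        x0, y0 = beads[:, 0].mean(), beads[:, 1].mean()
        nx = int(np.ceil(((beads[:, 0].max() - beads[:, 0].min()) / 2 + m) / s)) + 1
        ny = int(np.ceil(((beads[:, 1].max() - beads[:, 1].min()) / 2 + m)
                         / (s * np.sqrt(3) / 2))) + 1
        count = 0
        for k in range(-ny, ny + 1):
            y = y0 + k * s * np.sqrt(3) / 2
            offs = 0.5 if (k % 2) else 0.0
            for mx in range(-nx, nx + 1):
                x = x0 + (mx + offs) * s
                z = zc - 15.0 + s / 2
                while z < zc + 15.0:
                    d = np.sqrt(((beads - [x, y, z]) ** 2).sum(axis=1)).min()
                    if d >= params.mem_exclusion:
                        count += 1
                    z += s
        assert len(mem.particles) == count

    def test_empty_slab_warns(self):
        # beads split far above and below the slab: none inside
        s = _toy("AL", [[0, 0, -100], [4, 0, 100]])
        with pytest.warns(UserWarning):
            built = build_membrane(s, 2.0)
        assert len(built.particles) == 0


class TestTerms:
    def test_zero_charges_no_electrostatics(self, small_bundle):
        bd = folding_free_energy(small_bundle)
        assert bd.side_elec == 0.0
        assert bd.main_side_elec == 0.0

    def test_contact_pair_at_well_depth(self):
        # two leucine side beads exactly at their contact distance r0
        from gpcrland.cg_model import SIDE_RADIUS, side_chain_depth
        r0 = 2 * SIDE_RADIUS["L"]
        eps = side_chain_depth("L")
        bb = [[0, 0, 0], [r0, 0, 50.0]]
        sc = [[0, 3, 0], [r0, 3, 50.0]]
        s = _toy("LL", bb, sc)
        s.sc_pos = np.array([[0.0, 3, 0], [r0, 3, 0]])
        s.bb_pos = np.array([[0.0, -50, 0], [r0, -50, 0]])
        bd = folding_free_energy(s)
        assert bd.side_vdw == pytest.approx(-eps, abs=1e-9)

    def test_single_glycine_has_no_sidechain_terms(self):
        s = CGStructure(np.array(["A"]), np.array([1]), np.array([""]),
                        np.array(["G"]), np.zeros((1, 3)),
                        np.full((1, 3), np.nan), np.array([False]))
        bd = folding_free_energy(s)
        for t in ("side_vdw", "side_elec", "side_polar", "side_hyd",
                  "main_side_elec", "main_side_vdw"):
            assert getattr(bd, t) == 0.0

    def test_deterministic_bit_for_bit(self, small_bundle):
        mem = build_membrane(small_bundle, 15.0)
        a = folding_free_energy(small_bundle, membrane=mem).as_dict()
        b = folding_free_energy(small_bundle, membrane=mem).as_dict()
        assert a == b

    def test_hydrophobic_helix_prefers_membrane(self):
        # well-separated helices: side chains face lipid, not each other
        spec = BundleSpec(n_helices=2, helix_length=12, radius=30.0, seed=2,
                          lock_acid_helix=None, ionizable_fraction=0.0)
        cg = coarse_grain(make_bundle(spec))
        in_mem = build_membrane(cg, 15.0, with_particles=False)
        bd_mem = folding_free_energy(cg, membrane=in_mem)
        bd_wat = folding_free_energy(cg)
        assert bd_mem.side_hyd < bd_wat.side_hyd

    def test_overlapping_beads_error(self):
        s = _toy("LL", [[0, 0, 0], [0.05, 0, 0]],
                 [[0, 3, 0], [0.05, 3, 0]])
        with pytest.raises(EnergyError, match="overlap"):
            folding_free_energy(s)


class TestOracleEquivalence:
    """Vectorised kernels vs the plain double-loop reimplementation."""

    def test_all_terms_match_bruteforce(self, small_bundle):
        mem = build_membrane(small_bundle, 15.0)
        state = greedy_proton_descent(small_bundle, MCPTParams(),
                                      membrane=mem)
        charges = state.per_residue_charges(small_bundle)
        bd = folding_free_energy(small_bundle, charges, mem)
        expected = energy_terms_oracle(small_bundle, charges, mem)
        for name in TERM_NAMES:
            assert getattr(bd, name) == pytest.approx(
                expected[name], abs=1e-8), name

    def test_total_is_recombination_of_terms(self, small_bundle):
        bd = folding_free_energy(small_bundle)
        assert bd.total == pytest.approx(combine_terms(bd), abs=1e-9)


class TestRigidInvariance:
    def test_rigid_motion_preserves_all_terms(self, small_bundle):
        from scipy.spatial.transform import Rotation
        mem = build_membrane(small_bundle, 15.0)
        bd0 = folding_free_energy(small_bundle, membrane=mem)
        rot = Rotation.from_euler("z", 35, degrees=True).as_matrix()
        shift = np.array([3.0, -2.0, 0.0])  # in-plane: environments unchanged
        moved = small_bundle.transformed(rotation=rot, translation=shift)
        mem_moved = Membrane(mem.z_low, mem.z_high,
                             mem.particles @ rot.T + shift)
        bd1 = folding_free_energy(moved, membrane=mem_moved)
        for name in TERM_NAMES:
            assert getattr(bd1, name) == pytest.approx(
                getattr(bd0, name), abs=1e-6), name


class TestMutationLocality:
    def test_untouched_terms_are_bitwise_stable(self, small_bundle):
        from gpcrland import mutate_residue
        s = small_bundle
        # polar residue, no charge: electrostatics and backbone terms
        # cannot change
        i = int(np.where((np.isin(s.restype, ["S", "T", "N"])) & s.has_sc)[0][0])
        mut = mutate_residue(s, str(s.chain[i]), int(s.resnum[i]), "L")
        bd0 = folding_free_energy(s)
        bd1 = folding_free_energy(mut)
        assert bd1.main_hb == bd0.main_hb
        assert bd1.main_solv == bd0.main_solv
        assert bd1.side_elec == bd0.side_elec
        assert bd1.main_side_elec == bd0.main_side_elec
        assert bd1.side_polar != bd0.side_polar  # the mutated site moved class


class TestEnergyWithError:
    def test_constant_tail(self):
        r = RelaxationResult(None, np.full(10, 5.0), True, 10)
        assert energy_with_error(r) == (5.0, 0.0)

    def test_linear_tail_population_sd(self):
        r = RelaxationResult(None, np.arange(1.0, 11.0), True, 10)
        v, sd = energy_with_error(r)
        assert v == 10.0
        assert sd == pytest.approx(np.std(np.arange(1, 11)), abs=1e-12)

    def test_single_element_tail(self):
        r = RelaxationResult(None, np.array([2.5]), False, 1)
        assert energy_with_error(r) == (2.5, 0.0)

    def test_empty_tail_errors(self):
        r = RelaxationResult(None, np.array([]), False, 0)
        with pytest.raises(ValueError):
            energy_with_error(r)


def test_params_yaml_roundtrip():
    p = EnergyParams(c1=0.2, mem_spacing=4.0)
    q = EnergyParams.from_yaml(p.to_yaml())
    assert q == p
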