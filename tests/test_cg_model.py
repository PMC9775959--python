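import numpy as np
import pytest

from gpcrland import (
    read_structure, write_pdb, trim_to_common, coarse_grain, mutate_residue,
    PDBParseError, write_cg_table, read_cg_table, BundleSpec, make_bundle,
)
from gpcrland.cg_model import AtomRecord


def _atom_line(serial, name, resname, chain, resnum, x, y, z, record="ATOM"):
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {nm:<4s}{resname:>4s} {chain}"
            f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}")


class TestReadStructure:
    def test_single_atom_fields(self):
        pdb = _atom_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0) + "\nEND\n"
        atoms, het = read_structure(pdb)
        assert len(atoms) == 1 and not het
        a = atoms[0]
        assert (a.chain_id, a.residue_number, a.residue_name,
                a.atom_name) == ("A", 1, "ALA", "CA")
        assert np.allclose(a.position, [1.0, 2.0, 3.0])

    def test_first_model_only(self):
        pdb = "\n".join([
            "MODEL        1",
            _atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            "ENDMDL",
            "MODEL        2",
            _atom_line(1, "CA", "GLY", "A", 1, 9, 9, 9),
            "ENDMDL", "END", ""])
        atoms, _ = read_structure(pdb)
        assert len(atoms) == 1
        assert np.allclose(atoms[0].position, [0, 0, 0])

    def test_waters_dropped_hetero_separate(self):
        pdb = "\n".join([
            _atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0),
            _atom_line(2, "O", "HOH", "A", 90, 5, 5, 5, record="HETATM"),
            _atom_line(3, "C1", "LIG", "A", 91, 6, 6, 6, record="HETATM"),
            "END", ""])
        atoms, het = read_structure(pdb)
        assert len(atoms) == 1
        assert len(het) == 1 and het[0].residue_name == "LIG"

    def test_malformed_coordinate_names_line(self):
        good = _atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0)
        bad = good[:30] + "  xx.xxx" + good[38:]
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(good + "\n" + bad + "\n")

    def test_empty_structure_errors(self):
        with pytest.raises(PDBParseError):
            read_structure("REMARK nothing here\nEND\n")

    def test_bundle_roundtrip_exact(self):
        atoms = make_bundle(BundleSpec(n_helices=3, helix_length=10,
                                       radius=7.5, seed=3))
        back, _ = read_structure(write_pdb(atoms))
        assert len(back) == len(atoms)
        for a, b in zip(atoms, back):
            assert a.residue_number == b.residue_number
            assert a.atom_name == b.atom_name
            # PDB fixed-point format carries 3 decimals
            assert np.allclose(a.position, b.position, atol=5e-4)


class TestTrimToCommon:
    @staticmethod
    def _state(resnums, name="ALA"):
        return [AtomRecord("A", n, name, "CA", np.array([float(n), 0, 0]))
                for n in resnums]

    def test_pairwise_intersection(self):
        a, b = trim_to_common([self._state(range(1, 11)),
                               self._state(range(3, 13))])
        nums = [x.residue_number for x in a]
        assert nums == list(range(3, 11))
        assert nums == [x.residue_number for x in b]

    def test_identical_states_unchanged(self):
        s = self._state(range(1, 6))
        a, b = trim_to_common([s, self._state(range(1, 6))])
        assert [x.residue_number for x in a] == list(range(1, 6))
        assert [x.residue_number for x in b] == list(range(1, 6))

    def test_three_state_matches_set_oracle(self, rng):
        sets = [sorted(rng.choice(40, size=25, replace=False) + 1)
                for _ in range(3)]
        expected = sorted(set(sets[0]) & set(sets[1]) & set(sets[2]))
        trimmed = trim_to_common([self._state(s) for s in sets])
        for st in trimmed:
            assert [x.residue_number for x in st] == expected

    def test_residue_name_conflict(self):
        with pytest.raises(ValueError, match="conflict"):
            trim_to_common([self._state([1, 2], "ALA"),
                            self._state([1, 2], "GLY")])

    def test_disjoint_states(self):
        with pytest.raises(ValueError, match="no residues"):
            trim_to_common([self._state([1]), self._state([2])])


class TestCoarseGrain:
    def test_ala_single_atom_centroid(self):
        atoms = [AtomRecord("A", 1, "ALA", "CA", np.zeros(3)),
                 AtomRecord("A", 1, "ALA", "CB", np.array([1.5, 0, 0]))]
        cg = coarse_grain(atoms)
        assert np.allclose(cg.bb_pos[0], 0)
        assert np.allclose(cg.sc_pos[0], [1.5, 0, 0])

    def test_glycine_backbone_only(self):
        cg = coarse_grain([AtomRecord("A", 1, "GLY", "CA", np.zeros(3))])
        assert cg.n_beads == 1 and not cg.has_sc[0]

    def test_lysine_centroid_and_flag(self):
        side = {"CB": [1, 0, 0], "CG": [2, 0, 0], "CD": [3, 0, 0],
                "CE": [4, 0, 0], "NZ": [5, 0, 0]}
        atoms = [AtomRecord("A", 5, "LYS", "CA", np.zeros(3))]
        atoms += [AtomRecord("A", 5, "LYS", n, np.array(p, dtype=float))
                  for n, p in side.items()]
        cg = coarse_grain(atoms)
        assert np.allclose(cg.sc_pos[0], [3.0, 0, 0])
        assert cg.ionizable[0]

    def test_missing_ca_errors(self):
        with pytest.raises(ValueError, match="CA"):
            coarse_grain([AtomRecord("A", 1, "ALA", "CB", np.zeros(3))])

    def test_sidechain_bead_count(self):
        atoms = make_bundle(BundleSpec(n_helices=3, helix_length=12,
                                       radius=7.5, seed=11))
        cg = coarse_grain(atoms)
        n_gly = int(np.sum(cg.restype == "G"))
        assert cg.n_beads == 2 * cg.n_residues - n_gly


class TestMutateResidue:
    def test_type_swap_keeps_coordinates(self, small_bundle):
        i = int(np.where(small_bundle.restype == "T")[0][0]) \
            if "T" in small_bundle.restype else 0
        chain, num = str(small_bundle.chain[i]), int(small_bundle.resnum[i])
        mut = mutate_residue(small_bundle, chain, num, "A")
        assert mut.restype[i] == "A"
        assert np.allclose(mut.bb_pos, small_bundle.bb_pos)
        valid = small_bundle.has_sc
        assert np.allclose(mut.sc_pos[valid], small_bundle.sc_pos[valid])

    def test_charge_removal_bookkeeping(self, small_bundle):
        ion = np.where(small_bundle.ionizable)[0]
        assert len(ion) > 0
        i = int(ion[0])
        mut = mutate_residue(small_bundle, str(small_bundle.chain[i]),
                             int(small_bundle.resnum[i]), "A")
        assert mut.ionizable.sum() == small_bundle.ionizable.sum() - 1

    def test_roundtrip_restores_structure(self, small_bundle):
        i = 4
        orig = str(small_bundle.restype[i])
        chain, num = str(small_bundle.chain[i]), int(small_bundle.resnum[i])
        back = mutate_residue(mutate_residue(small_bundle, chain, num, "A"),
                              chain, num, orig)
        assert back.sequence() == small_bundle.sequence()
        assert np.allclose(back.sc_pos[back.has_sc],
                           small_bundle.sc_pos[small_bundle.has_sc])

    def test_to_glycine_drops_bead(self, small_bundle):
        i = 2
        mut = mutate_residue(small_bundle, str(small_bundle.chain[i]),
                             int(small_bundle.resnum[i]), "G")
        assert not mut.has_sc[i]
        assert mut.n_beads == small_bundle.n_beads - 1

    def test_unknown_type_errors(self, small_bundle):
        with pytest.raises(ValueError, match="unknown"):
            mutate_residue(small_bundle, str(small_bundle.chain[0]),
                           int(small_bundle.resnum[0]), "X")


def test_cg_table_roundtrip(small_bundle):
    back = read_cg_table(write_cg_table(small_bundle))
    assert back.sequence() == small_bundle.sequence()
    assert np.allclose(back.bb_pos, small_bundle.bb_pos, atol=1e-6)
    assert np.array_equal(back.has_sc, small_bundle.has_sc)
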