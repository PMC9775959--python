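import logging

import numpy as np
import pytest

from gpcrland import (
    Ligand, BindingParams, Pose, lra_electrostatic, binding_free_energy,
    bind_along_path,
)
from gpcrland.binding import write_ligand_table, read_ligand_table, _vdw
from gpcrland.cg_model import CGStructure, SIDE_RADIUS, side_chain_depth
from gpcrland.energetics import EnergyParams


def _receptor(restypes, bb, sc):
    n = len(restypes)
    return CGStructure(np.full(n, "A"), np.arange(1, n + 1), np.full(n, ""),
                       np.array(list(restypes)), np.asarray(bb, float),
                       np.asarray(sc, float))


def _ligand(positions, charges, radius=1.7, depth=0.15, name="toy"):
    positions = np.asarray(positions, float).reshape(-1, 3)
    n = len(positions)
    return Ligand(name, [f"X{i}" for i in range(n)], positions,
                  np.asarray(charges, float), np.full(n, radius),
                  np.full(n, depth))


RIGID = BindingParams(include_solvation=False, relax_poses=False)


class TestLRAElectrostatic:
    def test_apolar_ligand_is_exactly_zero(self):
        rec = _receptor("D", [[0, -20, 0]], [[0, 0, 0]])
        lig = _ligand([[8, 0, 0]], [0.0])
        charges = np.array([-1.0])
        assert lra_electrostatic(Pose(lig), rec, charges,
                                 BindingParams()) == 0.0

    def test_single_pair_matches_hand_coulomb(self):
        # +1 ligand atom 8 A from a -1 side bead; backbone partial charges
        # switched off so the pair is the only interaction
        rec = _receptor("D", [[0, 0, 200.0]], [[0, 0, 0]])
        lig = _ligand([[8.0, 0, 0]], [1.0])
        charges = np.array([-1.0])
        ep = EnergyParams(backbone_charge=0.0)
        got = lra_electrostatic(Pose(lig), rec, charges, RIGID, ep)
        expect = 332.0 * 1.0 * (-1.0) / (RIGID.dielectric_in * 8.0)
        assert got == pytest.approx(expect, abs=1e-9)

    def test_linearity_in_ligand_charges_when_rigid(self):
        rec = _receptor("DK", [[0, 0, 200.0], [5, 0, 200.0]],
                        [[0, 0, 0], [5.0, 0, 0]])
        charges = np.array([-1.0, 1.0])
        lig1 = _ligand([[8, 0, 0], [9.4, 0, 0]], [0.3, -0.1])
        lig2 = _ligand([[8, 0, 0], [9.4, 0, 0]], [0.6, -0.2])
        e1 = lra_electrostatic(Pose(lig1), rec, charges, RIGID)
        e2 = lra_electrostatic(Pose(lig2), rec, charges, RIGID)
        assert e2 == pytest.approx(2 * e1, rel=1e-9)

    def test_clash_rejected(self):
        rec = _receptor("D", [[0, 0, 200.0]], [[0, 0, 0]])
        lig = _ligand([[0.5, 0, 0]], [1.0])
        with pytest.raises(ValueError, match="clash"):
            lra_electrostatic(Pose(lig), rec, np.array([-1.0]), RIGID)


class TestBindingFreeEnergy:
    def test_zero_beta_zero_charges(self):
        rec = _receptor("L", [[0, 0, 200.0]], [[0, 0, 0]])
        lig = _ligand([[6, 0, 0]], [0.0])
        p = BindingParams(beta=0.0, include_solvation=False,
                          relax_poses=False)
        assert binding_free_energy(Pose(lig), rec, None, p) == 0.0

    def test_beta_scales_vdw_term(self):
        rec = _receptor("L", [[0, 0, 200.0]], [[0, 0, 0]])
        lig = _ligand([[5.0, 0, 0]], [0.0])
        ep = EnergyParams()
        u_vdw = _vdw(lig, np.vstack([rec.bb_pos, rec.sc_pos]),
                     np.array([2.3, SIDE_RADIUS["L"]]),
                     np.array([0.15, side_chain_depth("L")]), ep)
        p = BindingParams(beta=0.25, include_solvation=False,
                          relax_poses=False)
        got = binding_free_energy(Pose(lig), rec, None, p, ep)
        assert got == pytest.approx(0.25 * u_vdw, abs=1e-12)

    def test_linear_in_beta_at_fixed_configuration(self):
        rec = _receptor("LD", [[0, 0, 200.0], [6, 0, 200.0]],
                        [[0, 0, 0], [6.0, 0, 0]])
        charges = np.array([0.0, -1.0])
        lig = _ligand([[3.0, 4.0, 0]], [0.5])
        es = []
        for beta in (0.0, 0.2, 0.4):
            p = BindingParams(beta=beta, include_solvation=False,
                              relax_poses=False)
            es.append(binding_free_energy(Pose(lig), rec, charges, p))
        assert es[2] - es[1] == pytest.approx(es[1] - es[0], abs=1e-9)

    def test_three_bead_pocket_matches_hand_worked_sum(self):
        """Dipolar ligand in a three-bead pocket vs an independent
        step-by-step evaluation of the Coulomb and 8-6 sums."""
        rec = _receptor("LDK",
                        [[0, 0, 200.0], [7, 0, 200.0], [3.5, 6, 200.0]],
                        [[0, 0, 0], [7.0, 0, 0], [3.5, 6.0, 0]])
        charges = np.array([0.0, -1.0, 1.0])
        lig = _ligand([[3.5, 2.0, 0.0], [3.5, 3.4, 0.0]], [0.4, -0.4])
        p = BindingParams(beta=0.3, include_solvation=False,
                          relax_poses=False)
        ep = EnergyParams()
        got = binding_free_energy(Pose(lig), rec, charges, p, ep)

        # hand evaluation: Coulomb over ligand x charged beads (side beads
        # carry the ionisation charge; backbone beads alternate +-0.05),
        # plus beta * switched 8-6 over ligand x all beads
        bead_pos = [rec.bb_pos[0], rec.bb_pos[1], rec.bb_pos[2],
                    rec.sc_pos[0], rec.sc_pos[1], rec.sc_pos[2]]
        bead_q = [0.05, -0.05, 0.05, 0.0, -1.0, 1.0]
        bead_r = [2.3, 2.3, 2.3, SIDE_RADIUS["L"], SIDE_RADIUS["D"],
                  SIDE_RADIUS["K"]]
        bead_e = [0.15, 0.15, 0.15, side_chain_depth("L"),
                  side_chain_depth("D"), side_chain_depth("K")]
        elec = vdw = 0.0
        for lq, lp in zip(lig.charges, lig.positions):
            for q, pos, r0b, epsb in zip(bead_q, bead_pos, bead_r, bead_e):
                r = float(np.linalg.norm(lp - np.asarray(pos)))
                elec += 332.0 * lq * q / (p.dielectric_in * r)
                if r < ep.cutoff:
                    x = (1.7 + r0b) / r
                    sw = 1.0 if r <= ep.cutoff_on else (
                        ((ep.cutoff - r) / 2.0) ** 2
                        * (3 - 2 * (ep.cutoff - r) / 2.0))
                    vdw += np.sqrt(0.15 * epsb) * \
                        (3 * x ** 8 - 4 * x ** 6) * sw
        assert got == pytest.approx(elec + 0.3 * vdw, abs=1e-8)


class TestBindAlongPath:
    def _frames(self, n=4, wobble=0.0):
        frames = []
        for k in range(n):
            rec = _receptor("LLK",
                            [[0, 0, -20], [8, 0, -20], [4, 7, -20]],
                            [[0, 0, 0], [8.0, 0, 0],
                             [4.0, 7.0 - wobble * k, 0]])
            frames.append(rec)
        return frames

    def test_identical_frames_identical_energies(self):
        frames = self._frames(4, wobble=0.0)
        lig = _ligand([[4.0, 2.5, 0]], [0.5])
        pose = Pose(lig, 0, [("A", 1), ("A", 2)])
        e = bind_along_path(frames, pose, None, RIGID)
        assert np.allclose(e, e[0])

    def test_contracting_pocket_strengthens_then_repels(self):
        frames = self._frames(8, wobble=0.55)  # bead 3 approaches the ligand
        lig = _ligand([[4.0, 2.0, 0]], [0.0])
        pose = Pose(lig, 0, [("A", 1), ("A", 2)])
        p = BindingParams(beta=1.0, include_solvation=False,
                          relax_poses=False)
        e = bind_along_path(frames, pose, None, p)
        k = int(np.argmin(e))
        assert 0 < k and e[k] < e[0]          # attraction grows to a minimum
        assert e[-1] > e[k]                   # then the contact over-closes

    def test_missing_pocket_residue_errors(self):
        frames = self._frames(3)
        lig = _ligand([[4.0, 2.5, 0]], [0.0])
        pose = Pose(lig, 0, [("A", 99)])
        with pytest.raises(KeyError):
            bind_along_path(frames, pose, None, RIGID)

    def test_clashing_frame_warns_and_scores_zero(self, caplog):
        frames = self._frames(6, wobble=1.0)
        lig = _ligand([[4.0, 2.2, 0]], [0.0])
        pose = Pose(lig, 0, [("A", 1), ("A", 2)])
        with caplog.at_level(logging.WARNING):
            e = bind_along_path(frames, pose, None, RIGID)
        assert e[-1] == 0.0
        assert any("anchoring failed" in r.message for r in caplog.records)

    def test_binding_shift_changes_barrier_by_argmax_minus_start(self):
        from gpcrland import profile_1d, barrier
        fold = np.array([0.0, 2.0, 5.0, 1.0])
        bind = np.array([-1.0, -1.5, -3.0, -2.0])
        coords = np.linspace(0, 1, 4)
        b_apo = barrier(profile_1d(coords, fold))
        b_holo = barrier(profile_1d(coords, fold + bind))
        k = int(np.argmax(fold + bind))
        assert b_holo == pytest.approx(
            fold[k] + bind[k] - fold[0] - bind[0], abs=1e-12)
        assert b_holo < b_apo


def test_ligand_table_roundtrip():
    lig = _ligand([[0, 0, 0], [1.4, 0, 0], [0.5, 1.2, 0]],
                  [0.4, -0.3, -0.1], name="amine")
    back = read_ligand_table(write_ligand_table(lig))
    assert back.name == "amine"
    assert np.allclose(back.positions, lig.positions, atol=1e-6)
    assert np.allclose(back.charges, lig.charges, atol=1e-6)
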