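"""Soft-LJ potential, empirical pair wells, and pose score decomposition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from excidock.scoring import (
    AtomTyping,
    COULOMB_MIN_R,
    ScoringConfig,
    ScoringContext,
    SearchBox,
    SoftLJParams,
    assign_atom_types,
    coulomb,
    pair_energy,
    score_pose,
    soft_lj,
)
from excidock.structio import Structure

from conftest import make_atom, random_protein

CFG = ScoringConfig()


class TestSoftLJ:
    def test_zero_crossing_at_sigma(self):
        assert soft_lj(3.3, SoftLJParams(alpha=0.0)) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_at_r6_sigma(self):
        p = SoftLJParams(alpha=0.0)
        assert soft_lj(2 ** (1 / 6) * p.sigma, p) == pytest.approx(-p.epsilon)

    def test_value_at_zero_softened(self):
        # symbolic: V(0) = 4 eps (1 - alpha) / alpha^2
        assert soft_lj(0.0, SoftLJParams(alpha=0.4, epsilon=0.5)) == pytest.approx(7.5)
        assert soft_lj(0.0, SoftLJParams(alpha=0.2, sigma=1.0, epsilon=1.0)) == \
            pytest.approx(4 * (1 - 0.2) / 0.04)

    def test_alpha_zero_at_zero_is_singular(self):
        with pytest.raises(ZeroDivisionError):
            soft_lj(0.0, SoftLJParams(alpha=0.0))

    def test_recovers_standard_lj(self):
        p = SoftLJParams(alpha=0.0)
        r = np.linspace(0.2 * p.sigma, 4 * p.sigma, 1000)
        std = 4 * p.epsilon * ((p.sigma / r) ** 12 - (p.sigma / r) ** 6)
        np.testing.assert_allclose(soft_lj(r, p), std, atol=1e-9)

    @given(st.floats(0.0, 0.99))
    def test_single_minimum(self, alpha):
        p = SoftLJParams(alpha=alpha)
        r = np.linspace(0.05 if alpha > 0 else 0.5, 5 * p.sigma, 2000)
        v = soft_lj(r, p)
        dv = np.diff(v)
        sign_changes = np.sum(np.diff(np.sign(dv[np.abs(dv) > 1e-15])) != 0)
        assert sign_changes <= 1  # decreasing then increasing


class TestCoulomb:
    def test_zero_charge_is_zero(self):
        assert coulomb(0.0, 1.0, 3.0) == 0.0

    def test_direct_evaluation(self):
        assert coulomb(1.0, -1.0, 4.0) == pytest.approx(-332.0636 / 64.0)

    def test_antisymmetric_in_charge_sign(self):
        assert coulomb(1.0, 1.0, 3.5) == pytest.approx(-coulomb(-1.0, 1.0, 3.5))

    def test_singular_at_zero(self):
        with pytest.raises(ZeroDivisionError):
            coulomb(1.0, 1.0, 0.0)

    def test_clamped_below_contact(self):
        assert coulomb(1.0, 1.0, 1.0) == coulomb(1.0, 1.0, COULOMB_MIN_R)


class TestAtomTyping:
    def test_backbone_o_acceptor_not_donor(self):
        s = Structure([make_atom(1, "O", "O", "ALA", "A", 1, (0, 0, 0))])
        (t,) = assign_atom_types(s)
        assert t.acceptor and not t.donor

    def test_arginine_guanidinium_donor_and_charged(self):
        s = Structure([make_atom(1, "NH2", "N", "ARG", "A", 1, (0, 0, 0))])
        (t,) = assign_atom_types(s)
        assert t.donor and t.charge == 1

    def test_aliphatic_carbon_hydrophobic_only(self):
        s = Structure([make_atom(1, "CB", "C", "ALA", "A", 1, (0, 0, 0))])
        (t,) = assign_atom_types(s)
        assert t.hydrophobic and not t.donor and not t.acceptor and t.charge == 0

    def test_aspartate_charge(self):
        s = Structure([
            make_atom(1, "OD1", "O", "ASP", "A", 1, (0, 0, 0)),
            make_atom(2, "OD2", "O", "ASP", "A", 1, (1, 0, 0)),
        ])
        t = assign_atom_types(s)
        assert t[0].charge == 0 and t[1].charge == -1

    def test_ligand_atoms_typed_by_element(self):
        s = Structure([
            make_atom(1, "N1", "N", "LIG", "X", 1, (0, 0, 0), charge=1, het=True),
            make_atom(2, "C1", "C", "LIG", "X", 1, (1, 0, 0), het=True),
        ])
        t = assign_atom_types(s)
        assert t[0].donor and t[0].acceptor and t[0].charge == 1
        assert t[1].hydrophobic

    def test_unknown_element_warns_hydrophobic(self, caplog):
        s = Structure([make_atom(1, "FE", "Fe", "LIG", "X", 1, (0, 0, 0), het=True)])
        import logging

        with caplog.at_level(logging.WARNING, logger="excidock.scoring"):
            (t,) = assign_atom_types(s)
        assert t.hydrophobic
        assert any("unknown element" in r.message for r in caplog.records)


DON = AtomTyping(donor=True, acceptor=True)
ACC = AtomTyping(acceptor=True)
HYD = AtomTyping(hydrophobic=True)
POS = AtomTyping(donor=True, acceptor=True, charge=1)
NEG = AtomTyping(acceptor=True, charge=-1)


class TestPairEnergy:
    def test_hbond_flat_well(self):
        pi = pair_energy(DON, ACC, 2.7)
        assert pi.type == "hbond" and pi.energy == pytest.approx(-2.5)

    def test_hbond_ramp_end_zero(self):
        assert pair_energy(DON, ACC, 3.6).energy == pytest.approx(0.0)

    def test_steric_well(self):
        pi = pair_energy(HYD, HYD, 4.0)
        assert pi.type == "steric" and pi.energy == pytest.approx(-0.4)

    def test_steric_clash(self):
        assert pair_energy(HYD, HYD, 1.0).energy == pytest.approx(5.0)

    def test_charged_pair_adds_coulomb(self):
        r = 4.0
        pi = pair_energy(POS, NEG, r)
        base = pair_energy(DON, ACC, r).energy
        assert pi.energy == pytest.approx(base + 332.0636 * -1 / (4 * r * r))
        assert pi.type == "hbond"  # donor/acceptor priority over electrostatic

    def test_electrostatic_label_without_hbond(self):
        charged_c = AtomTyping(hydrophobic=True, charge=1)
        pi = pair_energy(charged_c, AtomTyping(hydrophobic=True, charge=-1), 4.0)
        assert pi.type == "electrostatic"

    @pytest.mark.parametrize("knot", [2.0, 2.3, 3.1, 3.3, 3.6, 4.5, 6.0])
    def test_continuity_at_knots(self, knot):
        for ti, tj in ((DON, ACC), (HYD, HYD)):
            lo = pair_energy(ti, tj, knot - 1e-6).energy
            hi = pair_energy(ti, tj, knot + 1e-6).energy
            assert abs(hi - lo) < 1e-4


def _typed_structure(spec):
    """spec: list of (element, xyz, charge); builds a het LIG structure."""
    atoms = [make_atom(i + 1, f"{el}{i+1}", el, "LIG", "X", 1, xyz, charge=q, het=True)
             for i, (el, xyz, q) in enumerate(spec)]
    return Structure(atoms)


class TestScorePose:
    def test_single_hbond_pair(self):
        target = Structure([make_atom(1, "O", "O", "ALA", "A", 1, (0, 0, 0))])
        lig = _typed_structure([("N", (2.7, 0, 0), 0)])
        box = SearchBox((-10, -10, -10), (10, 10, 10))
        bd = score_pose(target, lig, box)
        assert bd.e_total == pytest.approx(-2.5)
        assert bd.e_penal == 0.0

    def test_out_of_box_penalty(self):
        target = Structure([make_atom(1, "O", "O", "ALA", "A", 1, (0, 0, 0))])
        lig = _typed_structure([("N", (50.0, 0, 0), 0)])
        box = SearchBox((-10, -10, -10), (10, 10, 10))
        bd = score_pose(target, lig, box)
        assert bd.e_penal == 10000.0
        assert bd.e_total >= 10000.0 - 10.0

    def test_decomposition_identity_exact(self):
        rng = np.random.default_rng(3)
        target = random_protein(rng, 10)
        lig = _typed_structure(
            [(el, rng.uniform(-12, 12, 3), 0) for el in "NOCCO"])
        box = SearchBox.around(target)
        bd = score_pose(target, lig, box)
        assert bd.e_total == (bd.e_inter + bd.e_intra + bd.e_penal) + bd.e_pharma \
            + (bd.wp_elec + bd.wp_hb)

    def test_e_inter_matches_brute_force(self):
        rng = np.random.default_rng(3)
        target = random_protein(rng, 15)
        spec = [("N", rng.uniform(-12, 12, 3), 1)] + [
            (el, rng.uniform(-12, 12, 3), 0) for el in "OCCOCNOCC"
        ]
        lig = _typed_structure(spec)
        box = SearchBox((-100,) * 3, (100,) * 3)
        bd = score_pose(target, lig, box)
        # brute force over all heavy pairs within the 6-A cutoff
        ttypes = assign_atom_types(target)
        ltypes = assign_atom_types(lig)
        expected = 0.0
        for i in target.heavy_indices:
            for j in lig.heavy_indices:
                r = float(np.linalg.norm(np.array(target.atoms[i].coords)
                                         - np.array(lig.atoms[j].coords)))
                if r <= CFG.inter_cutoff:
                    expected += pair_energy(ttypes[i], ltypes[j], r).energy
        assert bd.e_inter == pytest.approx(expected, abs=1e-9)

    def test_wp_hb_penalty_when_no_hbond_formed(self):
        target = Structure([make_atom(1, "CB", "C", "ALA", "A", 1, (0, 0, 0))])
        lig = _typed_structure([("O", (4.0, 0, 0), 0), ("O", (5.5, 0, 0), 0),
                                ("O", (4.0, 1.5, 0), 0)])
        bd = score_pose(target, lig, SearchBox((-10,) * 3, (10,) * 3))
        assert bd.wp_hb == 5.0

    def test_wp_elec_penalty_for_unpaired_charge(self):
        target = Structure([make_atom(1, "CB", "C", "ALA", "A", 1, (0, 0, 0))])
        lig = _typed_structure([("N", (4.0, 0, 0), 1)])
        bd = score_pose(target, lig, SearchBox((-10,) * 3, (10, 10, 10)))
        assert bd.wp_elec == 5.0
        # neutralised by an opposite charge within 4 A
        target2 = Structure([make_atom(1, "OD2", "O", "ASP", "A", 1, (0, 0, 0))])
        bd2 = score_pose(target2, lig, SearchBox((-10,) * 3, (10, 10, 10)))
        assert bd2.wp_elec == 0.0
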