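"""MM energy evaluator: hand-checked values, filters, gradients."""

import math

import numpy as np
import pytest

from qmmmkit.mm import (
    ELEC_MM_MM_ONLY,
    ELEC_NONE,
    FILTER_ADDITIVE,
    FILTER_ALL,
    EnergyReport,
    TermFilter,
    embedding_coulomb,
    enumerate_terms,
    mm_energy,
)
from qmmmkit.topology import (
    Atom,
    AngleTerm,
    BondTerm,
    DihedralTerm,
    LJParam,
    Structure,
    Topology,
)
from qmmmkit.units import COULOMB_CONSTANT

from conftest import fd_gradient


def _two_atom_topology(charge_a=0.3, charge_b=-0.3, eps=0.1, rmin_half=1.7):
    atoms = [
        Atom("A", "C", "ca", 12.011, charge_a, 0, "MOL"),
        Atom("B", "C", "ca", 12.011, charge_b, 0, "MOL"),
    ]
    return Topology(atoms=atoms, lj={"ca": LJParam(rmin_half, eps)},
                    bonds=[], angles=[], dihedrals=[])


def test_single_pair_hand_values():
    """Coulomb and LJ of one pair match the defining formulas exactly."""
    top = _two_atom_topology()
    r = 3.2
    s = Structure(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))
    rep = mm_energy(top, s)
    e_elec = COULOMB_CONSTANT * 0.3 * (-0.3) / r
    rmin = 2 * 1.7
    a6 = (rmin / r) ** 6
    e_vdw = 0.1 * (a6 * a6 - 2 * a6)
    assert rep.components["elec"] == pytest.approx(e_elec, rel=1e-14)
    assert rep.components["vdw"] == pytest.approx(e_vdw, rel=1e-14)
    assert rep.total == pytest.approx(e_elec + e_vdw, rel=1e-14)


def test_vdw_minimum_is_at_rmin_sum():
    top = _two_atom_topology(charge_a=0.0, charge_b=0.0)
    rmin = 2 * 1.7
    at_min = mm_energy(top, Structure(np.array([[0, 0, 0], [rmin, 0, 0.0]])))
    assert at_min.components["vdw"] == pytest.approx(-0.1, rel=1e-12)
    assert np.allclose(at_min.gradient, 0.0, atol=1e-12)


def test_single_bond_energy_and_gradient():
    atoms = [Atom("A", "C", "ca", 12.0, 0.0, 0, "MOL"),
             Atom("B", "C", "ca", 12.0, 0.0, 0, "MOL")]
    top = Topology(atoms=atoms, lj={"ca": LJParam(0.0, 0.0)},
                   bonds=[BondTerm(0, 1, 310.0, 1.526)],
                   angles=[], dihedrals=[], exclusions={(0, 1)})
    s = Structure(np.array([[0.0, 0.0, 0.0], [1.8, 0.0, 0.0]]))
    rep = mm_energy(top, s)
    # AMBER convention: E = k (r - r0)^2 with no 1/2
    assert rep.total == pytest.approx(310.0 * (1.8 - 1.526) ** 2, rel=1e-14)
    assert rep.gradient[1, 0] == pytest.approx(2 * 310.0 * (1.8 - 1.526), rel=1e-12)


def test_scaled_14_divisors_hand_value():
    """A 4-atom chain: the 1-4 pair is divided by scee/scnb exactly."""
    atoms = [Atom(n, "C", "ca", 12.0, q, 0, "MOL")
             for n, q in (("A", 0.2), ("B", 0.0), ("C", 0.0), ("D", -0.2))]
    bonds = [BondTerm(0, 1, 0.0, 1.5), BondTerm(1, 2, 0.0, 1.5),
             BondTerm(2, 3, 0.0, 1.5)]
    top = Topology(atoms=atoms, lj={"ca": LJParam(1.7, 0.1)},
                   bonds=bonds, angles=[], dihedrals=[],
                   exclusions={(0, 1), (1, 2), (2, 3), (0, 2), (1, 3)},
                   pairs14={(0, 3): (1.2, 2.0)})
    coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0]])
    rep = mm_energy(top, Structure(coords))
    r = 4.5
    assert rep.components["elec14"] == pytest.approx(
        COULOMB_CONSTANT * 0.2 * (-0.2) / r / 1.2, rel=1e-14)
    a6 = (3.4 / r) ** 6
    assert rep.components["vdw14"] == pytest.approx(
        0.1 * (a6 * a6 - 2 * a6) / 2.0, rel=1e-14)
    assert rep.components["elec"] == 0.0 and rep.components["vdw"] == 0.0


def test_dihedral_term_value():
    atoms = [Atom(n, "C", "ca", 12.0, 0.0, 0, "MOL") for n in "ABCD"]
    top = Topology(atoms=atoms, lj={"ca": LJParam(0.0, 0.0)},
                   bonds=[], angles=[],
                   dihedrals=[DihedralTerm(0, 1, 2, 3, height=1.4,
                                           periodicity=3, phase=0.0)],
                   exclusions={(0, 1), (1, 2), (2, 3), (0, 2), (1, 3), (0, 3)})
    coords = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0],
                       [0.0, 1.5, 0.0], [math.cos(1.0), 1.5, math.sin(1.0)]])
    rep = mm_energy(top, Structure(coords))
    # the constructed torsion angle is exactly 1 radian
    assert rep.total == pytest.approx(1.4 * (1 + math.cos(3 * 1.0)), rel=1e-12)


def test_full_gradient_matches_fd(any_fixture):
    top, struct = any_fixture.topology, any_fixture.structure
    rep = mm_energy(top, struct)
    fd = fd_gradient(lambda s: mm_energy(top, s).total, struct.coords)
    assert np.abs(rep.gradient - fd).max() < 1e-6


def test_total_equals_component_sum(any_fixture):
    rep = mm_energy(any_fixture.topology, any_fixture.structure)
    assert rep.total == pytest.approx(sum(rep.components.values()), abs=1e-12)


def test_filters_partition_energy(ethanol):
    """ALL == ADDITIVE + (complement) term by term for bonded classes."""
    top, struct, rm = ethanol.topology, ethanol.structure, ethanol.region_map
    all_rep = mm_energy(top, struct, FILTER_ALL, region_map=rm)
    add_rep = mm_energy(top, struct, FILTER_ADDITIVE, region_map=rm)
    qm_only = TermFilter(
        bonded=lambda r: "MM" not in r,
        elec=lambda r: not all(x == "MM" for x in r),
        vdw=lambda r: all(x == "QM" for x in r),
        name="complement")
    rest = mm_energy(top, struct, qm_only, region_map=rm)
    assert all_rep.total == pytest.approx(add_rep.total + rest.total, abs=1e-10)
    assert np.allclose(all_rep.gradient, add_rep.gradient + rest.gradient,
                       atol=1e-10)


def test_elec_none_filter(ethanol):
    rep = mm_energy(ethanol.topology, ethanol.structure,
                    FILTER_ALL & ELEC_NONE)
    assert rep.components["elec"] == 0.0
    assert rep.components["elec14"] == 0.0


def test_elec_mm_mm_only(ethanol):
    rep = mm_energy(ethanol.topology, ethanol.structure, ELEC_MM_MM_ONLY,
                    region_map=ethanol.region_map)
    # only MM-MM electrostatics: the H21/H22/H23 pairs, all excluded or 1-4?
    labels = ethanol.region_map.labels
    expected = 0.0
    charges = ethanol.topology.charges
    for rec in enumerate_terms(ethanol.topology, ethanol.region_map):
        if rec["kind"] != "pair":
            continue
        i, j = rec["atoms"]
        if labels[i] == labels[j] == "MM":
            r = np.linalg.norm(ethanol.structure.coords[i]
                               - ethanol.structure.coords[j])
            scale = rec["scee"] if rec["scaled14"] else 1.0
            expected += COULOMB_CONSTANT * charges[i] * charges[j] / (r * scale)
    assert rep.components["elec"] + rep.components["elec14"] == \
        pytest.approx(expected, abs=1e-12)


def test_bonded_term_veto(ethanol):
    top, struct = ethanol.topology, ethanol.structure
    no_bonds = mm_energy(top, struct,
                         bonded_term_veto=lambda ats: len(ats) == 2)
    assert no_bonds.components["bond"] == 0.0
    assert no_bonds.components["angle"] == \
        pytest.approx(mm_energy(top, struct).components["angle"], abs=1e-12)


def test_charge_set_override(ethanol):
    top, struct = ethanol.topology, ethanol.structure
    zero = mm_energy(top, struct, charge_set=np.zeros(9))
    assert zero.components["elec"] == 0.0 and zero.components["elec14"] == 0.0
    base = mm_energy(top, struct)
    assert base.components["elec"] != 0.0


def test_embedding_coulomb_value_and_fd():
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(4, 3))
    q = rng.normal(size=4)
    pc_pos = rng.normal(size=(3, 3)) + 5.0
    pc_q = rng.normal(size=3)
    e, g_at, g_pc = embedding_coulomb(coords, q, pc_pos, pc_q)
    expected = sum(COULOMB_CONSTANT * q[i] * pc_q[m]
                   / np.linalg.norm(coords[i] - pc_pos[m])
                   for i in range(4) for m in range(3))
    assert e == pytest.approx(expected, rel=1e-12)

    h = 1e-6
    for i in range(4):
        for x in range(3):
            cp = coords.copy(); cp[i, x] += h
            cm = coords.copy(); cm[i, x] -= h
            fd = (embedding_coulomb(cp, q, pc_pos, pc_q)[0]
                  - embedding_coulomb(cm, q, pc_pos, pc_q)[0]) / (2 * h)
            assert g_at[i, x] == pytest.approx(fd, abs=1e-6)
    for m in range(3):
        for x in range(3):
            pp = pc_pos.copy(); pp[m, x] += h
            pm = pc_pos.copy(); pm[m, x] -= h
            fd = (embedding_coulomb(coords, q, pp, pc_q)[0]
                  - embedding_coulomb(coords, q, pm, pc_q)[0]) / (2 * h)
            assert g_pc[m, x] == pytest.approx(fd, abs=1e-6)


def test_embedding_coulomb_empty():
    e, g_at, g_pc = embedding_coulomb(np.zeros((2, 3)), [0.1, 0.2],
                                      np.zeros((0, 3)), [])
    assert e == 0.0 and g_pc.shape == (0, 3)


def test_energy_report_json_round_trip(ethanol):
    rep = mm_energy(ethanol.topology, ethanol.structure)
    back = EnergyReport.from_json(rep.to_json())
    assert back.total == rep.total
    assert np.array_equal(back.gradient, rep.gradient)
    assert back.components == rep.components


def test_no_cutoff_long_range_pair():
    """Even a 100 A pair interacts: there is no nonbonded cutoff."""
    top = _two_atom_topology(charge_a=1.0, charge_b=1.0, eps=0.0)
    rep = mm_energy(top, Structure(np.array([[0, 0, 0], [100.0, 0, 0]])))
    assert rep.components["elec"] == pytest.approx(COULOMB_CONSTANT / 100.0,
                                                   rel=1e-14)
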