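"""Region assignment, link-atom placement/projection, truncated topologies."""

import numpy as np
import pytest

from qmmmkit.mm import mm_energy
from qmmmkit.regions import (
    LinkSpec,
    RegionError,
    assign_regions,
    build_truncated_topology,
    place_link_atoms,
    project_link_gradient,
    resolve_link_specs,
    scale_link_force_constant,
)
from qmmmkit.topology import Structure, canonical_bond, validate_topology

from conftest import fd_gradient


def test_assign_regions_ethanol(ethanol):
    rm = ethanol.region_map
    assert rm.qm_indices == [0, 1, 2, 3, 4, 5]
    assert rm.mm_indices == [6, 7, 8]
    assert [j.cl for j in rm.junctions] == [5]
    jn = rm.junctions[0]
    assert jn.q1 == 2                       # C1 anchors the junction
    assert jn.m2 == (6, 7, 8)               # methyl hydrogens
    assert jn.q2 == (1, 3, 4)               # O, H11, H12
    assert rm.bonded_cl_pairs == []


def test_assign_regions_two_junctions(nma):
    rm = nma.region_map
    assert sorted(j.cl for j in rm.junctions) == [0, 8]
    assert {j.cl: j.q1 for j in rm.junctions} == {0: 4, 8: 6}


def test_assign_regions_bonded_cl_pair(dme):
    rm = dme.region_map
    assert rm.bonded_cl_pairs == [canonical_bond(5, 8)]
    assert sorted(j.cl for j in rm.junctions) == [5, 8]


def test_empty_selection_rejected(ethanol):
    with pytest.raises(RegionError):
        assign_regions(ethanol.topology, [])


def test_out_of_range_selection_rejected(ethanol):
    with pytest.raises(RegionError):
        assign_regions(ethanol.topology, [0, 1, 99])


def test_invalid_junctions_rejected(ethanol):
    # QM = {HO, O, C1, H11, H12}: C1 is a boundary atom with three QM
    # neighbours, so its Q1 anchor is ambiguous
    with pytest.raises(RegionError):
        assign_regions(ethanol.topology, [0, 1, 2, 3, 4])
    # QM = {C2} alone: the boundary atom has no QM neighbour at all
    with pytest.raises(RegionError):
        assign_regions(ethanol.topology, [5])


def test_link_spec_g_and_validation():
    spec = LinkSpec(r0_hl=1.090, r0_cl=1.526)
    assert spec.g == pytest.approx(1.090 / 1.526, rel=1e-15)
    with pytest.raises(ValueError):
        LinkSpec(r0_hl=-1.0, r0_cl=1.5)


def test_resolve_link_specs_reads_force_field(ethanol):
    specs = ethanol.link_specs
    spec = specs[5]
    assert spec.r0_hl == 1.090
    # r0_cl comes from the c3-c3 bond table entry
    q1cl = [b for b in ethanol.topology.bonds
            if canonical_bond(b.i, b.j) == (2, 5)][0]
    assert spec.r0_cl == q1cl.r_eq
    assert spec.hl_type == "hc"


def test_resolve_link_specs_missing_length(ethanol):
    with pytest.raises(RegionError):
        resolve_link_specs(ethanol.topology, ethanol.region_map, r0_hl={})


def test_place_link_atoms_geometry(ethanol):
    coords = ethanol.structure.coords
    hl = place_link_atoms(ethanol.structure, ethanol.region_map,
                          ethanol.link_specs)
    assert hl.coords.shape == (6, 3)
    # non-CL slots are untouched (bitwise)
    for s, a in enumerate(ethanol.region_map.qm_indices):
        if a != 5:
            assert np.array_equal(hl.coords[s], coords[a])
    g = ethanol.link_specs[5].g
    expected = coords[2] + g * (coords[5] - coords[2])
    assert np.allclose(hl.coords[5], expected, atol=1e-15)
    # HL lies on the Q1->CL segment at fraction g of the bond length
    d_q1_hl = np.linalg.norm(hl.coords[5] - coords[2])
    d_q1_cl = np.linalg.norm(coords[5] - coords[2])
    assert d_q1_hl == pytest.approx(g * d_q1_cl, rel=1e-12)


def test_project_link_gradient_matches_fd(ethanol):
    """Chain rule through the HL placement agrees with finite differences."""
    top, rm, specs = ethanol.topology, ethanol.region_map, ethanol.link_specs
    trunc, sys1 = build_truncated_topology(top, rm, specs, charges="keep")

    def energy_of_full(structure):
        hl = place_link_atoms(structure, rm, specs)
        return mm_energy(trunc, hl).total

    hl0 = place_link_atoms(ethanol.structure, rm, specs)
    g_hl = mm_energy(trunc, hl0).gradient
    g_sys1 = project_link_gradient(g_hl, rm, specs)
    full_grad = np.zeros_like(ethanol.structure.coords)
    full_grad[sys1] = g_sys1
    fd = fd_gradient(energy_of_full, ethanol.structure.coords)
    assert np.abs(full_grad - fd).max() < 1e-6


def test_scale_link_force_constant_identity():
    """k_hl (g r - r0_hl)^2 == k_cl (r - r0_cl)^2 for every r."""
    k_cl, r0_cl, r0_hl = 310.0, 1.526, 1.090
    k_hl = scale_link_force_constant(k_cl, r0_cl, r0_hl)
    assert k_hl == pytest.approx(k_cl * (r0_cl / r0_hl) ** 2, rel=1e-15)
    g = r0_hl / r0_cl
    for r in np.linspace(1.0, 2.2, 25):
        assert k_hl * (g * r - r0_hl) ** 2 == \
            pytest.approx(k_cl * (r - r0_cl) ** 2, abs=1e-10)
    with pytest.raises(ValueError):
        scale_link_force_constant(-1.0, 1.5, 1.1)


def test_truncated_topology_hl_contents(ethanol):
    top, rm, specs = ethanol.topology, ethanol.region_map, ethanol.link_specs
    trunc, sys1 = build_truncated_topology(top, rm, specs, charges="zero")
    assert sys1 == [0, 1, 2, 3, 4, 5]
    assert trunc.n_atoms == 6
    assert validate_topology(trunc) == []
    hl = trunc.atoms[5]
    assert (hl.name, hl.element, hl.type_label) == ("HL", "H", "hc")
    assert hl.mass == pytest.approx(1.008)
    assert np.all(trunc.charges == 0.0)
    # the Q1-HL bond is rescaled; all other bonds keep their parameters
    link = [b for b in trunc.bonds if canonical_bond(b.i, b.j) == (2, 5)][0]
    orig = [b for b in top.bonds if canonical_bond(b.i, b.j) == (2, 5)][0]
    assert link.r_eq == specs[5].r0_hl
    assert link.k == pytest.approx(
        scale_link_force_constant(orig.k, orig.r_eq, specs[5].r0_hl), rel=1e-15)
    # 5 bonds of methanol (HO-O, O-C1, C1-H11, C1-H12, C1-HL)
    assert len(trunc.bonds) == 5
    # no term may reference an out-of-range atom and no MM atom survives
    for b in trunc.bonds:
        assert 0 <= b.i < 6 and 0 <= b.j < 6


def test_truncated_topology_cl_representation(ethanol):
    top, rm, specs = ethanol.topology, ethanol.region_map, ethanol.link_specs
    trunc, sys1 = build_truncated_topology(top, rm, specs, charges="keep",
                                           link_representation="CL")
    cl = trunc.atoms[5]
    orig = top.atoms[5]
    assert (cl.name, cl.element, cl.type_label, cl.mass) == \
        (orig.name, orig.element, orig.type_label, orig.mass)
    link = [b for b in trunc.bonds if canonical_bond(b.i, b.j) == (2, 5)][0]
    orig_b = [b for b in top.bonds if canonical_bond(b.i, b.j) == (2, 5)][0]
    assert (link.k, link.r_eq) == (orig_b.k, orig_b.r_eq)
    assert np.array_equal(trunc.charges, top.charges[:6])


def test_truncated_topology_qm_charges(ethanol):
    top, rm = ethanol.topology, ethanol.region_map
    specs = resolve_link_specs(top, rm, r0_hl={5: 1.090}, hl_type="hc",
                               hl_charge={5: -0.0108})
    trunc, _ = build_truncated_topology(
        top, rm, specs, charges="qm",
        qm_charges=dict(enumerate(ethanol.qm_charges.values)))
    assert trunc.charges[5] == -0.0108
    assert trunc.charges[1] == ethanol.qm_charges.values[1]


def test_truncated_topology_exclusions_from_full_graph(ethanol):
    top, rm, specs = ethanol.topology, ethanol.region_map, ethanol.link_specs
    trunc, _ = build_truncated_topology(top, rm, specs)
    # HO(0)..HL(5) are 3 bonds apart in the full graph -> a 1-4 pair
    assert (0, 5) in trunc.pairs14
    # O(1)..HL(5) are 2 bonds apart -> excluded
    assert (1, 5) in trunc.exclusions
    assert not (set(trunc.exclusions) & set(trunc.pairs14))


def test_truncated_topology_drops_cross_junction_terms(dme):
    top, rm, specs = dme.topology, dme.region_map, dme.link_specs
    trunc, sys1 = build_truncated_topology(top, rm, specs, charges="keep")
    s = {a: i for i, a in enumerate(sys1)}
    pair = {s[5], s[8]}
    for b in trunc.bonds:
        assert not pair <= {b.i, b.j}
    for a in trunc.angles:
        assert not pair <= {a.i, a.j, a.k_atom}
    for d in trunc.dihedrals:
        assert not pair <= {d.i, d.j, d.k_atom, d.l}
    # but the removed bond's nonbonded exclusion is kept
    assert canonical_bond(s[5], s[8]) in trunc.exclusions
    assert validate_topology(trunc) == []
    # two junctions -> numbered link atoms
    assert {trunc.atoms[s[5]].name, trunc.atoms[s[8]].name} == {"HL1", "HL2"}


def test_truncated_nma_has_two_link_types(nma):
    trunc, sys1 = build_truncated_topology(
        nma.topology, nma.region_map, nma.link_specs, charges="keep")
    s = {a: i for i, a in enumerate(sys1)}
    assert trunc.atoms[s[0]].type_label == "hc"
    assert trunc.atoms[s[8]].type_label == "hn"
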