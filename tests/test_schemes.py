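"""Scheme assemblies: additive/subtractive identities, ME/ELAC, BLAC."""

import numpy as np
import pytest

from qmmmkit.backends import SmoothTestBackend
from qmmmkit.charges import ChargeSet
from qmmmkit.mm import mm_energy
from qmmmkit.regions import (
    RegionMap,
    assign_regions,
    build_truncated_topology,
    place_link_atoms,
)
from qmmmkit.schemes import (
    SCHEMES,
    SchemeConfig,
    SchemeError,
    apply_blac_parameters,
    compute_scheme_energy,
    energy_additive,
    energy_subtractive,
    make_objective,
    scheme_decomposition,
)
from qmmmkit.topology import Structure, canonical_bond
from qmmmkit.units import KCAL_PER_MOL_TO_KJ_PER_MOL

from conftest import fd_gradient, merged_for

TIGHT = 1e-10


def _me_config(fixture, scheme="ME"):
    return SchemeConfig(scheme=scheme, mm_charges=fixture.mm_charges,
                        qm_charges=fixture.qm_charges,
                        merged_charges=merged_for(fixture))


def _run(fixture, scheme, config=None, backend=None, structure=None):
    return compute_scheme_energy(
        fixture.topology, structure or fixture.structure, fixture.region_map,
        fixture.link_specs, config or SchemeConfig(scheme=scheme), backend)


# ----------------------------------------------------------------------
# Additive / strict-subtractive equivalence
# ----------------------------------------------------------------------

def test_additive_equals_strict_subtractive(any_fixture):
    add = _run(any_fixture, "ADD")
    sub = _run(any_fixture, "SUB_STRICT")
    assert abs(add.total - sub.total) < TIGHT
    assert np.abs(add.gradient - sub.gradient).max() < TIGHT


def test_additive_equals_strict_on_perturbed_geometries(ethanol):
    rng = np.random.default_rng(42)
    for _ in range(5):
        coords = ethanol.structure.coords + rng.normal(scale=0.05, size=(9, 3))
        s = Structure(coords)
        add = _run(ethanol, "ADD", structure=s)
        sub = _run(ethanol, "SUB_STRICT", structure=s)
        assert abs(add.total - sub.total) < TIGHT
        assert np.abs(add.gradient - sub.gradient).max() < TIGHT


def test_equivalence_holds_for_any_backend(any_fixture):
    """ADD vs SUB_STRICT is pure MM bookkeeping: swapping in an arbitrary
    smooth 'QM' function must not break it."""
    backend = SmoothTestBackend(len(any_fixture.region_map.qm_indices), seed=5)
    add = _run(any_fixture, "ADD", backend=backend)
    sub = _run(any_fixture, "SUB_STRICT", backend=backend)
    assert abs(add.total - sub.total) < TIGHT
    assert np.abs(add.gradient - sub.gradient).max() < TIGHT
    assert add.metadata["backend"] == "smooth-test"


# ----------------------------------------------------------------------
# Van der Waals link-atom correction (the VLAC decomposition)
# ----------------------------------------------------------------------

def _lj_pair_energy(topo, coords, i, j):
    pi, pj = topo.lj_for_atom(i), topo.lj_for_atom(j)
    eps = np.sqrt(pi.epsilon * pj.epsilon)
    if eps == 0.0:
        return 0.0
    rmin = pi.rmin_half + pj.rmin_half
    r = np.linalg.norm(coords[i] - coords[j])
    a6 = (rmin / r) ** 6
    e = eps * (a6 * a6 - 2.0 * a6)
    pair = canonical_bond(i, j)
    if pair in topo.pairs14:
        e /= topo.pairs14[pair][1]
    return e


def _boundary_vdw(topo, coords, slots):
    total = 0.0
    n = topo.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in topo.exclusions:
                continue
            if i in slots or j in slots:
                total += _lj_pair_energy(topo, coords, i, j)
    return total


def test_vlac_equals_boundary_vdw_difference(any_fixture):
    """VLAC - STRICT is exactly the vdW difference of boundary-involving
    pairs evaluated CL-wise minus HL-wise (brute-force enumeration)."""
    f = any_fixture
    vlac = _run(f, "SUB_VLAC")
    strict = _run(f, "SUB_STRICT")
    trunc_hl, sys1 = build_truncated_topology(
        f.topology, f.region_map, f.link_specs, charges="zero")
    trunc_cl, _ = build_truncated_topology(
        f.topology, f.region_map, f.link_specs, charges="zero",
        link_representation="CL")
    slot = {a: s for s, a in enumerate(sys1)}
    link_slots = {slot[cl] for cl in f.region_map.cl_indices}
    hl = place_link_atoms(f.structure, f.region_map, f.link_specs)
    expected = (_boundary_vdw(trunc_cl, f.structure.coords[sys1], link_slots)
                - _boundary_vdw(trunc_hl, hl.coords, link_slots))
    assert vlac.total - strict.total == pytest.approx(expected, abs=1e-12)


def test_vlac_magnitudes(ethanol, nma, dme):
    """The correction vanishes only when boundary vdW terms have zero depth."""
    def vlac_size(f):
        return _run(f, "SUB_VLAC").total - _run(f, "SUB_STRICT").total
    # ethanol's only boundary-involving intra-QM pair hits the zero-depth
    # hydroxyl hydrogen type, so the correction is identically zero
    assert abs(vlac_size(ethanol)) < 1e-12
    assert abs(vlac_size(nma)) > 0.1
    assert abs(vlac_size(dme)) > 0.1


# ----------------------------------------------------------------------
# Dummy-parameter invariance of the subtractive assembly
# ----------------------------------------------------------------------

def test_intra_qm_bonded_parameters_cancel(nma):
    """With a fixed QM backend, perturbing bonded parameters of pure intra-QM
    terms (not the junction bond) leaves the subtractive total unchanged."""
    import dataclasses

    backend = SmoothTestBackend(len(nma.region_map.qm_indices), seed=17)
    base = _run(nma, "SUB_VLAC", backend=backend)

    top = nma.topology
    qm = set(nma.region_map.qm_indices)
    cls = set(nma.region_map.cl_indices)
    link_keys = {canonical_bond(j.q1, j.cl) for j in nma.region_map.junctions}

    bonds = [dataclasses.replace(b, k=b.k * 1.7, r_eq=b.r_eq + 0.03)
             if {b.i, b.j} <= qm and not ({b.i, b.j} & cls)
             and canonical_bond(b.i, b.j) not in link_keys else b
             for b in top.bonds]
    angles = [dataclasses.replace(a, k=a.k + 25.0)
              if {a.i, a.j, a.k_atom} <= qm
              and not ({a.i, a.j, a.k_atom} & cls) else a
              for a in top.angles]
    dihedrals = [dataclasses.replace(d, height=d.height + 0.9)
                 if {d.i, d.j, d.k_atom, d.l} <= qm
                 and not ({d.i, d.j, d.k_atom, d.l} & cls) else d
                 for d in top.dihedrals]
    assert bonds != list(top.bonds)        # the perturbation is not vacuous
    perturbed = dataclasses.replace(top, bonds=bonds, angles=angles,
                                    dihedrals=dihedrals)

    rep = compute_scheme_energy(perturbed, nma.structure, nma.region_map,
                                nma.link_specs, SchemeConfig("SUB_VLAC"),
                                backend)
    assert abs(rep.total - base.total) < TIGHT
    assert np.abs(rep.gradient - base.gradient).max() < TIGHT


def test_link_bond_force_constant_cancels(ethanol):
    """The junction bond's k cancels too, because the Q1-HL bond is rescaled
    to reproduce the Q1-CL bond energy at every geometry."""
    import dataclasses

    backend = SmoothTestBackend(6, seed=17)
    base = _run(ethanol, "SUB_VLAC", backend=backend)
    bonds = [dataclasses.replace(b, k=b.k * 3.0)
             if canonical_bond(b.i, b.j) == (2, 5) else b
             for b in ethanol.topology.bonds]
    perturbed = dataclasses.replace(ethanol.topology, bonds=bonds)
    rep = compute_scheme_energy(perturbed, ethanol.structure,
                                ethanol.region_map, ethanol.link_specs,
                                SchemeConfig("SUB_VLAC"), backend)
    assert abs(rep.total - base.total) < TIGHT


# ----------------------------------------------------------------------
# Mechanical embedding and the electrostatic link-atom correction
# ----------------------------------------------------------------------

def test_me_total_is_merged_mm12(any_fixture):
    """With the MM surrogate, QM1 and MM1 cancel bitwise: the ME total is the
    full-system MM energy over the merged charge set."""
    f = any_fixture
    me = _run(f, "ME", config=_me_config(f))
    veto_pairs = f.region_map.bonded_cl_pairs
    ref = mm_energy(f.topology, f.structure, charge_set=merged_for(f),
                    bonded_term_veto=(
                        (lambda ats: any(set(p) <= set(ats) for p in veto_pairs))
                        if veto_pairs else None))
    assert me.total == ref.total
    assert np.abs(me.gradient - ref.gradient).max() < TIGHT
    assert me.metadata["embedding"] == "mechanical"


def test_me_closure_with_matched_charges(nma):
    """When the QM-derived charges coincide with the MM ones, the merge is the
    identity and the ME total equals the plain MM energy of the full system."""
    matched = ChargeSet(nma.mm_charges.values.copy(), provenance="qm_derived",
                        hl_charges=dict(nma.qm_charges.hl_charges))
    cfg = SchemeConfig(scheme="ME", mm_charges=nma.mm_charges,
                       qm_charges=matched,
                       merged_charges=None)
    from qmmmkit.charges import merge_charges_me
    cfg.merged_charges = merge_charges_me(nma.mm_charges, matched,
                                          nma.region_map, nma.unit_partition)
    assert np.array_equal(cfg.merged_charges.values, nma.mm_charges.values)
    me = _run(nma, "ME", config=cfg)
    ref = mm_energy(nma.topology, nma.structure)
    assert me.total == ref.total
    assert np.abs(me.gradient - ref.gradient).max() < TIGHT


def test_elac_equals_me_under_surrogate(any_fixture):
    """The ELAC point-charge terms are identical in QM1 and MM1, so with the
    surrogate backend ELAC collapses onto ME."""
    f = any_fixture
    me = _run(f, "ME", config=_me_config(f, "ME"))
    elac = _run(f, "ELAC", config=_me_config(f, "ELAC"))
    assert elac.total == pytest.approx(me.total, abs=TIGHT)
    assert np.abs(elac.gradient - me.gradient).max() < TIGHT
    assert elac.metadata["embedding"] == "electrostatic"


def test_me_requires_merged_and_qm_charges(ethanol):
    with pytest.raises(SchemeError):
        _run(ethanol, "ME", config=SchemeConfig(scheme="ME"))
    with pytest.raises(SchemeError):
        _run(ethanol, "ME", config=SchemeConfig(
            scheme="ME", merged_charges=merged_for(ethanol)))


# ----------------------------------------------------------------------
# BLAC
# ----------------------------------------------------------------------

def test_blac_empty_tables_is_vlac(any_fixture):
    vlac = _run(any_fixture, "SUB_VLAC")
    blac = _run(any_fixture, "BLAC", config=SchemeConfig(scheme="BLAC"))
    assert blac.total == vlac.total
    assert np.array_equal(blac.gradient, vlac.gradient)


def test_blac_single_angle_substitution_arithmetic(ethanol):
    """Replacing one angle in the subtracted (HL-side) term shifts the total
    by old-term-minus-new-term at the link-atom geometry, exactly."""
    from qmmmkit.mm import bond_angle

    key = ("oh", "c3", "hc")            # the O-C1-HL angle of the model
    orig = [a for a in ethanol.topology.angles
            if (a.i, a.j, a.k_atom) == (1, 2, 5)][0]
    new_k, new_t0 = orig.k + 20.0, orig.theta_eq + 0.05
    cfg = SchemeConfig(scheme="BLAC", blac_hl={key: (new_k, new_t0)})
    vlac = _run(ethanol, "SUB_VLAC")
    blac = _run(ethanol, "BLAC", config=cfg)
    hl = place_link_atoms(ethanol.structure, ethanol.region_map,
                          ethanol.link_specs)
    theta = bond_angle(hl.coords, 1, 2, 5)
    expected = (orig.k * (theta - orig.theta_eq) ** 2
                - new_k * (theta - new_t0) ** 2)
    assert blac.total - vlac.total == pytest.approx(expected, abs=1e-12)


def test_blac_j_rescaled_link_bond_cancels(ethanol):
    """The *J flavour: after substituting the junction bond's force constant
    on the CL side, rescaling the Q1-HL bond makes the junction bond drop out
    of the assembly entirely, so the total matches plain SUB_VLAC."""
    orig = [b for b in ethanol.topology.bonds
            if canonical_bond(b.i, b.j) == (2, 5)][0]
    cfg = SchemeConfig(scheme="BLAC",
                       blac_cl={("c3", "c3"): (orig.k * 2.5, orig.r_eq)},
                       blac_rescale_link=True)
    blac = _run(ethanol, "BLAC", config=cfg)
    vlac = _run(ethanol, "SUB_VLAC")
    assert blac.total == pytest.approx(vlac.total, abs=TIGHT)
    assert np.abs(blac.gradient - vlac.gradient).max() < TIGHT


def test_blac_unused_key_raises(ethanol):
    cfg = SchemeConfig(scheme="BLAC",
                       blac_hl={("zz", "zz"): (100.0, 1.0)})
    with pytest.raises(SchemeError):
        _run(ethanol, "BLAC", config=cfg)


def test_apply_blac_parameters_identity(ethanol):
    trunc, sys1 = build_truncated_topology(
        ethanol.topology, ethanol.region_map, ethanol.link_specs)
    t2, f2 = apply_blac_parameters(trunc, ethanol.topology)
    assert t2 is trunc and f2 is ethanol.topology


# ----------------------------------------------------------------------
# Gradients, degenerate regions, reporting, plumbing
# ----------------------------------------------------------------------

@pytest.mark.parametrize("scheme", SCHEMES)
def test_scheme_gradients_match_fd(ethanol, scheme):
    cfg = _me_config(ethanol, scheme) if scheme in ("ME", "ELAC") \
        else SchemeConfig(scheme=scheme)
    rep = _run(ethanol, scheme, config=cfg)

    def energy(s):
        return compute_scheme_energy(ethanol.topology, s, ethanol.region_map,
                                     ethanol.link_specs, cfg).total

    fd = fd_gradient(energy, ethanol.structure.coords)
    assert np.abs(rep.gradient - fd).max() < 1e-6


def test_empty_qm_region_is_plain_mm(ethanol):
    rm = RegionMap(n_atoms=9, qm_mask=np.zeros(9, dtype=bool), junctions=[])
    rep = compute_scheme_energy(ethanol.topology, ethanol.structure, rm, {},
                                SchemeConfig("ADD"))
    ref = mm_energy(ethanol.topology, ethanol.structure)
    assert rep.total == pytest.approx(ref.total, abs=TIGHT)
    assert np.abs(rep.gradient - ref.gradient).max() < TIGHT


def test_all_qm_region_is_bare_qm(ethanol):
    """With every atom QM there are no junctions, no point charges and no MM
    term: the total is exactly the backend's energy of the whole system."""
    rm = assign_regions(ethanol.topology, range(9))
    assert rm.junctions == []
    backend = SmoothTestBackend(9, seed=23)
    rep = compute_scheme_energy(ethanol.topology, ethanol.structure, rm, {},
                                SchemeConfig("ADD"), backend)
    bare = backend.evaluate(ethanol.structure, None)
    # the point-charge model is empty, so embedding adds nothing
    assert rep.total == pytest.approx(bare.energy, abs=TIGHT)


def test_scheme_aliases_and_entry_points(ethanol):
    assert SchemeConfig(scheme="sub-strict").scheme == "SUB_STRICT"
    assert SchemeConfig(scheme="Add").scheme == "ADD"
    with pytest.raises(SchemeError):
        SchemeConfig(scheme="nope")
    with pytest.raises(SchemeError):
        energy_subtractive(ethanol.topology, ethanol.structure,
                           ethanol.region_map, ethanol.link_specs,
                           variant="XXX")
    a = energy_additive(ethanol.topology, ethanol.structure,
                        ethanol.region_map, ethanol.link_specs)
    b = energy_subtractive(ethanol.topology, ethanol.structure,
                           ethanol.region_map, ethanol.link_specs,
                           variant="STRICT")
    assert abs(a.total - b.total) < TIGHT


def test_scheme_decomposition_render_and_recheck(ethanol):
    rep = _run(ethanol, "SUB_VLAC")
    text = scheme_decomposition(rep)
    assert "scheme: SUB_VLAC" in text
    assert "mm12" in text and "total" in text
    kj = scheme_decomposition(rep, units="kJ")
    assert "kJ/mol" in kj
    rep.total += 1.0      # corrupt the report: the renderer must notice
    with pytest.raises(SchemeError):
        scheme_decomposition(rep)


def test_report_kj_metadata(ethanol):
    rep = _run(ethanol, "ADD")
    assert rep.metadata["total_kJ_per_mol"] == \
        pytest.approx(rep.total * KCAL_PER_MOL_TO_KJ_PER_MOL, rel=1e-15)


def test_make_objective_shapes(ethanol):
    obj = make_objective(ethanol.topology, ethanol.region_map,
                         ethanol.link_specs, SchemeConfig("ADD"))
    flat = ethanol.structure.coords.ravel()
    e1, g1 = obj(flat)
    e2, g2 = obj(ethanol.structure.coords)
    assert e1 == e2
    assert g1.shape == (27,) and g2.shape == (9, 3)
    assert np.array_equal(g1, g2.ravel())


def test_structure_size_mismatch(ethanol):
    with pytest.raises(SchemeError):
        compute_scheme_energy(ethanol.topology, Structure(np.zeros((3, 3))),
                              ethanol.region_map, ethanol.link_specs,
                              SchemeConfig("ADD"))
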