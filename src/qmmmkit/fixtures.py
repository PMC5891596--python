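"""Self-contained test systems built from an embedded, versioned parameter set.

Everything is generated from code and the constants below — no downloads, no
external force-field distribution.  The parameter set mimics the magnitudes
of a general small-molecule force field (bond stretches of a few hundred
kcal/mol/A^2, tetrahedral angle bends near 109.5 degrees, threefold torsion
barriers well under 1 kcal/mol) but is a *toy*: its numbers are chosen for
plausibility and reproducibility, not transferability.  The hydroxyl
hydrogen type ``ho`` deliberately carries zero Lennard-Jones depth, the
convention of mainstream biomolecular force fields; it is what makes the van
der Waals link-atom correction vanish identically for the ethanol fixture.

Fixtures:

* ``ethanol_methanol`` — 9-atom ethanol whose QM region is the methanol
  fragment; one junction (Q1 = C1, CL = C2).  Carries the published MM and
  QM charge columns so the mechanical-embedding merge is checkable to the
  printed decimals.
* ``dipeptide_two_junctions`` — N-methylacetamide (NMA): QM = the amide
  core, both methyl carbons are CL atoms in the same residue, exercising the
  equal-split boundary-charge offset.
* ``bonded_cl_dithiolene_analogue`` — 1,2-dimethoxyethane (DME): QM = both
  methoxy groups plus the central carbons, making the two CL atoms
  covalently bonded (the discouraged junction type); the truncated system
  falls apart into two methanol-like fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .charges import ChargeSet
from .regions import LinkSpec, RegionMap, assign_regions, resolve_link_specs
from .topology import (
    Atom,
    AngleTerm,
    BondTerm,
    DihedralTerm,
    LJParam,
    Structure,
    Topology,
    bond_graph_distances,
    canonical_bond,
)

__all__ = [
    "FixtureError",
    "FixtureSpec",
    "Fixture",
    "FIXTURE_NAMES",
    "PARAM_SET_V1",
    "zmatrix_to_cartesian",
    "build_topology_from_bonds",
    "build_ethanol_fixture",
    "build_junction_stress_fixture",
    "build_fixture",
]

FIXTURE_NAMES = ("ethanol_methanol", "dipeptide_two_junctions",
                 "bonded_cl_dithiolene_analogue")


class FixtureError(ValueError):
    """Raised for unknown fixtures or missing parameters."""


# ----------------------------------------------------------------------
# Toy parameter set (version 1)
# ----------------------------------------------------------------------
# atom types: (element, mass, LJ rmin/2 [A], LJ epsilon [kcal/mol])
# bonds: (k [kcal/mol/A^2], r0 [A]); angles: (k [kcal/mol/rad^2], theta0 [deg])
# dihedrals: list of (height [kcal/mol], periodicity, phase [deg]);
#            "X" entries at both ends are wildcards.

PARAM_SET_V1 = {
    "version": "toy-1",
    "atom_types": {
        "c3": ("C", 12.011, 1.9080, 0.1094),   # sp3 carbon
        "c":  ("C", 12.011, 1.9080, 0.0860),   # carbonyl carbon
        "hc": ("H", 1.008, 1.4870, 0.0157),    # H on aliphatic carbon
        "h1": ("H", 1.008, 1.3870, 0.0157),    # H on carbon bonded to O/N
        "hn": ("H", 1.008, 0.6000, 0.0157),    # H on amide nitrogen
        "ho": ("H", 1.008, 0.0000, 0.0000),    # hydroxyl H: zero LJ depth
        "oh": ("O", 15.999, 1.7210, 0.2104),   # hydroxyl oxygen
        "os": ("O", 15.999, 1.6837, 0.1700),   # ether oxygen
        "o":  ("O", 15.999, 1.6612, 0.2100),   # carbonyl oxygen
        "n":  ("N", 14.007, 1.8240, 0.1700),   # amide nitrogen
    },
    "bonds": {
        ("c3", "c3"): (303.1, 1.535),
        ("c3", "hc"): (337.3, 1.092),
        ("c3", "h1"): (335.9, 1.093),
        ("c3", "oh"): (314.1, 1.426),
        ("oh", "ho"): (369.6, 0.974),
        ("c3", "os"): (301.5, 1.439),
        ("c3", "c"):  (328.3, 1.508),
        ("c", "o"):   (648.0, 1.214),
        ("c", "n"):   (427.6, 1.379),
        ("n", "hn"):  (403.2, 1.013),
        ("c3", "n"):  (330.6, 1.456),
    },
    "angles": {
        ("c3", "c3", "hc"): (46.37, 110.05),
        ("c3", "c3", "h1"): (46.36, 110.07),
        ("hc", "c3", "hc"): (39.43, 108.35),
        ("h1", "c3", "h1"): (39.18, 109.55),
        ("oh", "c3", "c3"): (67.72, 109.43),
        ("oh", "c3", "h1"): (60.99, 110.26),
        ("c3", "oh", "ho"): (47.09, 108.16),
        ("os", "c3", "h1"): (62.40, 109.78),
        ("c3", "os", "c3"): (62.47, 112.42),
        ("os", "c3", "c3"): (68.00, 107.97),
        ("hc", "c3", "c"):  (47.20, 109.68),
        ("c3", "c", "o"):   (68.03, 123.11),
        ("c3", "c", "n"):   (66.84, 115.15),
        ("o", "c", "n"):    (75.83, 122.03),
        ("c", "n", "c3"):   (63.88, 120.69),
        ("c", "n", "hn"):   (48.33, 118.46),
        ("c3", "n", "hn"):  (46.02, 117.68),
        ("n", "c3", "h1"):  (49.30, 109.50),
    },
    "dihedrals": {
        ("X", "c3", "oh", "X"): [(0.1667, 3, 0.0)],
        ("X", "c3", "c3", "X"): [(0.1556, 3, 0.0)],
        ("X", "c3", "os", "X"): [(0.3833, 3, 0.0)],
        ("X", "c", "n", "X"):   [(2.5000, 2, 180.0)],
        ("X", "c3", "c", "X"):  [(0.1000, 3, 0.0)],
        ("X", "c3", "n", "X"):  [(0.1500, 3, 0.0)],
    },
}


def _lookup_bond(params, t1, t2):
    table = params["bonds"]
    for key in ((t1, t2), (t2, t1)):
        if key in table:
            return table[key]
    raise FixtureError(f"no bond parameters for type tuple {(t1, t2)!r}")


def _lookup_angle(params, t1, t2, t3):
    table = params["angles"]
    for key in ((t1, t2, t3), (t3, t2, t1)):
        if key in table:
            return table[key]
    raise FixtureError(f"no angle parameters for type tuple {(t1, t2, t3)!r}")


def _lookup_dihedral(params, t1, t2, t3, t4):
    table = params["dihedrals"]
    for key in ((t1, t2, t3, t4), (t4, t3, t2, t1),
                ("X", t2, t3, "X"), ("X", t3, t2, "X")):
        if key in table:
            return table[key]
    raise FixtureError(
        f"no dihedral parameters for type tuple {(t1, t2, t3, t4)!r} "
        f"(wildcard ('X', {t2!r}, {t3!r}, 'X') also absent)")


# ----------------------------------------------------------------------
# Geometry: internal coordinates to Cartesian (NeRF placement)
# ----------------------------------------------------------------------

def zmatrix_to_cartesian(entries) -> np.ndarray:
    """Place atoms from internal coordinates.

    Each entry is ``(bond_ref, r, angle_ref, theta_deg, dihedral_ref,
    phi_deg)`` with ``None`` for the references an early atom does not have:
    the first atom is all-``None``, the second needs only ``bond_ref``/``r``,
    the third additionally the angle.  References must point at already
    placed atoms.
    """
    n = len(entries)
    coords = np.zeros((n, 3))
    for idx, entry in enumerate(entries):
        c, r, b, theta, a, phi = entry
        if idx == 0:
            continue
        if idx == 1:
            coords[idx] = coords[c] + np.array([r, 0.0, 0.0])
            continue
        th = math.radians(theta)
        if idx == 2 or a is None:
            ref = coords[b] - coords[c]
            ref /= np.linalg.norm(ref)
            # rotate within the xy-plane
            perp = np.array([-ref[1], ref[0], 0.0])
            if np.linalg.norm(perp) < 1e-10:
                perp = np.array([0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            coords[idx] = coords[c] + r * (math.cos(th) * ref
                                           + math.sin(th) * perp)
            continue
        ph = math.radians(phi)
        bc = coords[c] - coords[b]
        bc /= np.linalg.norm(bc)
        ab = coords[b] - coords[a]
        nvec = np.cross(ab, bc)
        norm = np.linalg.norm(nvec)
        if norm < 1e-10:
            raise FixtureError(
                f"collinear dihedral reference atoms for placement of atom {idx}")
        nvec /= norm
        mvec = np.cross(nvec, bc)
        d_local = np.array([-r * math.cos(th),
                            r * math.sin(th) * math.cos(ph),
                            r * math.sin(th) * math.sin(ph)])
        coords[idx] = coords[c] + (d_local[0] * bc + d_local[1] * mvec
                                   + d_local[2] * nvec)
    return coords


# ----------------------------------------------------------------------
# Topology construction from a bond list
# ----------------------------------------------------------------------

def build_topology_from_bonds(
    names, types, charges, bonds, params=PARAM_SET_V1,
    residue_indices=None, residue_labels=None, title="",
    extra_lj_types=(),
) -> Topology:
    """Assemble a full topology: angles and dihedrals are auto-enumerated
    from the bond list and parametrized from ``params`` (exact type tuple
    first, then the wildcard dihedral); exclusions and 1-4 pairs follow the
    bond-graph distances.
    """
    n = len(names)
    atom_types = params["atom_types"]
    for t in types:
        if t not in atom_types:
            raise FixtureError(f"unknown atom type {t!r}")
    if residue_indices is None:
        residue_indices = [0] * n
    if residue_labels is None:
        residue_labels = [title[:3].upper() or "MOL"] * n

    atoms = [Atom(name=names[i], element=atom_types[types[i]][0],
                  type_label=types[i], mass=atom_types[types[i]][1],
                  charge=float(charges[i]), residue_index=residue_indices[i],
                  residue_label=residue_labels[i]) for i in range(n)]
    lj = {t: LJParam(rmin_half=atom_types[t][2], epsilon=atom_types[t][3])
          for t in sorted(set(types) | set(extra_lj_types))}

    nbrs: dict[int, list[int]] = {i: [] for i in range(n)}
    bond_terms = []
    for (i, j) in bonds:
        i, j = canonical_bond(int(i), int(j))
        k, r0 = _lookup_bond(params, types[i], types[j])
        bond_terms.append(BondTerm(i, j, k, r0))
        nbrs[i].append(j)
        nbrs[j].append(i)

    angle_terms = []
    for j in range(n):
        partners = sorted(nbrs[j])
        for x in range(len(partners)):
            for y in range(x + 1, len(partners)):
                i, k = partners[x], partners[y]
                ak, th0 = _lookup_angle(params, types[i], types[j], types[k])
                angle_terms.append(AngleTerm(i, j, k, ak, math.radians(th0)))

    dihedral_terms = []
    for b in bond_terms:
        j, k = b.i, b.j
        for i in sorted(nbrs[j]):
            if i == k:
                continue
            for l in sorted(nbrs[k]):
                if l == j or l == i:
                    continue
                for height, per, phase in _lookup_dihedral(
                        params, types[i], types[j], types[k], types[l]):
                    dihedral_terms.append(DihedralTerm(
                        i, j, k, l, height=height, periodicity=per,
                        phase=math.radians(phase)))

    dist = bond_graph_distances(n, bond_terms, max_dist=3)
    exclusions = {p for p, d in dist.items() if d <= 2}
    pairs14 = {p: (1.2, 2.0) for p, d in dist.items() if d == 3}
    return Topology(atoms=atoms, lj=lj, bonds=bond_terms, angles=angle_terms,
                    dihedrals=dihedral_terms, exclusions=exclusions,
                    pairs14=pairs14, title=title)


# ----------------------------------------------------------------------
# Fixture objects
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    name: str
    seed: int = 0
    param_version: str = "toy-1"

    def __post_init__(self) -> None:
        if self.name not in FIXTURE_NAMES:
            raise FixtureError(
                f"unknown fixture {self.name!r}; choose from {FIXTURE_NAMES}")
        if self.param_version != PARAM_SET_V1["version"]:
            raise FixtureError(
                f"unknown parameter-set version {self.param_version!r}")


@dataclass
class Fixture:
    spec: FixtureSpec
    topology: Topology
    structure: Structure
    region_map: RegionMap
    link_specs: dict[int, LinkSpec]
    mm_charges: ChargeSet
    qm_charges: ChargeSet
    unit_partition: list[int] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.spec.name


_JITTER_SCALE = 0.01  # A; breaks exact symmetries so gradients are generic


def _jitter(coords: np.ndarray, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return coords + rng.normal(0.0, _JITTER_SCALE, size=coords.shape)


# ---------------------------- ethanol / methanol ----------------------

#: Published charge columns for the ethanol/methanol example (e).
ETHANOL_MM_CHARGES = {   # ethanol "Set1"
    "HO": 0.3570, "O": -0.5847, "C1": 0.3841, "H11": -0.0534,
    "H12": -0.0534, "C2": -0.2324, "H21": 0.0609, "H22": 0.0609,
    "H23": 0.0609,
}
METHANOL_QM_CHARGES = {  # methanol column; HL is the link atom replacing C2
    "HO": 0.3977, "O": -0.5903, "C1": 0.2120, "H11": -0.0043,
    "H12": -0.0043, "HL": -0.0108,
}
ETHANOL_MERGED_CHARGES = {  # "Set2": the expected mechanical-embedding merge
    "HO": 0.3977, "O": -0.5903, "C1": 0.2120, "H11": -0.0043,
    "H12": -0.0043, "C2": -0.1935, "H21": 0.0609, "H22": 0.0609,
    "H23": 0.0609,
}


def build_ethanol_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Ethanol with the methanol fragment as QM region (CL = C2, Q1 = C1)."""
    spec = spec or FixtureSpec("ethanol_methanol")
    names = ["HO", "O", "C1", "H11", "H12", "C2", "H21", "H22", "H23"]
    types = ["ho", "oh", "c3", "h1", "h1", "c3", "hc", "hc", "hc"]
    bonds = [(0, 1), (1, 2), (2, 3), (2, 4), (2, 5), (5, 6), (5, 7), (5, 8)]
    mm_q = [ETHANOL_MM_CHARGES[nm] for nm in names]
    topology = build_topology_from_bonds(
        names, types, mm_q, bonds, residue_labels=["EOH"] * 9, title="ethanol")

    zmat = [
        (None, None, None, None, None, None),             # HO
        (0, 0.974, None, None, None, None),               # O
        (1, 1.426, 0, 108.16, None, None),                # C1
        (2, 1.093, 1, 110.26, 0, 60.0),                   # H11
        (2, 1.093, 1, 110.26, 0, -60.0),                  # H12
        (2, 1.535, 1, 109.43, 0, 180.0),                  # C2
        (5, 1.092, 2, 110.05, 1, 180.0),                  # H21
        (5, 1.092, 2, 110.05, 1, 60.0),                   # H22
        (5, 1.092, 2, 110.05, 1, -60.0),                  # H23
    ]
    structure = Structure(_jitter(zmatrix_to_cartesian(zmat), spec.seed))

    region_map = assign_regions(topology, range(6))  # HO..C2; CL = C2
    link_specs = resolve_link_specs(topology, region_map, r0_hl={5: 1.090},
                                    hl_type="hc")
    qm_vals = np.zeros(9)
    for i, nm in enumerate(names):
        if nm in METHANOL_QM_CHARGES:
            qm_vals[i] = METHANOL_QM_CHARGES[nm]
    mm_charges = ChargeSet(np.array(mm_q), provenance="mm_original")
    qm_charges = ChargeSet(qm_vals, provenance="qm_derived",
                           hl_charges={5: METHANOL_QM_CHARGES["HL"]})
    return Fixture(spec=spec, topology=topology, structure=structure,
                   region_map=region_map, link_specs=link_specs,
                   mm_charges=mm_charges, qm_charges=qm_charges,
                   unit_partition=[a.residue_index for a in topology.atoms])


# ---------------------------- N-methylacetamide -----------------------

def _build_nma_fixture(spec: FixtureSpec) -> Fixture:
    """NMA with QM = amide core; both methyl carbons are CL atoms (one unit)."""
    names = ["CT1", "HT1A", "HT1B", "HT1C", "C", "O", "N", "HN",
             "CT2", "HT2A", "HT2B", "HT2C"]
    types = ["c3", "hc", "hc", "hc", "c", "o", "n", "hn",
             "c3", "h1", "h1", "h1"]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (4, 5), (4, 6), (6, 7),
             (6, 8), (8, 9), (8, 10), (8, 11)]
    mm_q = [-0.30, 0.10, 0.10, 0.10, 0.55, -0.55, -0.40, 0.30,
            -0.14, 0.08, 0.08, 0.08]
    topology = build_topology_from_bonds(
        names, types, mm_q, bonds, residue_labels=["NMA"] * 12, title="nma")

    zmat = [
        (None, None, None, None, None, None),             # CT1
        (0, 1.092, None, None, None, None),               # HT1A
        (0, 1.092, 1, 108.35, None, None),                # HT1B
        (0, 1.092, 1, 108.35, 2, 120.0),                  # HT1C
        (0, 1.508, 1, 109.68, 2, -120.0),                 # C
        (4, 1.214, 0, 123.11, 1, 30.0),                   # O
        (4, 1.379, 5, 122.03, 0, 180.0),                  # N
        (6, 1.013, 4, 118.46, 5, 180.0),                  # HN
        (6, 1.456, 4, 120.69, 7, 180.0),                  # CT2
        (8, 1.093, 6, 109.50, 4, 180.0),                  # HT2A
        (8, 1.093, 6, 109.50, 4, 60.0),                   # HT2B
        (8, 1.093, 6, 109.50, 4, -60.0),                  # HT2C
    ]
    structure = Structure(_jitter(zmatrix_to_cartesian(zmat), spec.seed))

    region_map = assign_regions(topology, [0, 4, 5, 6, 7, 8])
    # CL = CT1 (Q1 = C, H link at a C-H distance) and CT2 (Q1 = N, N-H)
    link_specs = resolve_link_specs(
        topology, region_map, r0_hl={0: 1.090, 8: 1.010},
        hl_type={0: "hc", 8: "hn"})
    qm_vals = np.zeros(12)
    for idx, q in ((4, 0.52), (5, -0.53), (6, -0.42), (7, 0.31)):
        qm_vals[idx] = q
    mm_charges = ChargeSet(np.array(mm_q, dtype=float), provenance="mm_original")
    qm_charges = ChargeSet(qm_vals, provenance="qm_derived",
                           hl_charges={0: 0.05, 8: 0.07})
    return Fixture(spec=spec, topology=topology, structure=structure,
                   region_map=region_map, link_specs=link_specs,
                   mm_charges=mm_charges, qm_charges=qm_charges,
                   unit_partition=[a.residue_index for a in topology.atoms])


# ---------------------------- dimethoxyethane -------------------------

def _build_dme_fixture(spec: FixtureSpec) -> Fixture:
    """DME with QM = both methoxy groups + central carbons: bonded CL pair.

    The central CH2 carbons are both boundary atoms and are covalently
    bonded to each other, mirroring the published dithiolene complication;
    the truncated system splits into two methanol-like fragments.
    """
    names = ["C1", "H1A", "H1B", "H1C", "O1", "C2", "H2A", "H2B",
             "C3", "H3A", "H3B", "O2", "C4", "H4A", "H4B", "H4C"]
    types = ["c3", "h1", "h1", "h1", "os", "c3", "h1", "h1",
             "c3", "h1", "h1", "os", "c3", "h1", "h1", "h1"]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (4, 5), (5, 6), (5, 7),
             (5, 8), (8, 9), (8, 10), (8, 11), (11, 12),
             (12, 13), (12, 14), (12, 15)]
    mm_q = [0.11, 0.03, 0.03, 0.03, -0.40, 0.10, 0.05, 0.05,
            0.10, 0.05, 0.05, -0.40, 0.11, 0.03, 0.03, 0.03]
    topology = build_topology_from_bonds(
        names, types, mm_q, bonds, residue_labels=["DME"] * 16, title="dme",
        extra_lj_types=("ho",))  # the link atoms are hydroxyl-like hydrogens

    zmat = [
        (None, None, None, None, None, None),             # C1
        (0, 1.093, None, None, None, None),               # H1A
        (0, 1.093, 1, 109.55, None, None),                # H1B
        (0, 1.093, 1, 109.55, 2, 120.0),                  # H1C
        (0, 1.439, 1, 109.78, 2, -120.0),                 # O1
        (4, 1.439, 0, 112.42, 1, 180.0),                  # C2
        (5, 1.093, 4, 109.78, 0, 60.0),                   # H2A
        (5, 1.093, 4, 109.78, 0, -60.0),                  # H2B
        (5, 1.535, 4, 107.97, 0, 180.0),                  # C3
        (8, 1.093, 5, 110.07, 4, 60.0),                   # H3A
        (8, 1.093, 5, 110.07, 4, -60.0),                  # H3B
        (8, 1.439, 5, 107.97, 4, 180.0),                  # O2
        (11, 1.439, 8, 112.42, 5, 180.0),                 # C4
        (12, 1.093, 11, 109.78, 8, 180.0),                # H4A
        (12, 1.093, 11, 109.78, 8, 60.0),                 # H4B
        (12, 1.093, 11, 109.78, 8, -60.0),                # H4C
    ]
    structure = Structure(_jitter(zmatrix_to_cartesian(zmat), spec.seed))

    region_map = assign_regions(topology, [0, 1, 2, 3, 4, 5, 8, 11, 12, 13, 14, 15])
    # CL = C2 (Q1 = O1) and C3 (Q1 = O2); each link atom is a hydroxyl-like H
    link_specs = resolve_link_specs(
        topology, region_map, r0_hl={5: 0.960, 8: 0.960}, hl_type="ho")
    qm_vals = np.zeros(16)
    for idx, q in ((0, 0.12), (1, 0.04), (2, 0.04), (3, 0.04), (4, -0.43),
                   (11, -0.43), (12, 0.12), (13, 0.04), (14, 0.04), (15, 0.04)):
        qm_vals[idx] = q
    mm_charges = ChargeSet(np.array(mm_q, dtype=float), provenance="mm_original")
    qm_charges = ChargeSet(qm_vals, provenance="qm_derived",
                           hl_charges={5: 0.19, 8: 0.19})
    return Fixture(spec=spec, topology=topology, structure=structure,
                   region_map=region_map, link_specs=link_specs,
                   mm_charges=mm_charges, qm_charges=qm_charges,
                   unit_partition=[a.residue_index for a in topology.atoms])


def build_junction_stress_fixture(spec: FixtureSpec) -> Fixture:
    """Either stress variant: two junctions in one unit, or a bonded CL pair."""
    if spec.name == "dipeptide_two_junctions":
        return _build_nma_fixture(spec)
    if spec.name == "bonded_cl_dithiolene_analogue":
        return _build_dme_fixture(spec)
    raise FixtureError(f"{spec.name!r} is not a junction-stress fixture")


def build_fixture(name: str, seed: int = 0) -> Fixture:
    """Build any fixture by name."""
    spec = FixtureSpec(name, seed=seed)
    if name == "ethanol_methanol":
        return build_ethanol_fixture(spec)
    return build_junction_stress_fixture(spec)
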