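"""QM/MM partitioning, hydrogen link atoms and truncated-topology generation.

Terminology (the conventions of link-atom QM/MM): the QM region is *system
1* and the MM environment *system 2*.  A covalent bond crossing the boundary
defines a *junction* (Q1, CL): CL is the boundary atom that still belongs to
system 1 but is replaced by a hydrogen link atom (HL) in every QM
calculation, and Q1 is the single QM atom it stays bonded to.  HL and CL are
two representations of the same atom and never appear in the same
calculation.  Neighbour shells are named Q2/Q3 (bonded outwards from Q1
inside the QM region) and M2 (MM atoms bonded to CL).

The HL atom sits on the Q1->CL ray::

    r_HL = r_Q1 + g (r_CL - r_Q1),      g = r0(Q1-HL) / r0(Q1-CL)

with r0(Q1-CL) the force-field equilibrium length and r0(Q1-HL) the
QM-optimised bond length of the truncated model (a user input).  Because g
is a constant, HL introduces no degrees of freedom and the force on HL maps
back onto Q1 and CL by a fixed linear chain rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .topology import (
    Atom,
    BondTerm,
    Structure,
    Topology,
    TopologyError,
    bond_graph_distances,
    canonical_bond,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegionError",
    "Junction",
    "RegionMap",
    "LinkSpec",
    "assign_regions",
    "resolve_link_specs",
    "place_link_atoms",
    "project_link_gradient",
    "scale_link_force_constant",
    "build_truncated_topology",
]

HL_MASS = 1.008


class RegionError(ValueError):
    """Raised when a QM selection cannot be resolved into valid junctions."""


@dataclass(frozen=True)
class Junction:
    q1: int                      # QM anchor atom
    cl: int                      # boundary atom (in the QM region)
    m2: tuple[int, ...] = ()     # MM atoms bonded to CL
    q2: tuple[int, ...] = ()     # QM atoms bonded to Q1 (other than CL)
    q3: tuple[int, ...] = ()     # QM atoms bonded to any Q2 (excluding Q1)


@dataclass
class RegionMap:
    """Per-atom QM/MM assignment plus the junction list."""

    n_atoms: int
    qm_mask: np.ndarray                       # bool, True = system 1 (incl. CL)
    junctions: list[Junction]
    bonded_cl_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return ["QM" if q else "MM" for q in self.qm_mask]

    @property
    def qm_indices(self) -> list[int]:
        return [i for i in range(self.n_atoms) if self.qm_mask[i]]

    @property
    def mm_indices(self) -> list[int]:
        return [i for i in range(self.n_atoms) if not self.qm_mask[i]]

    @property
    def cl_indices(self) -> list[int]:
        return [j.cl for j in self.junctions]

    def junction_for_cl(self, cl: int) -> Junction:
        for j in self.junctions:
            if j.cl == cl:
                return j
        raise KeyError(f"no junction with CL atom {cl}")


@dataclass(frozen=True)
class LinkSpec:
    """Geometric and parametric data for one junction.

    ``r0_hl`` is the ideal Q1-HL bond length (from a QM optimisation of the
    truncated model, supplied by the user), ``r0_cl`` the force-field
    equilibrium Q1-CL length.  ``hl_type`` names the LJ atom type of the
    link hydrogen; ``hl_charge`` is the QM-derived HL charge used by
    mechanical embedding and the electrostatic link-atom correction.
    """

    r0_hl: float
    r0_cl: float
    hl_type: str = "hc"
    hl_charge: float | None = None

    def __post_init__(self) -> None:
        if self.r0_hl <= 0 or self.r0_cl <= 0:
            raise ValueError("ideal bond lengths must be positive")
        if not (0.0 < self.g < 1.0):
            logger.warning(
                "link scale ratio g=%.3f outside (0, 1); HL is usually closer "
                "to Q1 than CL", self.g)

    @property
    def g(self) -> float:
        """Geometry-independent scale ratio r0_hl / r0_cl."""
        return self.r0_hl / self.r0_cl


def assign_regions(topology: Topology, qm_atom_selection) -> RegionMap:
    """Partition atoms into QM (system 1, including CL) and MM (system 2).

    Boundary CL atoms are auto-detected as QM atoms bonded to at least one
    MM atom; each must have exactly one QM neighbour that is not itself a CL
    atom (its Q1).  Covalently bonded CL pairs are allowed but flagged with
    a warning, since such junctions are discouraged.
    """
    n = topology.n_atoms
    sel = sorted(set(int(i) for i in qm_atom_selection))
    if not sel:
        raise RegionError("QM selection is empty")
    if sel[0] < 0 or sel[-1] >= n:
        raise RegionError(f"QM selection index out of range: {sel[0]}..{sel[-1]}")
    qm_mask = np.zeros(n, dtype=bool)
    qm_mask[sel] = True

    nbrs = topology.bonded_neighbors()
    cl_atoms = [i for i in sel if any(not qm_mask[j] for j in nbrs[i])]
    cl_set = set(cl_atoms)

    junctions: list[Junction] = []
    for cl in cl_atoms:
        q_neighbors = [j for j in nbrs[cl] if qm_mask[j] and j not in cl_set]
        if len(q_neighbors) != 1:
            raise RegionError(
                f"boundary atom {cl} ({topology.atoms[cl].name}) must have exactly "
                f"one QM neighbour outside the boundary set, found {len(q_neighbors)}"
            )
        q1 = q_neighbors[0]
        if q1 in cl_set:
            raise RegionError(f"junction whose Q1 atom {q1} is itself a boundary atom")
        m2 = tuple(sorted(j for j in nbrs[cl] if not qm_mask[j]))
        q2 = tuple(sorted(j for j in nbrs[q1] if qm_mask[j] and j != cl))
        q3 = tuple(sorted({
            k for j in q2 for k in nbrs[j] if qm_mask[k] and k != q1
        }))
        junctions.append(Junction(q1=q1, cl=cl, m2=m2, q2=q2, q3=q3))

    bonded_cl_pairs = []
    for b in topology.bonds:
        if b.i in cl_set and b.j in cl_set:
            bonded_cl_pairs.append(canonical_bond(b.i, b.j))
    if bonded_cl_pairs:
        logger.warning(
            "covalently connected boundary (CL) atoms detected %s; such "
            "junctions are discouraged — cross-junction bonded terms will be "
            "removed", bonded_cl_pairs)
    return RegionMap(n_atoms=n, qm_mask=qm_mask, junctions=junctions,
                     bonded_cl_pairs=bonded_cl_pairs)


def _find_link_bond(topology: Topology, q1: int, cl: int) -> BondTerm:
    for b in topology.bonds:
        if canonical_bond(b.i, b.j) == canonical_bond(q1, cl):
            return b
    raise RegionError(f"no bond term between Q1 {q1} and CL {cl}")


def resolve_link_specs(
    topology: Topology,
    region_map: RegionMap,
    r0_hl: dict[int, float],
    hl_type: dict[int, str] | str = "hc",
    hl_charge: dict[int, float] | None = None,
) -> dict[int, LinkSpec]:
    """Build one :class:`LinkSpec` per junction, keyed by CL atom index.

    ``r0_hl`` maps CL index to the ideal Q1-HL length; ``r0_cl`` is looked up
    in the force field (the Q1-CL bond's equilibrium value).
    """
    specs: dict[int, LinkSpec] = {}
    for jn in region_map.junctions:
        bond = _find_link_bond(topology, jn.q1, jn.cl)
        try:
            r0 = r0_hl[jn.cl]
        except KeyError:
            raise RegionError(f"no ideal Q1-HL bond length given for CL atom {jn.cl}")
        ht = hl_type if isinstance(hl_type, str) else hl_type[jn.cl]
        hc = None if hl_charge is None else hl_charge.get(jn.cl)
        specs[jn.cl] = LinkSpec(r0_hl=r0, r0_cl=bond.r_eq, hl_type=ht, hl_charge=hc)
    return specs


def place_link_atoms(
    structure: Structure,
    region_map: RegionMap,
    link_specs: dict[int, LinkSpec],
) -> Structure:
    """Coordinates of system 1 in the HL representation.

    Returns a structure over the system-1 atoms (original order) where each
    CL slot holds its HL position ``Q1 + g (CL - Q1)``.  HL is colinear with
    the Q1->CL bond by construction and adds no degrees of freedom.
    """
    coords = structure.coords
    sys1 = region_map.qm_indices
    out = coords[sys1].copy()
    slot = {a: s for s, a in enumerate(sys1)}
    for jn in region_map.junctions:
        spec = link_specs[jn.cl]
        vec = coords[jn.cl] - coords[jn.q1]
        if float(vec @ vec) < 1e-20:
            raise RegionError(f"zero-length Q1-CL vector at junction (Q1={jn.q1}, CL={jn.cl})")
        out[slot[jn.cl]] = coords[jn.q1] + spec.g * vec
    return Structure(out)


def project_link_gradient(
    gradient_with_hl: np.ndarray,
    region_map: RegionMap,
    link_specs: dict[int, LinkSpec],
) -> np.ndarray:
    """Chain-rule a system-1 (HL representation) gradient onto real atoms.

    With ``HL = Q1 + g (CL - Q1)`` and constant g, a force on HL splits as
    ``dE/dCL += g dE/dHL`` and ``dE/dQ1 += (1 - g) dE/dHL``.  Input and
    output are over the system-1 atom slots (original ordering); the CL slot
    of the output refers to the real CL atom.
    """
    sys1 = region_map.qm_indices
    grad = np.asarray(gradient_with_hl, dtype=float).reshape(len(sys1), 3).copy()
    slot = {a: s for s, a in enumerate(sys1)}
    for jn in region_map.junctions:
        g = link_specs[jn.cl].g
        ghl = grad[slot[jn.cl]].copy()
        grad[slot[jn.cl]] = g * ghl
        grad[slot[jn.q1]] += (1.0 - g) * ghl
    return grad


def scale_link_force_constant(k_cl: float, r0_cl: float, r0_hl: float) -> float:
    """Force constant of the Q1-HL bond that preserves the bond energy.

    With HL placed at ``g`` times the current Q1-CL length (g = r0_hl/r0_cl),
    ``k_hl (g r - r0_hl)^2 = k_cl (r - r0_cl)^2`` for every r requires

    ``k_hl = k_cl (r0_cl / r0_hl)^2``.

    Any other choice (including the inverted ratio) introduces a spurious
    force at the junction.
    """
    if k_cl <= 0 or r0_cl <= 0 or r0_hl <= 0:
        raise ValueError("force constant and bond lengths must be positive")
    return k_cl * (r0_cl / r0_hl) ** 2


def _crosses_bonded_cl_pair(atoms: tuple[int, ...], pairs: list[tuple[int, int]]) -> bool:
    s = set(atoms)
    return any(i in s and j in s for (i, j) in pairs)


def build_truncated_topology(
    full_topology: Topology,
    region_map: RegionMap,
    link_specs: dict[int, LinkSpec],
    charges: str = "zero",
    qm_charges=None,
    link_representation: str = "HL",
) -> tuple[Topology, list[int]]:
    """Topology of system 1 with boundary atoms converted to link atoms.

    This is the automated truncated-topology generation: read the topology
    of the full system and emit the topology used for the MM calculation of
    the QM system, with no hand-built parameters.

    Rules (HL representation):

    * atoms: exactly system 1, original order; each CL becomes an HL
      (element H, mass 1.008, LJ type ``link_specs[cl].hl_type``);
    * bonded terms: every term of the full topology whose atoms all lie in
      system 1.  The Q1-HL bond gets ``r_eq = r0_hl`` and the force constant
      of :func:`scale_link_force_constant`; angles and dihedrals involving
      the boundary atom keep the corresponding ...-CL parameters unchanged;
    * covalently bonded CL pairs: the CL-CL bond and every angle/dihedral
      containing both atoms are removed.  Their nonbonded exclusions are
      kept (see below);
    * nonbonded bookkeeping: pairs are classified by their FULL-system bond
      graph distance, so intra-QM pair scaling is identical in full and
      truncated evaluations (this is what makes the van der Waals link-atom
      difference, and nothing else, survive the subtraction);
    * charges: ``'zero'`` (electrostatic-embedding variant: the truncated
      system carries no electrostatics), ``'keep'`` (original MM charges) or
      ``'qm'`` (QM-derived charges from ``qm_charges`` over the full-system
      indices, with each HL slot taking the link spec's ``hl_charge``).

    With ``link_representation='CL'`` boundary atoms keep their identity and
    parameters; this realises the strict-subtractive reference in which the
    small MM term uses CL atoms, coordinates and parameters.

    Returns (topology, index_map) where ``index_map[s]`` is the full-system
    index of truncated slot ``s``.
    """
    if link_representation not in ("HL", "CL"):
        raise ValueError("link_representation must be 'HL' or 'CL'")
    use_hl = link_representation == "HL"
    sys1 = region_map.qm_indices
    slot = {a: s for s, a in enumerate(sys1)}
    cl_set = set(region_map.cl_indices)
    for jn in region_map.junctions:
        if jn.q1 in cl_set:
            raise TopologyError(
                f"unsupported topology: Q1 atom {jn.q1} is itself a boundary atom")

    hl_counter = 0
    atoms: list[Atom] = []
    for a_idx in sys1:
        a = full_topology.atoms[a_idx]
        if use_hl and a_idx in cl_set:
            hl_counter += 1
            spec = link_specs[a_idx]
            if spec.hl_type not in full_topology.lj:
                raise TopologyError(
                    f"missing LJ parameters for link-atom type {spec.hl_type!r}")
            if charges == "zero":
                q = 0.0
            elif charges == "keep":
                q = a.charge
            else:
                if spec.hl_charge is None:
                    raise TopologyError(
                        f"link-atom charge needed for CL atom {a_idx} but not set")
                q = spec.hl_charge
            atoms.append(Atom(
                name=f"HL{hl_counter}" if len(cl_set) > 1 else "HL",
                element="H", type_label=spec.hl_type, mass=HL_MASS, charge=q,
                residue_index=a.residue_index, residue_label=a.residue_label))
        else:
            if charges == "zero":
                q = 0.0
            elif charges == "keep":
                q = a.charge
            else:
                if qm_charges is None:
                    raise TopologyError("charges='qm' requires a qm_charges mapping")
                q = float(np.asarray(getattr(qm_charges, "values", qm_charges))[a_idx]) \
                    if not isinstance(qm_charges, dict) else qm_charges[a_idx]
            atoms.append(replace(a, charge=q))

    link_bonds = {canonical_bond(j.q1, j.cl): j for j in region_map.junctions}
    bcp = region_map.bonded_cl_pairs

    bonds: list[BondTerm] = []
    for b in full_topology.bonds:
        if b.i not in slot or b.j not in slot:
            continue
        if _crosses_bonded_cl_pair((b.i, b.j), bcp):
            continue
        key = canonical_bond(b.i, b.j)
        if use_hl and key in link_bonds:
            jn = link_bonds[key]
            spec = link_specs[jn.cl]
            bonds.append(BondTerm(
                slot[key[0]], slot[key[1]],
                scale_link_force_constant(b.k, b.r_eq, spec.r0_hl),
                spec.r0_hl))
        else:
            bonds.append(replace(b, i=slot[b.i], j=slot[b.j]))

    angles = []
    for a in full_topology.angles:
        ats = (a.i, a.j, a.k_atom)
        if not all(x in slot for x in ats):
            continue
        if _crosses_bonded_cl_pair(ats, bcp):
            continue
        angles.append(replace(a, i=slot[a.i], j=slot[a.j], k_atom=slot[a.k_atom]))
    dihedrals = []
    for d in full_topology.dihedrals:
        ats = (d.i, d.j, d.k_atom, d.l)
        if not all(x in slot for x in ats):
            continue
        if _crosses_bonded_cl_pair(ats, bcp):
            continue
        dihedrals.append(replace(d, i=slot[d.i], j=slot[d.j],
                                 k_atom=slot[d.k_atom], l=slot[d.l]))

    lj = dict(full_topology.lj)

    # Nonbonded classification from the FULL bond graph, restricted to
    # system-1 pairs: scaling classes then match the full-system evaluation
    # exactly, including across removed CL-CL bonds (which stay excluded)
    # and, pathologically, paths running through the MM region.
    dist = bond_graph_distances(full_topology.n_atoms, full_topology.bonds, max_dist=3)
    exclusions: set[tuple[int, int]] = set()
    pairs14: dict[tuple[int, int], tuple[float, float]] = {}
    for (i, j), d in dist.items():
        if i in slot and j in slot:
            p = canonical_bond(slot[i], slot[j])
            if d <= 2:
                exclusions.add(p)
            else:
                pairs14[p] = full_topology.pairs14.get(
                    (i, j), (full_topology.scee_default, full_topology.scnb_default))

    top = Topology(
        atoms=atoms, lj=lj, bonds=bonds, angles=angles, dihedrals=dihedrals,
        exclusions=exclusions, pairs14=pairs14,
        scee_default=full_topology.scee_default,
        scnb_default=full_topology.scnb_default,
        title=f"truncated system 1 ({link_representation} representation)",
    )
    return top, sys1
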