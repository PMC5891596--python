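"""Molecular-mechanics topologies: data model, validation and file I/O.

A :class:`Topology` is the single source of truth for force-field parameters
and connectivity of one system (either the full system or a truncated QM
system).  Two on-disk dialects are supported:

* the AMBER parameter--topology ("prmtop") format, and
* a native plain-text key--value format (exact round trip, one section per
  term class; see :func:`write_native` for the layout).

Coordinates are handled by :class:`Structure` with readers/writers for XYZ
and AMBER restart (inpcrd) files.

Conventions
-----------
* Atom indexing is 0-based internally; prmtop's 1-based/``3*i`` pointer
  conventions are converted at the I/O boundary.
* Harmonic bonds and angles use the AMBER convention *without* the 1/2
  factor: ``E = K (x - x0)**2``.
* Charges are stored in electron charges (prmtop's 18.2223 scaling is
  removed on read and re-applied on write).
* Nonbonded bookkeeping is explicit: ``exclusions`` holds the fully excluded
  pairs (normally 1-2 and 1-3) and ``pairs14`` maps each scaled 1-4 pair to
  its (scee, scnb) divisors.  :func:`rebuild_nonbonded_lists` regenerates
  both from the bond graph.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .units import DEFAULT_SCEE, DEFAULT_SCNB, PRMTOP_CHARGE_SCALE

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "LJParam",
    "Topology",
    "Structure",
    "TopologyError",
    "canonical_bond",
    "canonical_angle",
    "canonical_dihedral",
    "bond_graph_distances",
    "rebuild_nonbonded_lists",
    "validate_topology",
    "read_prmtop",
    "write_prmtop",
    "read_native",
    "write_native",
    "read_topology",
    "write_topology",
    "read_xyz",
    "write_xyz",
    "read_inpcrd",
    "write_inpcrd",
]


class TopologyError(ValueError):
    """Raised for parse and validation failures of topology files."""


# Masses used to guess elements when a file carries no atomic numbers.
_ELEMENT_BY_ROUNDED_MASS = {
    1: "H", 4: "He", 7: "Li", 11: "B", 12: "C", 14: "N", 16: "O",
    19: "F", 23: "Na", 24: "Mg", 28: "Si", 31: "P", 32: "S", 35: "Cl",
    39: "K", 40: "Ca", 56: "Fe", 64: "Cu", 65: "Zn", 80: "Br", 96: "Mo",
    127: "I",
}

_ATOMIC_NUMBER = {
    "H": 1, "He": 2, "Li": 3, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9,
    "Na": 11, "Mg": 12, "Si": 14, "P": 15, "S": 16, "Cl": 17, "K": 19,
    "Ca": 20, "Fe": 26, "Cu": 29, "Zn": 30, "Br": 35, "Mo": 42, "I": 53,
}


def element_from_mass(mass: float) -> str:
    return _ELEMENT_BY_ROUNDED_MASS.get(int(round(mass)), "X")


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    type_label: str
    mass: float          # amu
    charge: float        # e
    residue_index: int   # 0-based
    residue_label: str


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k: float       # kcal/mol/A^2, E = k (r - r_eq)^2
    r_eq: float    # A


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k_atom: int
    k: float        # kcal/mol/rad^2, E = k (theta - theta_eq)^2
    theta_eq: float  # rad


@dataclass(frozen=True)
class DihedralTerm:
    """One Fourier term: E = height * (1 + cos(n*phi - phase)).

    ``height`` is the barrier divided by two (AMBER's DIHEDRAL_FORCE_CONSTANT).
    Several terms may share the same atom quadruple.
    """

    i: int
    j: int
    k_atom: int
    l: int
    height: float       # kcal/mol
    periodicity: int
    phase: float        # rad
    scee: float = DEFAULT_SCEE
    scnb: float = DEFAULT_SCNB
    improper: bool = False


@dataclass(frozen=True)
class LJParam:
    rmin_half: float   # A
    epsilon: float     # kcal/mol


def canonical_bond(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def canonical_angle(i: int, j: int, k: int) -> tuple[int, int, int]:
    return (i, j, k) if i < k else (k, j, i)


def canonical_dihedral(i: int, j: int, k: int, l: int) -> tuple[int, int, int, int]:
    if (j, i) > (k, l):
        return (l, k, j, i)
    return (i, j, k, l)


@dataclass
class Topology:
    atoms: list[Atom]
    lj: dict[str, LJParam]
    bonds: list[BondTerm]
    angles: list[AngleTerm]
    dihedrals: list[DihedralTerm]
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    pairs14: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    scee_default: float = DEFAULT_SCEE
    scnb_default: float = DEFAULT_SCNB
    title: str = "qmmmkit topology"

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def with_charges(self, charges: np.ndarray) -> "Topology":
        """Return a copy whose per-atom charges are replaced."""
        if len(charges) != self.n_atoms:
            raise TopologyError("charge vector length does not match atom count")
        atoms = [replace(a, charge=float(q)) for a, q in zip(self.atoms, charges)]
        return replace(self, atoms=atoms)

    def bonded_neighbors(self) -> list[set[int]]:
        nbrs: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for b in self.bonds:
            nbrs[b.i].add(b.j)
            nbrs[b.j].add(b.i)
        return nbrs

    def lj_for_atom(self, index: int) -> LJParam:
        label = self.atoms[index].type_label
        try:
            return self.lj[label]
        except KeyError:
            raise TopologyError(
                f"missing Lennard-Jones parameters for atom type {label!r}"
            ) from None

    def approx_equal(self, other: "Topology", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Field-for-field comparison with a numeric tolerance.

        Term lists are compared in canonical order, so dialects that regroup
        terms (e.g. prmtop's hydrogen/non-hydrogen sections) still compare
        equal when the terms themselves match.
        """

        def close(a: float, b: float) -> bool:
            return math.isclose(a, b, rel_tol=rtol, abs_tol=atol)

        if self.n_atoms != other.n_atoms:
            return False
        for a, b in zip(self.atoms, other.atoms):
            if (a.name, a.element, a.type_label, a.residue_index, a.residue_label) != (
                b.name, b.element, b.type_label, b.residue_index, b.residue_label
            ):
                return False
            if not (close(a.mass, b.mass) and close(a.charge, b.charge)):
                return False
        if set(self.lj) != set(other.lj):
            return False
        for t in self.lj:
            if not (
                close(self.lj[t].rmin_half, other.lj[t].rmin_half)
                and close(self.lj[t].epsilon, other.lj[t].epsilon)
            ):
                return False
        if len(self.bonds) != len(other.bonds):
            return False
        bonds_a = sorted(self.bonds, key=lambda b: canonical_bond(b.i, b.j))
        bonds_b = sorted(other.bonds, key=lambda b: canonical_bond(b.i, b.j))
        for x, y in zip(bonds_a, bonds_b):
            if canonical_bond(x.i, x.j) != canonical_bond(y.i, y.j) or not (
                close(x.k, y.k) and close(x.r_eq, y.r_eq)
            ):
                return False
        if len(self.angles) != len(other.angles):
            return False
        ang_a = sorted(self.angles, key=lambda a: canonical_angle(a.i, a.j, a.k_atom))
        ang_b = sorted(other.angles, key=lambda a: canonical_angle(a.i, a.j, a.k_atom))
        for x, y in zip(ang_a, ang_b):
            if canonical_angle(x.i, x.j, x.k_atom) != canonical_angle(y.i, y.j, y.k_atom):
                return False
            if not (close(x.k, y.k) and close(x.theta_eq, y.theta_eq)):
                return False
        if len(self.dihedrals) != len(other.dihedrals):
            return False

        def dihedral_key(d: DihedralTerm):
            return (canonical_dihedral(d.i, d.j, d.k_atom, d.l),
                    d.periodicity, d.improper)

        dih_a = sorted(self.dihedrals, key=dihedral_key)
        dih_b = sorted(other.dihedrals, key=dihedral_key)
        for x, y in zip(dih_a, dih_b):
            if dihedral_key(x) != dihedral_key(y):
                return False
            if not (
                close(x.height, y.height)
                and close(x.phase, y.phase)
                and close(x.scee, y.scee)
                and close(x.scnb, y.scnb)
            ):
                return False
        if self.exclusions != other.exclusions:
            return False
        if set(self.pairs14) != set(other.pairs14):
            return False
        for p in self.pairs14:
            if not all(close(a, b) for a, b in zip(self.pairs14[p], other.pairs14[p])):
                return False
        return True


@dataclass
class Structure:
    """Cartesian coordinates (A), parallel to a Topology's atom list."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise TopologyError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Structure":
        return Structure(self.coords.copy())


# ----------------------------------------------------------------------
# Connectivity helpers
# ----------------------------------------------------------------------

def bond_graph_distances(n_atoms: int, bonds, max_dist: int = 3) -> dict[tuple[int, int], int]:
    """Shortest bond-graph distance for all pairs up to ``max_dist`` bonds.

    Returns a dict over canonical pairs; pairs further apart are absent.
    ``bonds`` is any iterable of objects/tuples with atom indices first.
    """
    nbrs: list[set[int]] = [set() for _ in range(n_atoms)]
    for b in bonds:
        i, j = (b.i, b.j) if hasattr(b, "i") else (b[0], b[1])
        nbrs[i].add(j)
        nbrs[j].add(i)
    dist: dict[tuple[int, int], int] = {}
    for start in range(n_atoms):
        seen = {start: 0}
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            d = seen[cur]
            if d == max_dist:
                continue
            for nxt in nbrs[cur]:
                if nxt not in seen:
                    seen[nxt] = d + 1
                    queue.append(nxt)
        for other, d in seen.items():
            if other > start:
                dist[(start, other)] = d
    return dist


def rebuild_nonbonded_lists(topology: Topology, extra_bonds=()) -> None:
    """Regenerate ``exclusions`` (1-2, 1-3) and ``pairs14`` from connectivity.

    ``extra_bonds`` may list (i, j) pairs treated as bonds for exclusion
    purposes only (used when bonded terms are deliberately removed but the
    atoms should stay excluded, e.g. covalently connected boundary atoms).

    Scale divisors for each 1-4 pair are taken from a proper dihedral term
    whose end atoms span the pair, falling back to the topology defaults.
    """
    all_bonds = [(b.i, b.j) for b in topology.bonds] + [tuple(p) for p in extra_bonds]
    dist = bond_graph_distances(topology.n_atoms, all_bonds, max_dist=3)
    topology.exclusions = {p for p, d in dist.items() if d <= 2}
    scale_by_pair: dict[tuple[int, int], tuple[float, float]] = {}
    for t in topology.dihedrals:
        if t.improper:
            continue
        p = canonical_bond(t.i, t.l)
        scale_by_pair.setdefault(p, (t.scee, t.scnb))
    topology.pairs14 = {
        p: scale_by_pair.get(p, (topology.scee_default, topology.scnb_default))
        for p, d in dist.items()
        if d == 3
    }


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------

def validate_topology(topology: Topology) -> list[str]:
    """Check Topology invariants; returns a list of human-readable violations.

    An empty list means the topology is valid.  Never raises.
    """
    report: list[str] = []
    n = topology.n_atoms

    def chk_idx(idx: int, what: str) -> bool:
        if not (0 <= idx < n):
            report.append(f"{what} references atom index {idx} outside 0..{n - 1}")
            return False
        return True

    seen_bonds: set[tuple[int, int]] = set()
    for b in topology.bonds:
        ok = chk_idx(b.i, "bond") and chk_idx(b.j, "bond")
        if not ok:
            continue
        key = canonical_bond(b.i, b.j)
        if key in seen_bonds:
            report.append(f"duplicated bond {key}")
        seen_bonds.add(key)
    seen_angles: set[tuple[int, int, int]] = set()
    for a in topology.angles:
        if not all(chk_idx(x, "angle") for x in (a.i, a.j, a.k_atom)):
            continue
        key = canonical_angle(a.i, a.j, a.k_atom)
        if key in seen_angles:
            report.append(f"duplicated angle {key}")
        seen_angles.add(key)
    for d in topology.dihedrals:
        all(chk_idx(x, "dihedral") for x in (d.i, d.j, d.k_atom, d.l))
    for p in topology.exclusions:
        all(chk_idx(x, "exclusion") for x in p)
    for p in topology.pairs14:
        all(chk_idx(x, "1-4 pair") for x in p)

    overlap = topology.exclusions & set(topology.pairs14)
    for p in sorted(overlap):
        report.append(f"pair {p} listed both as exclusion and as 1-4 pair")

    # 1-2 and 1-3 pairs must be excluded and must not appear as 1-4 pairs.
    valid_bonds = [b for b in topology.bonds
                   if 0 <= b.i < n and 0 <= b.j < n]
    dist = bond_graph_distances(n, valid_bonds, max_dist=2)
    for p, d in dist.items():
        if d <= 2 and p not in topology.exclusions:
            report.append(f"pair {p} at bond distance {d} missing from exclusions")
        if d <= 2 and p in topology.pairs14:
            report.append(f"pair {p} at bond distance {d} listed as 1-4 pair")

    for atom in topology.atoms:
        if atom.mass <= 0:
            report.append(f"atom {atom.name}: non-positive mass {atom.mass}")
        if atom.type_label not in topology.lj:
            report.append(f"atom {atom.name}: no LJ parameters for type {atom.type_label!r}")
    for label, p in topology.lj.items():
        if p.rmin_half < 0 or p.epsilon < 0:
            report.append(f"LJ type {label!r}: negative parameter")
    return report


# ----------------------------------------------------------------------
# AMBER prmtop dialect
# ----------------------------------------------------------------------

_REQUIRED_FLAGS = (
    "POINTERS", "ATOM_NAME", "CHARGE", "MASS", "ATOM_TYPE_INDEX",
    "AMBER_ATOM_TYPE", "RESIDUE_LABEL", "RESIDUE_POINTER",
    "BOND_FORCE_CONSTANT", "BOND_EQUIL_VALUE",
    "ANGLE_FORCE_CONSTANT", "ANGLE_EQUIL_VALUE",
    "DIHEDRAL_FORCE_CONSTANT", "DIHEDRAL_PERIODICITY", "DIHEDRAL_PHASE",
    "NONBONDED_PARM_INDEX", "LENNARD_JONES_ACOEF", "LENNARD_JONES_BCOEF",
    "BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN",
    "ANGLES_INC_HYDROGEN", "ANGLES_WITHOUT_HYDROGEN",
    "DIHEDRALS_INC_HYDROGEN", "DIHEDRALS_WITHOUT_HYDROGEN",
)

_REJECTED_FLAGS = ("CMAP_COUNT", "CHARMM_CMAP_COUNT", "EXTRA_POINTS_INFO")

_KNOWN_FLAGS = set(_REQUIRED_FLAGS) | {
    "TITLE", "ATOMIC_NUMBER", "NUMBER_EXCLUDED_ATOMS", "EXCLUDED_ATOMS_LIST",
    "SCEE_SCALE_FACTOR", "SCNB_SCALE_FACTOR", "SOLTY", "HBOND_ACOEF",
    "HBOND_BCOEF", "HBCUT", "TREE_CHAIN_CLASSIFICATION", "JOIN_ARRAY",
    "IROTAT", "RADIUS_SET", "RADII", "SCREEN", "IPOL", "POLARIZABILITY",
    "BOX_DIMENSIONS", "SOLVENT_POINTERS", "ATOMS_PER_MOLECULE",
}


def _parse_prmtop_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    flag = None
    for line in text.splitlines():
        if line.startswith("%VERSION"):
            continue
        if line.startswith("%FLAG"):
            flag = line.split()[1]
            sections[flag] = []
        elif line.startswith("%FORMAT") or line.startswith("%COMMENT"):
            continue
        elif flag is not None:
            sections[flag].append(line)
    return sections


def _ints(lines: list[str]) -> list[int]:
    out: list[int] = []
    for line in lines:
        out.extend(int(tok) for tok in line.split())
    return out


def _floats(lines: list[str]) -> list[float]:
    out: list[float] = []
    for line in lines:
        out.extend(float(tok) for tok in line.split())
    return out


def _a4(lines: list[str]) -> list[str]:
    out: list[str] = []
    for line in lines:
        line = line.rstrip("\n")
        for pos in range(0, len(line), 4):
            tok = line[pos:pos + 4].strip()
            if tok:
                out.append(tok)
    return out


def read_prmtop(path) -> Topology:
    """Read an AMBER parameter--topology file.

    Charges are unscaled to electron charges (the file stores them multiplied
    by 18.2223).  Per-type LJ parameters are recovered from the diagonal of
    the A/B coefficient tables (Lorentz--Berthelot combination rules are
    assumed for off-diagonal entries).  Unknown sections are ignored with a
    warning; CMAP/extra-point sections are rejected.
    """
    with open(path) as fh:
        sections = _parse_prmtop_sections(fh.read())

    for flag in _REJECTED_FLAGS:
        if flag in sections:
            raise TopologyError(f"unsupported prmtop section {flag}")
    for flag in sections:
        if flag not in _KNOWN_FLAGS:
            logger.warning("ignoring unknown prmtop section %s", flag)
    for flag in _REQUIRED_FLAGS:
        if flag not in sections:
            raise TopologyError(f"missing mandatory prmtop section {flag}")

    ptr = _ints(sections["POINTERS"])
    natom, ntypes = ptr[0], ptr[1]
    nbonh, mbona, ntheth, mtheta, nphih, mphia = ptr[2:8]
    nres = ptr[11]
    numbnd, numang, nptra = ptr[15], ptr[16], ptr[17]

    names = _a4(sections["ATOM_NAME"])
    types = _a4(sections["AMBER_ATOM_TYPE"])
    charges = [q / PRMTOP_CHARGE_SCALE for q in _floats(sections["CHARGE"])]
    masses = _floats(sections["MASS"])
    type_index = _ints(sections["ATOM_TYPE_INDEX"])
    if not (len(names) == len(types) == len(charges) == len(masses)
            == len(type_index) == natom):
        raise TopologyError("inconsistent atom counts across prmtop sections")

    if "ATOMIC_NUMBER" in sections:
        zs = _ints(sections["ATOMIC_NUMBER"])
        num_to_sym = {v: k for k, v in _ATOMIC_NUMBER.items()}
        elements = [num_to_sym.get(z, "X") for z in zs]
    else:
        elements = [element_from_mass(m) for m in masses]

    res_labels = _a4(sections["RESIDUE_LABEL"])
    res_ptr = _ints(sections["RESIDUE_POINTER"])
    if len(res_labels) != nres or len(res_ptr) != nres:
        raise TopologyError("inconsistent residue counts")
    res_index = [0] * natom
    for ri in range(nres):
        start = res_ptr[ri] - 1
        end = (res_ptr[ri + 1] - 1) if ri + 1 < nres else natom
        for ai in range(start, end):
            res_index[ai] = ri

    atoms = [
        Atom(names[i], elements[i], types[i], masses[i], charges[i],
             res_index[i], res_labels[res_index[i]])
        for i in range(natom)
    ]

    # LJ per type label, from the diagonal of the pair tables.
    nb_index = _ints(sections["NONBONDED_PARM_INDEX"])
    acoef = _floats(sections["LENNARD_JONES_ACOEF"])
    bcoef = _floats(sections["LENNARD_JONES_BCOEF"])
    lj: dict[str, LJParam] = {}
    for i in range(natom):
        label = types[i]
        if label in lj:
            continue
        t = type_index[i]  # 1-based
        idx = nb_index[ntypes * (t - 1) + (t - 1)] - 1
        a, b = acoef[idx], bcoef[idx]
        if a <= 0.0 or b <= 0.0:
            lj[label] = LJParam(0.0, 0.0)
        else:
            rmin = (2.0 * a / b) ** (1.0 / 6.0)
            eps = b * b / (4.0 * a)
            lj[label] = LJParam(rmin / 2.0, eps)

    bond_k = _floats(sections["BOND_FORCE_CONSTANT"])
    bond_r = _floats(sections["BOND_EQUIL_VALUE"])
    if len(bond_k) != numbnd or len(bond_r) != numbnd:
        raise TopologyError("inconsistent bond parameter counts")
    bonds: list[BondTerm] = []
    raw_bonds = _ints(sections["BONDS_INC_HYDROGEN"]) + _ints(sections["BONDS_WITHOUT_HYDROGEN"])
    if len(raw_bonds) != 3 * (nbonh + mbona):
        raise TopologyError("inconsistent bond term counts")
    for pos in range(0, len(raw_bonds), 3):
        i, j, t = raw_bonds[pos] // 3, raw_bonds[pos + 1] // 3, raw_bonds[pos + 2]
        if not (0 <= i < natom and 0 <= j < natom):
            raise TopologyError(f"bond references atom index beyond atom count: {(i, j)}")
        i, j = canonical_bond(i, j)
        bonds.append(BondTerm(i, j, bond_k[t - 1], bond_r[t - 1]))

    angle_k = _floats(sections["ANGLE_FORCE_CONSTANT"])
    angle_t = _floats(sections["ANGLE_EQUIL_VALUE"])  # radians in prmtop
    if len(angle_k) != numang:
        raise TopologyError("inconsistent angle parameter counts")
    angles: list[AngleTerm] = []
    raw_angles = _ints(sections["ANGLES_INC_HYDROGEN"]) + _ints(sections["ANGLES_WITHOUT_HYDROGEN"])
    if len(raw_angles) != 4 * (ntheth + mtheta):
        raise TopologyError("inconsistent angle term counts")
    for pos in range(0, len(raw_angles), 4):
        i, j, k, t = (raw_angles[pos] // 3, raw_angles[pos + 1] // 3,
                      raw_angles[pos + 2] // 3, raw_angles[pos + 3])
        if not all(0 <= x < natom for x in (i, j, k)):
            raise TopologyError(f"angle references atom index beyond atom count: {(i, j, k)}")
        i, j, k = canonical_angle(i, j, k)
        angles.append(AngleTerm(i, j, k, angle_k[t - 1], angle_t[t - 1]))

    dih_k = _floats(sections["DIHEDRAL_FORCE_CONSTANT"])
    dih_n = _floats(sections["DIHEDRAL_PERIODICITY"])
    dih_p = _floats(sections["DIHEDRAL_PHASE"])
    if len(dih_k) != nptra:
        raise TopologyError("inconsistent dihedral parameter counts")
    if "SCEE_SCALE_FACTOR" in sections:
        scee = _floats(sections["SCEE_SCALE_FACTOR"])
    else:
        scee = [DEFAULT_SCEE] * nptra
    if "SCNB_SCALE_FACTOR" in sections:
        scnb = _floats(sections["SCNB_SCALE_FACTOR"])
    else:
        scnb = [DEFAULT_SCNB] * nptra
    dihedrals: list[DihedralTerm] = []
    raw_dih = (_ints(sections["DIHEDRALS_INC_HYDROGEN"])
               + _ints(sections["DIHEDRALS_WITHOUT_HYDROGEN"]))
    if len(raw_dih) != 5 * (nphih + mphia):
        raise TopologyError("inconsistent dihedral term counts")
    for pos in range(0, len(raw_dih), 5):
        ii, jj, kk, ll, t = raw_dih[pos:pos + 5]
        improper = ll < 0
        i, j, k, l = abs(ii) // 3, abs(jj) // 3, abs(kk) // 3, abs(ll) // 3
        if not all(0 <= x < natom for x in (i, j, k, l)):
            raise TopologyError(
                f"dihedral references atom index beyond atom count: {(i, j, k, l)}")
        if not improper:
            i, j, k, l = canonical_dihedral(i, j, k, l)
        dihedrals.append(DihedralTerm(
            i, j, k, l, dih_k[t - 1], int(round(dih_n[t - 1])), dih_p[t - 1],
            scee[t - 1] if scee[t - 1] > 0 else DEFAULT_SCEE,
            scnb[t - 1] if scnb[t - 1] > 0 else DEFAULT_SCNB,
            improper,
        ))

    top = Topology(
        atoms=atoms, lj=lj, bonds=bonds, angles=angles, dihedrals=dihedrals,
        title="prmtop import",
    )
    # Exclusion and 1-4 bookkeeping follows the bond graph (the authoritative
    # connectivity); EXCLUDED_ATOMS_LIST is cross-checked when present.
    rebuild_nonbonded_lists(top)
    if "EXCLUDED_ATOMS_LIST" in sections and "NUMBER_EXCLUDED_ATOMS" in sections:
        counts = _ints(sections["NUMBER_EXCLUDED_ATOMS"])
        flat = _ints(sections["EXCLUDED_ATOMS_LIST"])
        listed: set[tuple[int, int]] = set()
        pos = 0
        for i, c in enumerate(counts):
            for j in flat[pos:pos + c]:
                if j > 0:
                    listed.add(canonical_bond(i, j - 1))
            pos += c
        derived = top.exclusions | set(top.pairs14)
        if listed != derived:
            logger.warning(
                "prmtop EXCLUDED_ATOMS_LIST differs from bond-graph derivation "
                "(%d listed vs %d derived); using the bond graph",
                len(listed), len(derived),
            )
    return top


def _wrap(values: list[str], per_line: int) -> str:
    lines = []
    for pos in range(0, len(values), per_line):
        lines.append("".join(values[pos:pos + per_line]))
    if not lines:
        lines = [""]
    return "\n".join(lines) + "\n"


def _sec_int(flag: str, values: list[int]) -> str:
    body = _wrap([f"{v:8d}" for v in values], 10)
    return f"%FLAG {flag}\n%FORMAT(10I8)\n{body}"


def _sec_float(flag: str, values: list[float]) -> str:
    body = _wrap([f"{v:16.8E}" for v in values], 5)
    return f"%FLAG {flag}\n%FORMAT(5E16.8)\n{body}"


def _sec_str(flag: str, values: list[str]) -> str:
    body = _wrap([f"{v:<4s}" for v in values], 20)
    return f"%FLAG {flag}\n%FORMAT(20a4)\n{body}"


def write_prmtop(topology: Topology, path) -> None:
    """Write an AMBER parameter--topology file.

    The 1-4 pair list of this dialect is implied by the proper dihedral
    terms (AMBER semantics): a 1-4 pair that no dihedral spans cannot be
    represented and is written as a plain exclusion with a warning.  The
    native dialect has no such limitation.
    """
    n = topology.n_atoms
    is_h = [a.element == "H" for a in topology.atoms]

    # Dedupe parameter tables.
    def table(items):
        index: dict[tuple, int] = {}
        for it in items:
            index.setdefault(it, len(index) + 1)
        return index

    bond_types = table((round(b.k, 10), round(b.r_eq, 10)) for b in topology.bonds)
    angle_types = table((round(a.k, 10), round(a.theta_eq, 10)) for a in topology.angles)
    dih_types = table(
        (round(d.height, 10), d.periodicity, round(d.phase, 10),
         round(d.scee, 10), round(d.scnb, 10))
        for d in topology.dihedrals
    )

    type_labels: list[str] = []
    for a in topology.atoms:
        if a.type_label not in type_labels:
            type_labels.append(a.type_label)
    ntypes = len(type_labels)
    type_of_atom = [type_labels.index(a.type_label) for a in topology.atoms]

    # LJ pair tables (Lorentz-Berthelot).
    npairs = ntypes * (ntypes + 1) // 2
    acoef = [0.0] * npairs
    bcoef = [0.0] * npairs
    nb_index = [0] * (ntypes * ntypes)
    for ti in range(ntypes):
        for tj in range(ti + 1):
            idx = ti * (ti + 1) // 2 + tj
            pi, pj = topology.lj[type_labels[ti]], topology.lj[type_labels[tj]]
            rmin = pi.rmin_half + pj.rmin_half
            eps = math.sqrt(pi.epsilon * pj.epsilon)
            acoef[idx] = eps * rmin ** 12
            bcoef[idx] = 2.0 * eps * rmin ** 6
            nb_index[ti * ntypes + tj] = idx + 1
            nb_index[tj * ntypes + ti] = idx + 1

    bonds_h, bonds_a = [], []
    for b in topology.bonds:
        t = bond_types[(round(b.k, 10), round(b.r_eq, 10))]
        entry = [b.i * 3, b.j * 3, t]
        (bonds_h if (is_h[b.i] or is_h[b.j]) else bonds_a).append(entry)
    angles_h, angles_a = [], []
    for a in topology.angles:
        t = angle_types[(round(a.k, 10), round(a.theta_eq, 10))]
        entry = [a.i * 3, a.j * 3, a.k_atom * 3, t]
        (angles_h if any(is_h[x] for x in (a.i, a.j, a.k_atom)) else angles_a).append(entry)

    dih_h, dih_a = [], []
    covered14: set[tuple[int, int]] = set()
    for d in topology.dihedrals:
        t = dih_types[(round(d.height, 10), d.periodicity, round(d.phase, 10),
                       round(d.scee, 10), round(d.scnb, 10))]
        i, j, k, l = d.i, d.j, d.k_atom, d.l
        end_pair = canonical_bond(i, l)
        compute14 = (not d.improper and end_pair in topology.pairs14
                     and end_pair not in covered14)
        if compute14:
            covered14.add(end_pair)
        if (k == 0 and not compute14) or (l == 0 and d.improper):
            i, j, k, l = l, k, j, i  # a sign cannot be placed on index 0
        entry = [i * 3, j * 3, (k * 3) if compute14 else -(k * 3),
                 -(l * 3) if d.improper else (l * 3), t]
        (dih_h if any(is_h[x] for x in (i, j, k, l)) else dih_a).append(entry)
    missing14 = set(topology.pairs14) - covered14
    if missing14:
        logger.warning(
            "%d 1-4 pair(s) have no spanning dihedral and are written as plain "
            "exclusions in the prmtop dialect: %s", len(missing14), sorted(missing14))

    # Excluded atoms list: exclusions plus 1-4 pairs, AMBER convention.
    excl_sets: list[list[int]] = [[] for _ in range(n)]
    for (i, j) in sorted(topology.exclusions | set(topology.pairs14)):
        excl_sets[i].append(j + 1)
    counts, flat = [], []
    for i in range(n):
        if excl_sets[i]:
            counts.append(len(excl_sets[i]))
            flat.extend(sorted(excl_sets[i]))
        else:
            counts.append(1)
            flat.append(0)

    res_labels: list[str] = []
    res_ptr: list[int] = []
    for i, a in enumerate(topology.atoms):
        if not res_ptr or a.residue_index != topology.atoms[i - 1].residue_index:
            res_labels.append(a.residue_label)
            res_ptr.append(i + 1)
    nres = len(res_labels)

    pointers = [0] * 32
    pointers[0] = n
    pointers[1] = ntypes
    pointers[2] = len(bonds_h)
    pointers[3] = len(bonds_a)
    pointers[4] = len(angles_h)
    pointers[5] = len(angles_a)
    pointers[6] = len(dih_h)
    pointers[7] = len(dih_a)
    pointers[10] = len(flat)          # NNB
    pointers[11] = nres
    pointers[12] = len(bonds_a)       # NBONA
    pointers[13] = len(angles_a)
    pointers[14] = len(dih_a)
    pointers[15] = len(bond_types)
    pointers[16] = len(angle_types)
    pointers[17] = len(dih_types)
    pointers[18] = ntypes             # NATYP (SOLTY length)
    res_sizes = [b - a for a, b in zip(res_ptr, res_ptr[1:] + [n + 1])]
    pointers[21] = max(res_sizes, default=0)  # NMXRS: largest residue

    out = ["%VERSION  VERSION_STAMP = V0001.000  DATE = qmmmkit\n"]
    out.append(f"%FLAG TITLE\n%FORMAT(20a4)\n{topology.title[:80]}\n")
    out.append(_sec_int("POINTERS", pointers))
    out.append(_sec_str("ATOM_NAME", [a.name for a in topology.atoms]))
    out.append(_sec_float("CHARGE", [a.charge * PRMTOP_CHARGE_SCALE for a in topology.atoms]))
    out.append(_sec_int("ATOMIC_NUMBER",
                        [_ATOMIC_NUMBER.get(a.element, 0) for a in topology.atoms]))
    out.append(_sec_float("MASS", [a.mass for a in topology.atoms]))
    out.append(_sec_int("ATOM_TYPE_INDEX", [t + 1 for t in type_of_atom]))
    out.append(_sec_int("NUMBER_EXCLUDED_ATOMS", counts))
    out.append(_sec_int("NONBONDED_PARM_INDEX", nb_index))
    out.append(_sec_str("RESIDUE_LABEL", res_labels))
    out.append(_sec_int("RESIDUE_POINTER", res_ptr))
    out.append(_sec_float("BOND_FORCE_CONSTANT", [kv[0] for kv in bond_types]))
    out.append(_sec_float("BOND_EQUIL_VALUE", [kv[1] for kv in bond_types]))
    out.append(_sec_float("ANGLE_FORCE_CONSTANT", [kv[0] for kv in angle_types]))
    out.append(_sec_float("ANGLE_EQUIL_VALUE", [kv[1] for kv in angle_types]))
    out.append(_sec_float("DIHEDRAL_FORCE_CONSTANT", [kv[0] for kv in dih_types]))
    out.append(_sec_float("DIHEDRAL_PERIODICITY", [float(kv[1]) for kv in dih_types]))
    out.append(_sec_float("DIHEDRAL_PHASE", [kv[2] for kv in dih_types]))
    out.append(_sec_float("SCEE_SCALE_FACTOR", [kv[3] for kv in dih_types]))
    out.append(_sec_float("SCNB_SCALE_FACTOR", [kv[4] for kv in dih_types]))
    out.append(_sec_float("SOLTY", [0.0] * ntypes))
    out.append(_sec_float("LENNARD_JONES_ACOEF", acoef))
    out.append(_sec_float("LENNARD_JONES_BCOEF", bcoef))
    out.append(_sec_int("BONDS_INC_HYDROGEN", [v for e in bonds_h for v in e]))
    out.append(_sec_int("BONDS_WITHOUT_HYDROGEN", [v for e in bonds_a for v in e]))
    out.append(_sec_int("ANGLES_INC_HYDROGEN", [v for e in angles_h for v in e]))
    out.append(_sec_int("ANGLES_WITHOUT_HYDROGEN", [v for e in angles_a for v in e]))
    out.append(_sec_int("DIHEDRALS_INC_HYDROGEN", [v for e in dih_h for v in e]))
    out.append(_sec_int("DIHEDRALS_WITHOUT_HYDROGEN", [v for e in dih_a for v in e]))
    out.append(_sec_int("EXCLUDED_ATOMS_LIST", flat))
    out.append(_sec_str("AMBER_ATOM_TYPE", [a.type_label for a in topology.atoms]))
    with open(path, "w") as fh:
        fh.write("".join(out))


# ----------------------------------------------------------------------
# Native plain-text dialect (exact round trip)
# ----------------------------------------------------------------------

def write_native(topology: Topology, path) -> None:
    """Write the native key--value topology format.

    Layout: one ``[section]`` per term class; whitespace-separated columns;
    ``#`` starts a comment.  Floats are written with ``repr`` so a
    write/read cycle is numerically exact.  Sections may appear in any
    order.  Angles and dihedral phases are in radians.
    """
    lines = ["# qmmmkit native topology v1", f"# title: {topology.title}"]
    lines.append("[defaults]")
    lines.append(f"scee {topology.scee_default!r}")
    lines.append(f"scnb {topology.scnb_default!r}")
    lines.append("[atoms]")
    lines.append("# index name element type mass charge resid reslabel")
    for i, a in enumerate(topology.atoms):
        lines.append(
            f"{i} {a.name} {a.element} {a.type_label} {a.mass!r} {a.charge!r} "
            f"{a.residue_index} {a.residue_label}"
        )
    lines.append("[lj]")
    lines.append("# type rmin_half epsilon")
    for label in sorted(topology.lj):
        p = topology.lj[label]
        lines.append(f"{label} {p.rmin_half!r} {p.epsilon!r}")
    lines.append("[bonds]")
    for b in topology.bonds:
        lines.append(f"{b.i} {b.j} {b.k!r} {b.r_eq!r}")
    lines.append("[angles]")
    for a in topology.angles:
        lines.append(f"{a.i} {a.j} {a.k_atom} {a.k!r} {a.theta_eq!r}")
    lines.append("[dihedrals]")
    lines.append("# i j k l height periodicity phase scee scnb improper")
    for d in topology.dihedrals:
        lines.append(
            f"{d.i} {d.j} {d.k_atom} {d.l} {d.height!r} {d.periodicity} "
            f"{d.phase!r} {d.scee!r} {d.scnb!r} {int(d.improper)}"
        )
    lines.append("[exclusions]")
    for (i, j) in sorted(topology.exclusions):
        lines.append(f"{i} {j}")
    lines.append("[pairs14]")
    for (i, j) in sorted(topology.pairs14):
        scee, scnb = topology.pairs14[(i, j)]
        lines.append(f"{i} {j} {scee!r} {scnb!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_native(path) -> Topology:
    atoms: list[Atom] = []
    lj: dict[str, LJParam] = {}
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    dihedrals: list[DihedralTerm] = []
    exclusions: set[tuple[int, int]] = set()
    pairs14: dict[tuple[int, int], tuple[float, float]] = {}
    defaults = {"scee": DEFAULT_SCEE, "scnb": DEFAULT_SCNB}
    title = "qmmmkit topology"
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("# title:"):
                title = line.split(":", 1)[1].strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            tok = line.split()
            if section == "defaults":
                defaults[tok[0]] = float(tok[1])
            elif section == "atoms":
                atoms.append(Atom(tok[1], tok[2], tok[3], float(tok[4]),
                                  float(tok[5]), int(tok[6]), tok[7]))
            elif section == "lj":
                lj[tok[0]] = LJParam(float(tok[1]), float(tok[2]))
            elif section == "bonds":
                bonds.append(BondTerm(int(tok[0]), int(tok[1]),
                                      float(tok[2]), float(tok[3])))
            elif section == "angles":
                angles.append(AngleTerm(int(tok[0]), int(tok[1]), int(tok[2]),
                                        float(tok[3]), float(tok[4])))
            elif section == "dihedrals":
                dihedrals.append(DihedralTerm(
                    int(tok[0]), int(tok[1]), int(tok[2]), int(tok[3]),
                    float(tok[4]), int(tok[5]), float(tok[6]),
                    float(tok[7]), float(tok[8]), bool(int(tok[9]))))
            elif section == "exclusions":
                exclusions.add(canonical_bond(int(tok[0]), int(tok[1])))
            elif section == "pairs14":
                pairs14[canonical_bond(int(tok[0]), int(tok[1]))] = (
                    float(tok[2]), float(tok[3]))
            else:
                raise TopologyError(f"unknown native-topology section {section!r}")
    return Topology(atoms=atoms, lj=lj, bonds=bonds, angles=angles,
                    dihedrals=dihedrals, exclusions=exclusions, pairs14=pairs14,
                    scee_default=defaults["scee"], scnb_default=defaults["scnb"],
                    title=title)


def write_topology(topology: Topology, path, dialect: str = "native") -> None:
    """Write a topology in the requested dialect ('native' or 'prmtop')."""
    if dialect == "native":
        write_native(topology, path)
    elif dialect == "prmtop":
        write_prmtop(topology, path)
    else:
        raise TopologyError(f"unknown topology dialect {dialect!r}")


def read_topology(path, dialect: str | None = None) -> Topology:
    """Read a topology, sniffing the dialect when not given."""
    if dialect is None:
        with open(path) as fh:
            head = fh.read(2048)
        dialect = "prmtop" if "%FLAG" in head or "%VERSION" in head else "native"
    if dialect == "prmtop":
        return read_prmtop(path)
    if dialect == "native":
        return read_native(path)
    raise TopologyError(f"unknown topology dialect {dialect!r}")


# ----------------------------------------------------------------------
# Coordinates
# ----------------------------------------------------------------------

def read_xyz(path) -> Structure:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].split()[0])
    coords = []
    for line in lines[2:2 + n]:
        tok = line.split()
        coords.append([float(tok[1]), float(tok[2]), float(tok[3])])
    return Structure(np.array(coords))


def write_xyz(structure: Structure, path, symbols=None, comment: str = "") -> None:
    n = structure.n_atoms
    if symbols is None:
        symbols = ["X"] * n
    with open(path, "w") as fh:
        fh.write(f"{n}\n{comment}\n")
        for s, (x, y, z) in zip(symbols, structure.coords):
            fh.write(f"{s:<4s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


def read_inpcrd(path) -> Structure:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[1].split()[0])
    vals: list[float] = []
    for line in lines[2:]:
        for pos in range(0, len(line.rstrip()), 12):
            tok = line[pos:pos + 12].strip()
            if tok:
                vals.append(float(tok))
        if len(vals) >= 3 * n:
            break
    return Structure(np.array(vals[:3 * n]).reshape(n, 3))


def write_inpcrd(structure: Structure, path, title: str = "qmmmkit coordinates") -> None:
    n = structure.n_atoms
    flat = structure.coords.reshape(-1)
    with open(path, "w") as fh:
        fh.write(f"{title}\n{n:6d}\n")
        for pos in range(0, len(flat), 6):
            fh.write("".join(f"{v:12.7f}" for v in flat[pos:pos + 6]) + "\n")
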