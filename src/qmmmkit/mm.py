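"""Molecular-mechanics energy and analytic gradient with per-term filters.

The evaluator computes the standard AMBER-style potential

``E = sum K_r (r - r_eq)^2  +  sum K_th (th - th_eq)^2
    + sum h (1 + cos(n phi - gamma))
    + sum_pairs [A/r^12 - B/r^6] / scnb  +  sum_pairs C q_i q_j / (r scee)``

with no nonbonded cutoff of any kind.  Every term can be switched on or off
by a :class:`TermFilter` predicate over the QM/MM region labels of its
atoms; this is what lets an additive QM/MM scheme cherry-pick exactly the
terms the QM calculation does not already cover, while ``FILTER_ALL``
evaluates a plain MM energy.

Pair scaling is driven by the topology's explicit bookkeeping: pairs in
``exclusions`` are skipped, pairs in ``pairs14`` are divided by their
(scee, scnb) divisors, and all remaining pairs interact at full strength.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .topology import Structure, Topology, canonical_bond
from .units import COULOMB_CONSTANT

__all__ = [
    "QM",
    "MM",
    "TermFilter",
    "FILTER_ALL",
    "FILTER_ADDITIVE",
    "BONDED_AT_LEAST_ONE_MM",
    "ELEC_MM_MM_ONLY",
    "VDW_NOT_BOTH_QM",
    "ELEC_NONE",
    "EnergyReport",
    "enumerate_terms",
    "mm_energy",
    "embedding_coulomb",
    "bond_length",
    "bond_angle",
    "dihedral_angle",
]

QM = "QM"
MM = "MM"

RegionPredicate = Callable[[tuple[str, ...]], bool]


def _always(regions: tuple[str, ...]) -> bool:
    return True


def _never(regions: tuple[str, ...]) -> bool:
    return False


def _at_least_one_mm(regions: tuple[str, ...]) -> bool:
    return MM in regions


def _all_mm(regions: tuple[str, ...]) -> bool:
    return all(r == MM for r in regions)


def _not_all_qm(regions: tuple[str, ...]) -> bool:
    return not all(r == QM for r in regions)


@dataclass(frozen=True)
class TermFilter:
    """Predicates over the region labels of a term's atoms, per term class.

    Each predicate receives the tuple of region labels ('QM'/'MM', with
    boundary CL atoms counted as QM) of the term's atoms and returns whether
    the term is evaluated.  Filters compose by conjunction via ``__and__``.
    """

    bonded: RegionPredicate = _always
    elec: RegionPredicate = _always
    vdw: RegionPredicate = _always
    name: str = "custom"

    def __and__(self, other: "TermFilter") -> "TermFilter":
        return TermFilter(
            bonded=lambda r, a=self.bonded, b=other.bonded: a(r) and b(r),
            elec=lambda r, a=self.elec, b=other.elec: a(r) and b(r),
            vdw=lambda r, a=self.vdw, b=other.vdw: a(r) and b(r),
            name=f"({self.name} & {other.name})",
        )


#: Evaluate everything (plain MM energy).
FILTER_ALL = TermFilter(name="ALL")

#: Bonded terms with at least one MM atom (additive rule 3, which together
#: with rule 1 excludes the all-QM bonded terms already described by QM).
BONDED_AT_LEAST_ONE_MM = TermFilter(bonded=_at_least_one_mm, name="BONDED_AT_LEAST_ONE_MM")

#: Electrostatics between MM atoms only (rules 2 + 4: QM-MM electrostatics
#: live in the embedded QM calculation).
ELEC_MM_MM_ONLY = TermFilter(elec=_all_mm, name="ELEC_MM_MM_ONLY")

#: Van der Waals terms unless both atoms are QM (rules 2 + 5).
VDW_NOT_BOTH_QM = TermFilter(vdw=_not_all_qm, name="VDW_NOT_BOTH_QM")

#: No electrostatics at all.
ELEC_NONE = TermFilter(elec=_never, name="ELEC_NONE")

#: The additive scheme's MM term: rules 1-5 combined.
FILTER_ADDITIVE = TermFilter(
    bonded=_at_least_one_mm, elec=_all_mm, vdw=_not_all_qm, name="ADDITIVE",
)


@dataclass
class EnergyReport:
    """Total energy (kcal/mol), gradient (kcal/mol/A) and decomposition.

    ``components`` decomposes the total by term class; ``assembly`` holds
    scheme-level top terms (e.g. the QM and MM contributions of a QM/MM
    assembly).  The total always equals the sum of ``components`` (or of
    ``assembly`` when present).
    """

    total: float
    gradient: np.ndarray
    components: dict[str, float]
    scheme: str = "MM"
    assembly: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "gradient": self.gradient.tolist(),
            "components": dict(self.components),
            "scheme": self.scheme,
            "assembly": dict(self.assembly),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EnergyReport":
        return cls(
            total=data["total"],
            gradient=np.array(data["gradient"], dtype=float),
            components=dict(data["components"]),
            scheme=data.get("scheme", "MM"),
            assembly=dict(data.get("assembly", {})),
            metadata=dict(data.get("metadata", {})),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "EnergyReport":
        return cls.from_dict(json.loads(text))


# ----------------------------------------------------------------------
# Geometry primitives (values and gradients)
# ----------------------------------------------------------------------

def bond_length(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[i] - coords[j]))


def bond_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in radians."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    cross = np.cross(u, v)
    return float(np.arctan2(np.linalg.norm(cross), float(u @ v)))


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """IUPAC-signed torsion i-j-k-l in radians, in (-pi, pi]."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(float(m @ n2), float(n1 @ n2)))


_LINEAR_GUARD = 1e-12  # |u x v| below this is treated as exactly (anti)linear


def _angle_gradient(coords, i, j, k):
    """theta and d(theta)/d(r_i, r_j, r_k); guarded near linearity."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    cross = np.cross(u, v)
    s = np.linalg.norm(cross)
    theta = np.arctan2(s, float(u @ v))
    if s < _LINEAR_GUARD:
        zero = np.zeros(3)
        return theta, zero, zero, zero
    di = np.cross(u, cross) / (s * float(u @ u))
    dk = -np.cross(v, cross) / (s * float(v @ v))
    dj = -di - dk
    return theta, di, dj, dk


def _dihedral_gradient(coords, i, j, k, l):
    """phi and d(phi)/d(r_i..r_l) (standard cross-product formulation)."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    m = np.cross(n1, b2 / nb2)
    phi = np.arctan2(float(m @ n2), float(n1 @ n2))
    sq1 = float(n1 @ n1)
    sq2 = float(n2 @ n2)
    if sq1 < _LINEAR_GUARD or sq2 < _LINEAR_GUARD:
        zero = np.zeros(3)
        return phi, zero, zero, zero, zero
    di = nb2 / sq1 * n1
    dl = -nb2 / sq2 * n2
    dot12 = float(b1 @ b2) / (nb2 * nb2)
    dot32 = float(b3 @ b2) / (nb2 * nb2)
    dj = -(1.0 + dot12) * di + dot32 * dl
    dk = dot12 * di - (1.0 + dot32) * dl
    return phi, di, dj, dk, dl


# ----------------------------------------------------------------------
# Term enumeration
# ----------------------------------------------------------------------

def _region_labels(n_atoms: int, region_map) -> list[str]:
    if region_map is None:
        return [MM] * n_atoms
    return list(region_map.labels)


def enumerate_terms(topology: Topology, region_map=None) -> list[dict]:
    """List every energy term with its atoms and region annotation.

    Each record has ``kind`` in {'bond', 'angle', 'dihedral', 'pair'},
    ``atoms`` (indices) and ``regions`` (parallel labels, CL counted as QM).
    Pair records additionally carry ``scaled14`` and the (scee, scnb)
    divisors.  Pairs in the exclusion list are not enumerated.
    """
    labels = _region_labels(topology.n_atoms, region_map)
    out: list[dict] = []
    for b in topology.bonds:
        out.append({"kind": "bond", "atoms": (b.i, b.j),
                    "regions": (labels[b.i], labels[b.j]), "term": b})
    for a in topology.angles:
        ats = (a.i, a.j, a.k_atom)
        out.append({"kind": "angle", "atoms": ats,
                    "regions": tuple(labels[x] for x in ats), "term": a})
    for d in topology.dihedrals:
        ats = (d.i, d.j, d.k_atom, d.l)
        out.append({"kind": "dihedral", "atoms": ats,
                    "regions": tuple(labels[x] for x in ats), "term": d})
    n = topology.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            pair = (i, j)
            if pair in topology.exclusions:
                continue
            scaled = pair in topology.pairs14
            scee, scnb = topology.pairs14.get(
                pair, (topology.scee_default, topology.scnb_default))
            out.append({"kind": "pair", "atoms": pair,
                        "regions": (labels[i], labels[j]),
                        "scaled14": scaled, "scee": scee, "scnb": scnb})
    return out


# ----------------------------------------------------------------------
# Energy evaluation
# ----------------------------------------------------------------------

def mm_energy(
    topology: Topology,
    structure: Structure,
    term_filter: TermFilter = FILTER_ALL,
    charge_set=None,
    region_map=None,
    bonded_term_veto: Callable[[tuple[int, ...]], bool] | None = None,
) -> EnergyReport:
    """MM energy and analytic gradient under a term filter.

    Parameters
    ----------
    charge_set
        Optional per-atom charges (array or ChargeSet-like with ``values``)
        overriding the topology charges.
    region_map
        Region labels used by the filter; all-MM when absent.
    bonded_term_veto
        Optional predicate on a bonded term's atom tuple; terms for which it
        returns True are skipped regardless of the filter (used to drop
        cross-junction terms between covalently bonded boundary atoms).
    """
    coords = structure.coords
    if coords.shape[0] != topology.n_atoms:
        raise ValueError("structure does not match topology atom count")
    if charge_set is None:
        charges = topology.charges
    else:
        charges = np.asarray(getattr(charge_set, "values", charge_set), dtype=float)
    if charges.shape[0] != topology.n_atoms:
        raise ValueError("charge set length does not match topology atom count")

    labels = _region_labels(topology.n_atoms, region_map)
    grad = np.zeros_like(coords)
    comp = {"bond": 0.0, "angle": 0.0, "dihedral": 0.0,
            "vdw": 0.0, "vdw14": 0.0, "elec": 0.0, "elec14": 0.0}

    def check(term_atoms, value):
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite geometry in term over atoms {term_atoms}")
        return value

    for b in topology.bonds:
        ats = (b.i, b.j)
        if bonded_term_veto is not None and bonded_term_veto(ats):
            continue
        if not term_filter.bonded(tuple(labels[x] for x in ats)):
            continue
        dvec = coords[b.i] - coords[b.j]
        r = check(ats, float(np.linalg.norm(dvec)))
        comp["bond"] += b.k * (r - b.r_eq) ** 2
        dEdr = 2.0 * b.k * (r - b.r_eq)
        g = dEdr * dvec / r
        grad[b.i] += g
        grad[b.j] -= g

    for a in topology.angles:
        ats = (a.i, a.j, a.k_atom)
        if bonded_term_veto is not None and bonded_term_veto(ats):
            continue
        if not term_filter.bonded(tuple(labels[x] for x in ats)):
            continue
        theta, di, dj, dk = _angle_gradient(coords, *ats)
        check(ats, theta)
        comp["angle"] += a.k * (theta - a.theta_eq) ** 2
        dEdt = 2.0 * a.k * (theta - a.theta_eq)
        grad[a.i] += dEdt * di
        grad[a.j] += dEdt * dj
        grad[a.k_atom] += dEdt * dk

    for d in topology.dihedrals:
        ats = (d.i, d.j, d.k_atom, d.l)
        if bonded_term_veto is not None and bonded_term_veto(ats):
            continue
        if not term_filter.bonded(tuple(labels[x] for x in ats)):
            continue
        phi, di, dj, dk, dl = _dihedral_gradient(coords, *ats)
        check(ats, phi)
        arg = d.periodicity * phi - d.phase
        comp["dihedral"] += d.height * (1.0 + np.cos(arg))
        dEdphi = -d.height * d.periodicity * np.sin(arg)
        grad[d.i] += dEdphi * di
        grad[d.j] += dEdphi * dj
        grad[d.k_atom] += dEdphi * dk
        grad[d.l] += dEdphi * dl

    n = topology.n_atoms
    lj = [topology.lj_for_atom(i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pair = (i, j)
            if pair in topology.exclusions:
                continue
            regions = (labels[i], labels[j])
            do_vdw = term_filter.vdw(regions)
            do_elec = term_filter.elec(regions)
            if not (do_vdw or do_elec):
                continue
            scaled = pair in topology.pairs14
            scee, scnb = topology.pairs14.get(
                pair, (topology.scee_default, topology.scnb_default))
            dvec = coords[i] - coords[j]
            r2 = float(dvec @ dvec)
            r = check(pair, np.sqrt(r2))
            dEdr = 0.0
            if do_vdw:
                eps = np.sqrt(lj[i].epsilon * lj[j].epsilon)
                if eps > 0.0:
                    rmin = lj[i].rmin_half + lj[j].rmin_half
                    a6 = (rmin * rmin / r2) ** 3
                    s = (1.0 / scnb) if scaled else 1.0
                    e = s * eps * (a6 * a6 - 2.0 * a6)
                    comp["vdw14" if scaled else "vdw"] += e
                    dEdr += s * eps * 12.0 * (a6 - a6 * a6) / r
            if do_elec:
                qq = charges[i] * charges[j]
                if qq != 0.0:
                    s = (1.0 / scee) if scaled else 1.0
                    e = s * COULOMB_CONSTANT * qq / r
                    comp["elec14" if scaled else "elec"] += e
                    dEdr += -e / r
            if dEdr != 0.0:
                g = dEdr * dvec / r
                grad[i] += g
                grad[j] -= g

    total = float(sum(comp.values()))
    return EnergyReport(
        total=total, gradient=grad, components=comp, scheme="MM",
        metadata={"filter": term_filter.name,
                  "charge_set": getattr(charge_set, "provenance", "topology")},
    )


def embedding_coulomb(
    coords: np.ndarray,
    charges: Sequence[float],
    pc_positions: np.ndarray,
    pc_charges: Sequence[float],
) -> tuple[float, np.ndarray, np.ndarray]:
    """Unscaled Coulomb interaction of a charge cloud with external point charges.

    Mirrors how a QM code sees an embedding point-charge model: every
    atom--charge pair interacts at full strength (no exclusions, no 1-4
    scaling) and the self-energy of the point charges is never included.
    Returns (energy, gradient on atoms, gradient on point charges).
    """
    coords = np.asarray(coords, dtype=float)
    q = np.asarray(charges, dtype=float)
    pos = np.asarray(pc_positions, dtype=float).reshape(-1, 3)
    pq = np.asarray(pc_charges, dtype=float)
    g_at = np.zeros_like(coords)
    g_pc = np.zeros_like(pos)
    if len(pq) == 0 or coords.shape[0] == 0:
        return 0.0, g_at, g_pc
    diff = coords[:, None, :] - pos[None, :, :]          # (n, m, 3)
    r = np.sqrt(np.sum(diff * diff, axis=2))             # (n, m)
    if np.any(r < 1e-10):
        raise FloatingPointError("point charge coincides with an atom")
    pairE = COULOMB_CONSTANT * np.outer(q, pq) / r
    energy = float(pairE.sum())
    # dE/dr = -E/r along the pair axis
    f = (pairE / (r * r))[:, :, None] * diff
    g_at -= f.sum(axis=1)
    g_pc += f.sum(axis=0)
    return energy, g_at, g_pc
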