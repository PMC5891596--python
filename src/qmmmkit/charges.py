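"""Charge sets, point-charge models and the mechanical-embedding charge merge.

Electrostatic embedding polarises the QM calculation with a point-charge
model of the environment: every system-2 atom enters with its MM charge at
its current position, and boundary (CL) atoms never do — they belong to
system 1.  Mechanical embedding instead needs one consistent charge set for
the whole system, built from QM-derived charges of the truncated system and
the original MM charges, with the boundary atoms absorbing the residual so
that every biochemical unit keeps its original integer charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import LinkSpec, RegionMap
from .topology import Structure, Topology

__all__ = [
    "ChargeError",
    "ChargeSet",
    "PointChargeModel",
    "build_point_charge_model",
    "zero_region_charges",
    "merge_charges_me",
    "assign_hl_charges",
]


class ChargeError(ValueError):
    """Raised for inconsistent charge bookkeeping."""


@dataclass
class ChargeSet:
    """A named per-atom charge vector (e) with provenance.

    ``provenance`` is one of 'mm_original', 'qm_derived', 'merged', 'zeroed'.
    ``hl_charges`` optionally maps a CL atom index to the QM-derived charge
    of its hydrogen link atom (used by the truncated system in mechanical
    embedding and the electrostatic link-atom correction).
    """

    values: np.ndarray
    provenance: str = "mm_original"
    hl_charges: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if not np.all(np.isfinite(self.values)):
            raise ChargeError("non-finite charges")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]

    def total(self) -> float:
        return float(self.values.sum())

    def copy(self, provenance: str | None = None) -> "ChargeSet":
        return ChargeSet(self.values.copy(),
                         provenance or self.provenance,
                         dict(self.hl_charges))


@dataclass
class PointChargeModel:
    """External charges embedding a QM calculation: one per system-2 atom.

    CL atoms and all other system-1 atoms are never included.  ``atom_indices``
    records which full-system atom each charge belongs to, so gradients on
    the charges can be mapped back.
    """

    positions: np.ndarray     # (m, 3) A
    charges: np.ndarray       # (m,) e
    atom_indices: list[int]

    def __len__(self) -> int:
        return len(self.atom_indices)


def build_point_charge_model(
    topology: Topology,
    structure: Structure,
    region_map: RegionMap,
    charge_set: ChargeSet | None = None,
) -> PointChargeModel:
    """Point-charge model of system 2 at the current coordinates.

    All MM atoms enter with their charges from ``charge_set`` (topology
    charges by default); no charge is deleted or redistributed near the
    junction, and no CL or other QM atom ever appears.
    """
    q = topology.charges if charge_set is None else charge_set.values
    mm = region_map.mm_indices
    return PointChargeModel(
        positions=structure.coords[mm].copy(),
        charges=np.asarray([q[i] for i in mm], dtype=float),
        atom_indices=list(mm),
    )


def zero_region_charges(
    charge_set: ChargeSet,
    region_map: RegionMap,
    which_region: str = "QM",
) -> ChargeSet:
    """Zero the charges of one region (idempotent); the other is untouched.

    Zeroing the QM region is how the full-system MM term of an
    electrostatically embedded scheme avoids double counting: the QM-MM
    electrostatics already live in the embedded QM calculation.
    """
    if which_region not in ("QM", "MM"):
        raise ChargeError(f"unknown region {which_region!r}")
    out = charge_set.values.copy()
    mask = region_map.qm_mask if which_region == "QM" else ~region_map.qm_mask
    out[mask] = 0.0
    return ChargeSet(out, provenance="zeroed", hl_charges=dict(charge_set.hl_charges))


def merge_charges_me(
    mm_charges: ChargeSet,
    qm_charges_with_hl: ChargeSet,
    region_map: RegionMap,
    unit_partition=None,
    external_integer_charge: int = 0,
    tol: float = 1e-4,
) -> ChargeSet:
    """Merged full-system charges for mechanical embedding.

    Procedure: QM atoms (except the boundary CL atoms) take their QM-derived
    charges; MM atoms keep the original MM charges; then, within each
    biochemical unit that contains CL atoms, a constant offset is added to
    each CL atom's *original MM* charge so the unit total returns to its
    original integer value (plus ``external_integer_charge``, a declared
    integer sitting outside the QM system).  When a unit holds several CL
    atoms the residual is split equally among them.  Charge transfer across
    the QM region is allowed: units that lie entirely inside the QM region
    are not constrained to integer totals.

    ``qm_charges_with_hl.values`` is indexed by full-system atom index for
    the QM atoms; its ``hl_charges`` are ignored here (the merged set is a
    CL-representation object).  ``unit_partition`` maps each atom to a unit
    id and defaults to the residue index.
    """
    n = mm_charges.n_atoms
    if qm_charges_with_hl.n_atoms != n:
        raise ChargeError("QM charge vector must be indexed over the full system")
    if unit_partition is None:
        raise ChargeError("unit partition required (pass topology residue indices)")
    units = np.asarray(unit_partition)
    if units.shape[0] != n:
        raise ChargeError("unit partition length does not match atom count")

    qm_mask = region_map.qm_mask
    cl_set = set(region_map.cl_indices)
    merged = mm_charges.values.copy()
    for i in range(n):
        if qm_mask[i] and i not in cl_set:
            merged[i] = qm_charges_with_hl.values[i]

    external_assigned = False
    for u in np.unique(units):
        idx = np.where(units == u)[0]
        cls = [i for i in idx if i in cl_set]
        has_mm = any(not qm_mask[i] for i in idx)
        all_qm = all(qm_mask[i] for i in idx)
        target = round(float(mm_charges.values[idx].sum()))
        if cls and not external_assigned:
            target += external_integer_charge
            external_assigned = True
        if cls:
            residual = target - float(merged[idx].sum())
            offset = residual / len(cls)
            for i in cls:
                merged[i] = mm_charges.values[i] + offset
        else:
            if all_qm:
                continue  # charge transfer within the QM region is allowed
            residual = target - float(merged[idx].sum())
            if abs(residual) > tol:
                raise ChargeError(
                    f"unit {u} has no boundary atom to absorb a charge residual "
                    f"of {residual:+.4f} e" + ("" if has_mm else " (QM-only unit)"))
    return ChargeSet(merged, provenance="merged", hl_charges=dict(qm_charges_with_hl.hl_charges))


def assign_hl_charges(
    qm_charges_with_hl: ChargeSet,
    region_map: RegionMap,
    link_specs: dict[int, LinkSpec],
) -> dict[int, LinkSpec]:
    """Copy QM-derived link-atom charges into the link specs.

    ``qm_charges_with_hl.hl_charges`` must hold one value per junction
    (keyed by CL atom index); these are representative of a hydrogen atom
    and enter the truncated system's charge set for mechanical embedding and
    the electrostatic link-atom correction.
    """
    cls = set(region_map.cl_indices)
    have = set(qm_charges_with_hl.hl_charges)
    if have != cls:
        raise ChargeError(
            f"link-atom charge bookkeeping mismatch: junctions at {sorted(cls)}, "
            f"charges given for {sorted(have)}")
    out = {}
    for cl, spec in link_specs.items():
        out[cl] = LinkSpec(r0_hl=spec.r0_hl, r0_cl=spec.r0_cl, hl_type=spec.hl_type,
                           hl_charge=qm_charges_with_hl.hl_charges[cl])
    return out
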