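"""Total QM/MM energy and gradient assembly for every coupling variant.

Supported schemes (electrostatic embedding unless noted):

* ``ADD`` — additive: ``E = E_QM1+ptch2(HL) + E_MM2-1(CL)`` where the MM term
  keeps every term with at least one MM atom except QM-MM electrostatics
  (those live in the embedded QM calculation) and all-QM terms.
* ``SUB_VLAC`` — subtractive: ``E = E_QM1+ptch2(HL) + E_MM12,q1=0(CL)
  - E_MM1,q1=0(HL)``.  The small MM term uses HL atoms, coordinates and
  parameters, so the assembly implicitly applies a van der Waals link-atom
  correction (VLAC): intra-QM vdW pairs involving the boundary atom are
  described CL-wise by the large term and HL-wise by the subtracted one.
* ``SUB_STRICT`` — the small MM term uses CL atoms, coordinates and
  parameters instead; every duplicated MM term then cancels exactly and the
  result is identical to ``ADD``.
* ``ME`` — mechanical embedding: ``E = E_QM1(HL) + E_MM12(CL, merged
  charges) - E_MM1(HL, QM charges)``; no point-charge model anywhere.
* ``ELAC`` — electrostatic link-atom correction: like ``SUB_VLAC`` but both
  MM terms use QM charges for the QM system (the large term via the merged
  set) and the subtracted term includes the same point-charge model as the
  QM calculation.
* ``BLAC`` — bonded link-atom correction layered on ``SUB_VLAC``: bonded
  parameters on the HL side of the junction (and optionally the CL side)
  are replaced from alternate tables; the *J flavour additionally resets the
  Q1-HL bond so its energy matches the Q1-CL bond at every geometry.

Junctions between covalently bonded boundary atoms are handled by removing
every bonded term that contains both atoms from *all* MM evaluations (the
large full-system term included); leaving the term in the full-system term
only, as a file-level truncation would, produces an uncancelled remnant
that breaks the additive/strict-subtractive equivalence.  The nonbonded
exclusions implied by the removed terms are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .backends import MMSurrogateBackend, QMResult
from .charges import (
    ChargeError,
    ChargeSet,
    assign_hl_charges,
    build_point_charge_model,
    zero_region_charges,
)
from .mm import (
    FILTER_ADDITIVE,
    FILTER_ALL,
    EnergyReport,
    embedding_coulomb,
    mm_energy,
)
from .regions import (
    RegionMap,
    _crosses_bonded_cl_pair,
    build_truncated_topology,
    place_link_atoms,
    project_link_gradient,
    scale_link_force_constant,
)
from .topology import BondTerm, Structure, Topology, canonical_bond
from .units import KCAL_PER_MOL_TO_KJ_PER_MOL

__all__ = [
    "SchemeError",
    "SchemeConfig",
    "SCHEMES",
    "compute_scheme_energy",
    "energy_additive",
    "energy_subtractive",
    "apply_blac_parameters",
    "scheme_decomposition",
    "make_objective",
]

SCHEMES = ("ADD", "SUB_VLAC", "SUB_STRICT", "ME", "ELAC", "BLAC")

_ALIASES = {
    "add": "ADD",
    "sub": "SUB_VLAC",
    "sub_vlac": "SUB_VLAC",
    "sub-vlac": "SUB_VLAC",
    "sub_strict": "SUB_STRICT",
    "sub-strict": "SUB_STRICT",
    "me": "ME",
    "elac": "ELAC",
    "blac": "BLAC",
}


class SchemeError(ValueError):
    """Raised for inconsistent scheme configuration."""


@dataclass
class SchemeConfig:
    """Everything a scheme evaluation needs beyond topology and geometry.

    ``mm_charges`` defaults to the topology charges.  ``qm_charges`` is a
    full-system-indexed QM-derived charge set whose ``hl_charges`` hold the
    link-atom charges (required for ME and ELAC), and ``merged_charges`` is
    the mechanical-embedding merged set used by the large MM term of ME and
    ELAC.  The BLAC tables map bonded-parameter keys — tuples of atom type
    labels, length 2 (bond: value ``(k, r_eq)``), 3 (angle: ``(k,
    theta_eq)``) or 4 (dihedral: ``(height, periodicity, phase)``) — to
    replacement values; ``blac_rescale_link`` selects the *J flavour.
    """

    scheme: str = "SUB_VLAC"
    mm_charges: ChargeSet | None = None
    qm_charges: ChargeSet | None = None
    merged_charges: ChargeSet | None = None
    blac_hl: dict = field(default_factory=dict)
    blac_cl: dict = field(default_factory=dict)
    blac_rescale_link: bool = False

    def __post_init__(self) -> None:
        key = str(self.scheme).strip().lower()
        self.scheme = _ALIASES.get(key, str(self.scheme).strip().upper())
        if self.scheme not in SCHEMES:
            raise SchemeError(
                f"unknown scheme {self.scheme!r}; expected one of {', '.join(SCHEMES)}")

    @property
    def embedding(self) -> str:
        return "mechanical" if self.scheme == "ME" else "electrostatic"


# ----------------------------------------------------------------------
# Gradient scatter helpers
# ----------------------------------------------------------------------

def _scatter_sys1(n_atoms: int, sys1: list[int], grad: np.ndarray) -> np.ndarray:
    out = np.zeros((n_atoms, 3))
    if sys1:
        out[sys1] = grad
    return out


def _scatter_indices(n_atoms: int, indices: list[int], grad) -> np.ndarray:
    out = np.zeros((n_atoms, 3))
    if indices and grad is not None and len(grad):
        out[indices] = np.asarray(grad, dtype=float).reshape(len(indices), 3)
    return out


def _qm_gradient_contribution(
    n_atoms: int,
    region_map: RegionMap,
    link_specs,
    qm_res: QMResult,
    pcm,
) -> np.ndarray:
    """Map a QM result's gradients back onto full-system atoms."""
    sys1 = region_map.qm_indices
    grad = _scatter_sys1(
        n_atoms, sys1,
        project_link_gradient(qm_res.gradient, region_map, link_specs))
    if pcm is not None and qm_res.pc_gradient is not None:
        grad += _scatter_indices(n_atoms, pcm.atom_indices, qm_res.pc_gradient)
    return grad


def _empty_qm_result() -> QMResult:
    return QMResult(energy=0.0, gradient=np.zeros((0, 3)),
                    pc_gradient=None, backend="none")


def _make_veto(region_map: RegionMap):
    pairs = region_map.bonded_cl_pairs
    if not pairs:
        return None
    return lambda atoms: _crosses_bonded_cl_pair(atoms, pairs)


def _resolve_mm_charges(topology: Topology, config: SchemeConfig) -> ChargeSet:
    if config.mm_charges is not None:
        if config.mm_charges.n_atoms != topology.n_atoms:
            raise SchemeError("mm_charges length does not match the topology")
        return config.mm_charges
    return ChargeSet(topology.charges, provenance="mm_original")


def _qm_link_specs(region_map, link_specs, config: SchemeConfig):
    """Link specs with HL charges resolved, for the QM-charged truncated system."""
    if config.qm_charges is None:
        raise SchemeError(f"scheme {config.scheme} requires a QM-derived charge set")
    if config.qm_charges.hl_charges:
        return assign_hl_charges(config.qm_charges, region_map, link_specs)
    missing = [cl for cl, s in link_specs.items() if s.hl_charge is None]
    if missing:
        raise SchemeError(
            f"no link-atom charge available for CL atoms {missing}; provide "
            "hl_charges on the QM charge set or on the link specs")
    return link_specs


# ----------------------------------------------------------------------
# Scheme assembly
# ----------------------------------------------------------------------

def compute_scheme_energy(
    topology: Topology,
    structure: Structure,
    region_map: RegionMap,
    link_specs,
    config: SchemeConfig | None = None,
    qm_backend=None,
) -> EnergyReport:
    """Assemble the requested scheme's total energy and gradient.

    ``qm_backend`` is any object with ``evaluate(structure, point_charges)``;
    when absent an MM surrogate over the internally built truncated topology
    is used, which makes the exact cancelation identities of the subtractive
    assemblies hold by construction.
    """
    config = config or SchemeConfig()
    scheme = config.scheme
    n = topology.n_atoms
    if structure.coords.shape[0] != n:
        raise SchemeError("structure does not match topology atom count")
    mm_charges = _resolve_mm_charges(topology, config)
    veto = _make_veto(region_map)
    sys1 = region_map.qm_indices
    hl_struct = place_link_atoms(structure, region_map, link_specs) if sys1 \
        else Structure(np.zeros((0, 3)))

    if scheme in ("ME", "ELAC"):
        return _assemble_me_elac(topology, structure, region_map, link_specs,
                                 config, qm_backend, mm_charges, veto, hl_struct)
    if scheme == "ADD":
        return _assemble_additive(topology, structure, region_map, link_specs,
                                  config, qm_backend, mm_charges, veto, hl_struct)
    return _assemble_subtractive_ee(topology, structure, region_map, link_specs,
                                    config, qm_backend, mm_charges, veto, hl_struct)


def _evaluate_qm(qm_backend, surrogate_topology, hl_struct, pcm) -> QMResult:
    if hl_struct.coords.shape[0] == 0:
        return _empty_qm_result()
    backend = qm_backend if qm_backend is not None \
        else MMSurrogateBackend(surrogate_topology)
    return backend.evaluate(hl_struct, pcm)


def _net_components(qm_energy: float, large: EnergyReport,
                    small: EnergyReport | None) -> dict[str, float]:
    comp = {"qm": qm_energy}
    for k, v in large.components.items():
        comp[k] = v - (small.components.get(k, 0.0) if small is not None else 0.0)
    return comp


def _finish(scheme, total, grad, comp, assembly, meta) -> EnergyReport:
    meta = dict(meta)
    meta["total_kJ_per_mol"] = total * KCAL_PER_MOL_TO_KJ_PER_MOL
    return EnergyReport(total=float(total), gradient=grad, components=comp,
                        scheme=scheme, assembly=assembly, metadata=meta)


def _assemble_additive(topology, structure, region_map, link_specs, config,
                       qm_backend, mm_charges, veto, hl_struct) -> EnergyReport:
    n = topology.n_atoms
    pcm = build_point_charge_model(topology, structure, region_map, mm_charges)
    surrogate_top = None
    if qm_backend is None and region_map.qm_indices:
        surrogate_top, _ = build_truncated_topology(
            topology, region_map, link_specs, charges="keep")
    qm_res = _evaluate_qm(qm_backend, surrogate_top, hl_struct, pcm)

    mm_rep = mm_energy(topology, structure, FILTER_ADDITIVE,
                       charge_set=mm_charges, region_map=region_map,
                       bonded_term_veto=veto)
    total = qm_res.energy + mm_rep.total
    grad = mm_rep.gradient + _qm_gradient_contribution(
        n, region_map, link_specs, qm_res, pcm)
    return _finish(
        "ADD", total, grad,
        _net_components(qm_res.energy, mm_rep, None),
        {"qm": qm_res.energy, "mm2m1": mm_rep.total},
        {"embedding": "electrostatic", "backend": qm_res.backend},
    )


def _assemble_subtractive_ee(topology, structure, region_map, link_specs,
                             config, qm_backend, mm_charges, veto,
                             hl_struct) -> EnergyReport:
    n = topology.n_atoms
    scheme = config.scheme
    sys1 = region_map.qm_indices
    pcm = build_point_charge_model(topology, structure, region_map, mm_charges)

    surrogate_top = None
    if qm_backend is None and sys1:
        surrogate_top, _ = build_truncated_topology(
            topology, region_map, link_specs, charges="keep")
    qm_res = _evaluate_qm(qm_backend, surrogate_top, hl_struct, pcm)

    zeroed = zero_region_charges(mm_charges, region_map, "QM")

    if scheme == "SUB_STRICT":
        mm12_topology = topology
        trunc, _ = build_truncated_topology(
            topology, region_map, link_specs, charges="zero",
            link_representation="CL")
        small_struct = Structure(structure.coords[sys1]) if sys1 \
            else Structure(np.zeros((0, 3)))
        mm1 = mm_energy(trunc, small_struct)
        small_grad_full = _scatter_sys1(n, sys1, mm1.gradient)
    else:
        mm12_topology = topology
        trunc, _ = build_truncated_topology(
            topology, region_map, link_specs, charges="zero",
            link_representation="HL")
        if scheme == "BLAC":
            trunc, mm12_topology = apply_blac_parameters(
                trunc, topology, config.blac_hl, config.blac_cl,
                region_map=region_map, link_specs=link_specs,
                index_map=sys1,
                rescale_link_bonds=config.blac_rescale_link)
        mm1 = mm_energy(trunc, hl_struct)
        small_grad_full = _scatter_sys1(
            n, sys1, project_link_gradient(mm1.gradient, region_map, link_specs))

    mm12 = mm_energy(mm12_topology, structure, FILTER_ALL, charge_set=zeroed,
                     bonded_term_veto=veto)

    total = qm_res.energy + mm12.total - mm1.total
    grad = (mm12.gradient - small_grad_full
            + _qm_gradient_contribution(n, region_map, link_specs, qm_res, pcm))
    return _finish(
        scheme, total, grad,
        _net_components(qm_res.energy, mm12, mm1),
        {"qm": qm_res.energy, "mm12": mm12.total, "minus_mm1": -mm1.total},
        {"embedding": "electrostatic", "backend": qm_res.backend},
    )


def _assemble_me_elac(topology, structure, region_map, link_specs, config,
                      qm_backend, mm_charges, veto, hl_struct) -> EnergyReport:
    n = topology.n_atoms
    scheme = config.scheme
    sys1 = region_map.qm_indices
    if config.merged_charges is None:
        raise SchemeError(f"scheme {scheme} requires merged charges for the "
                          "full-system MM term (see merge_charges_me)")
    if config.merged_charges.n_atoms != n:
        raise SchemeError("merged charge set length does not match the topology")
    specs_q = _qm_link_specs(region_map, link_specs, config)

    trunc, _ = build_truncated_topology(
        topology, region_map, specs_q, charges="qm",
        qm_charges=config.qm_charges, link_representation="HL")

    pcm = None
    if scheme == "ELAC":
        pcm = build_point_charge_model(topology, structure, region_map, mm_charges)
    qm_res = _evaluate_qm(qm_backend, trunc, hl_struct, pcm)

    mm12 = mm_energy(topology, structure, FILTER_ALL,
                     charge_set=config.merged_charges, bonded_term_veto=veto)
    mm1 = mm_energy(trunc, hl_struct)
    mm1_total = mm1.total
    mm1_components = dict(mm1.components)
    small_grad_hl = mm1.gradient.copy()
    small_pc_grad = None
    if scheme == "ELAC" and len(pcm) > 0 and sys1:
        # the subtracted small term sees the identical point-charge model as
        # the QM calculation, with unscaled Coulomb interactions
        e_emb, g_at, small_pc_grad = embedding_coulomb(
            hl_struct.coords, trunc.charges, pcm.positions, pcm.charges)
        mm1_total += e_emb
        mm1_components["elec"] = mm1_components.get("elec", 0.0) + e_emb
        small_grad_hl += g_at

    small_grad_full = _scatter_sys1(
        n, sys1, project_link_gradient(small_grad_hl, region_map, specs_q)) \
        if sys1 else np.zeros((n, 3))
    if small_pc_grad is not None:
        small_grad_full += _scatter_indices(n, pcm.atom_indices, small_pc_grad)

    total = qm_res.energy + mm12.total - mm1_total
    grad = (mm12.gradient - small_grad_full
            + _qm_gradient_contribution(n, region_map, specs_q, qm_res, pcm))
    comp = {"qm": qm_res.energy}
    for k, v in mm12.components.items():
        comp[k] = v - mm1_components.get(k, 0.0)
    return _finish(
        scheme, total, grad, comp,
        {"qm": qm_res.energy, "mm12": mm12.total, "minus_mm1": -mm1_total},
        {"embedding": config.embedding, "backend": qm_res.backend},
    )


# ----------------------------------------------------------------------
# Spec'd entry points
# ----------------------------------------------------------------------

def energy_additive(topology, structure, region_map, link_specs,
                    qm_backend=None, config: SchemeConfig | None = None) -> EnergyReport:
    """Additive electrostatic-embedding assembly."""
    cfg = replace(config, scheme="ADD") if config is not None \
        else SchemeConfig(scheme="ADD")
    return compute_scheme_energy(topology, structure, region_map, link_specs,
                                 cfg, qm_backend)


def energy_subtractive(topology, structure, region_map, link_specs,
                       qm_backend=None, variant: str = "VLAC",
                       config: SchemeConfig | None = None) -> EnergyReport:
    """Subtractive assembly; ``variant`` in {VLAC, STRICT, ME, ELAC, BLAC}."""
    key = variant.strip().upper()
    name = {"VLAC": "SUB_VLAC", "STRICT": "SUB_STRICT",
            "ME": "ME", "ELAC": "ELAC", "BLAC": "BLAC"}.get(key)
    if name is None:
        raise SchemeError(f"unknown subtractive variant {variant!r}")
    cfg = replace(config, scheme=name) if config is not None \
        else SchemeConfig(scheme=name)
    return compute_scheme_energy(topology, structure, region_map, link_specs,
                                 cfg, qm_backend)


# ----------------------------------------------------------------------
# BLAC parameter substitution
# ----------------------------------------------------------------------

def _substitute_params(topology: Topology, table: dict, side: str) -> Topology:
    if not table:
        return topology
    types = [a.type_label for a in topology.atoms]
    used = {tuple(k): 0 for k in table}

    def lookup(tt):
        if tt in used:
            return tt
        if tt[::-1] in used:
            return tt[::-1]
        return None

    bonds = []
    for b in topology.bonds:
        key = lookup((types[b.i], types[b.j]))
        if key is not None:
            k, r_eq = table[key]
            used[key] += 1
            bonds.append(replace(b, k=float(k), r_eq=float(r_eq)))
        else:
            bonds.append(b)
    angles = []
    for a in topology.angles:
        key = lookup((types[a.i], types[a.j], types[a.k_atom]))
        if key is not None:
            k, theta_eq = table[key]
            used[key] += 1
            angles.append(replace(a, k=float(k), theta_eq=float(theta_eq)))
        else:
            angles.append(a)
    dihedrals = []
    for d in topology.dihedrals:
        key = lookup((types[d.i], types[d.j], types[d.k_atom], types[d.l]))
        if key is not None:
            height, periodicity, phase = table[key]
            used[key] += 1
            dihedrals.append(replace(d, height=float(height),
                                     periodicity=int(periodicity),
                                     phase=float(phase)))
        else:
            dihedrals.append(d)

    unused = [k for k, c in used.items() if c == 0]
    if unused:
        raise SchemeError(
            f"BLAC {side}-side parameter keys matched no term: "
            + ", ".join(repr(k) for k in unused))
    return replace(topology, bonds=bonds, angles=angles, dihedrals=dihedrals)


def apply_blac_parameters(
    truncated_topology: Topology,
    full_topology: Topology,
    alt_params_hl: dict | None = None,
    alt_params_cl: dict | None = None,
    *,
    region_map: RegionMap | None = None,
    link_specs=None,
    index_map=None,
    rescale_link_bonds: bool = False,
) -> tuple[Topology, Topology]:
    """Replace bonded parameters around the junction (BLAC).

    ``alt_params_hl`` rewrites matching terms of the truncated (HL-side)
    topology and ``alt_params_cl`` matching terms of the full (CL-side)
    topology; keys are atom-type tuples as in :class:`SchemeConfig`.  Empty
    tables are the identity.  With ``rescale_link_bonds`` (the *J flavour)
    each Q1-HL bond is reset to ``r_eq = r0_hl`` with the force constant of
    :func:`scale_link_force_constant` taken from the current (possibly
    substituted) Q1-CL bond, which makes the two bonds' energies identical
    at every geometry.
    """
    trunc = _substitute_params(truncated_topology, alt_params_hl or {}, "HL")
    full = _substitute_params(full_topology, alt_params_cl or {}, "CL")

    if rescale_link_bonds:
        if region_map is None or link_specs is None or index_map is None:
            raise SchemeError(
                "rescaling link bonds needs region_map, link_specs and index_map")
        slot = {a: s for s, a in enumerate(index_map)}
        full_bonds = {canonical_bond(b.i, b.j): b for b in full.bonds}
        new_bonds = list(trunc.bonds)
        for jn in region_map.junctions:
            spec = link_specs[jn.cl]
            cl_bond = full_bonds.get(canonical_bond(jn.q1, jn.cl))
            if cl_bond is None:
                raise SchemeError(f"no Q1-CL bond for junction at atom {jn.cl}")
            key = canonical_bond(slot[jn.q1], slot[jn.cl])
            for idx, b in enumerate(new_bonds):
                if canonical_bond(b.i, b.j) == key:
                    new_bonds[idx] = BondTerm(
                        b.i, b.j,
                        scale_link_force_constant(cl_bond.k, cl_bond.r_eq, spec.r0_hl),
                        spec.r0_hl)
                    break
            else:
                raise SchemeError(
                    f"no Q1-HL bond in the truncated topology for junction at "
                    f"atom {jn.cl}")
        trunc = replace(trunc, bonds=new_bonds)
    return trunc, full


# ----------------------------------------------------------------------
# Reporting and optimizer plumbing
# ----------------------------------------------------------------------

def scheme_decomposition(report: EnergyReport, units: str = "kcal") -> str:
    """Human-readable breakdown of a scheme report; totals are re-checked."""
    if units not in ("kcal", "kJ"):
        raise ValueError("units must be 'kcal' or 'kJ'")
    scale = 1.0 if units == "kcal" else KCAL_PER_MOL_TO_KJ_PER_MOL
    unit_label = "kcal/mol" if units == "kcal" else "kJ/mol"

    lines = [f"scheme: {report.scheme}"]
    if report.assembly:
        asm_sum = sum(report.assembly.values())
        if abs(asm_sum - report.total) > 1e-9 * max(1.0, abs(report.total)):
            raise SchemeError(
                f"assembly terms sum to {asm_sum!r}, total is {report.total!r}")
        lines.append("assembly terms:")
        for k, v in report.assembly.items():
            lines.append(f"  {k:<12s} {v * scale:18.8f} {unit_label}")
    comp_sum = sum(report.components.values())
    if abs(comp_sum - report.total) > 1e-9 * max(1.0, abs(report.total)):
        raise SchemeError(
            f"components sum to {comp_sum!r}, total is {report.total!r}")
    lines.append("net components:")
    for k, v in report.components.items():
        lines.append(f"  {k:<12s} {v * scale:18.8f} {unit_label}")
    lines.append(f"total        {report.total * scale:18.8f} {unit_label}")
    return "\n".join(lines)


def make_objective(topology, region_map, link_specs,
                   config: SchemeConfig | None = None, qm_backend=None):
    """Callable ``f(coords) -> (energy, gradient)`` over full-system coordinates.

    Accepts a flat ``(3n,)`` vector or an ``(n, 3)`` array; the gradient is
    returned with the same shape as the input.
    """
    n = topology.n_atoms

    def objective(coords):
        arr = np.asarray(coords, dtype=float)
        rep = compute_scheme_energy(
            topology, Structure(arr.reshape(n, 3)), region_map, link_specs,
            config, qm_backend)
        return rep.total, rep.gradient.reshape(arr.shape)

    return objective
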