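"""Geometry minimization with frozen atoms and the structure-comparison metrics.

The optimizer minimizes any scheme objective (``coords -> (energy,
gradient)``) over the non-frozen atoms only; frozen atoms keep bitwise
identical coordinates.  Harmonic distance restraints ``k (r - target)^2``
support constrained scans.  Comparison metrics are the coordinate RMSD
(with optional rigid-body superposition) and the mean absolute deviation of
the bonds, angles and dihedrals of a topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .mm import bond_angle, bond_length, dihedral_angle
from .topology import Structure, Topology

__all__ = [
    "OptimizationError",
    "Restraint",
    "OptimizationSettings",
    "MinimizationResult",
    "minimize",
    "rmsd",
    "mad_internal_coordinates",
]


class OptimizationError(RuntimeError):
    """Raised when a minimization cannot proceed."""


@dataclass(frozen=True)
class Restraint:
    """Harmonic distance restraint ``k (r_ij - target)^2``."""

    i: int
    j: int
    target: float      # A
    k: float           # kcal/mol/A^2

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("restraint atoms must be distinct")
        if self.k <= 0 or self.target < 0:
            raise ValueError("restraint needs k > 0 and target >= 0")


@dataclass
class OptimizationSettings:
    """Convergence thresholds and constraints for :func:`minimize`.

    Defaults: max gradient component 4.5e-4 and RMS gradient 3.0e-4
    (kcal/mol/A scale).  ``frozen`` atoms never move.
    """

    frozen: frozenset = frozenset()
    max_gradient: float = 4.5e-4
    rms_gradient: float = 3.0e-4
    energy_change: float = 1e-10
    max_iterations: int = 2000
    restraints: tuple = ()

    def __post_init__(self) -> None:
        self.frozen = frozenset(int(i) for i in self.frozen)
        if min(self.max_gradient, self.rms_gradient,
               self.energy_change) <= 0 or self.max_iterations < 0:
            raise ValueError("thresholds must be positive")
        self.restraints = tuple(
            r if isinstance(r, Restraint) else Restraint(*r)
            for r in self.restraints)


@dataclass
class MinimizationResult:
    structure: Structure
    energies: list[float]            # energy at start plus each accepted step
    converged: bool
    n_iterations: int
    message: str = ""
    final_max_gradient: float = float("nan")
    final_rms_gradient: float = float("nan")


def _restraint_terms(coords: np.ndarray, restraints) -> tuple[float, np.ndarray]:
    energy = 0.0
    grad = np.zeros_like(coords)
    for res in restraints:
        dvec = coords[res.i] - coords[res.j]
        r = float(np.linalg.norm(dvec))
        if r < 1e-12:
            raise OptimizationError(
                f"restrained atoms {res.i},{res.j} coincide")
        energy += res.k * (r - res.target) ** 2
        g = 2.0 * res.k * (r - res.target) * dvec / r
        grad[res.i] += g
        grad[res.j] -= g
    return energy, grad


def _grad_measures(g_free: np.ndarray) -> tuple[float, float]:
    if g_free.size == 0:
        return 0.0, 0.0
    return float(np.max(np.abs(g_free))), float(np.sqrt(np.mean(g_free ** 2)))


def minimize(
    objective,
    structure: Structure,
    settings: OptimizationSettings | None = None,
) -> MinimizationResult:
    """Minimize ``objective(coords) -> (energy, gradient)`` over free atoms.

    Converged when both the maximum free-gradient component and the RMS free
    gradient fall below the thresholds (a structure already satisfying them
    is returned after zero iterations).  Frozen atoms are excluded from the
    optimization variables entirely, so their coordinates are bitwise
    unchanged.  Restraint energies are included in the reported energies.
    """
    settings = settings or OptimizationSettings()
    coords0 = structure.coords.copy()
    n = coords0.shape[0]
    bad = [i for i in settings.frozen if i < 0 or i >= n]
    if bad:
        raise OptimizationError(f"frozen atom indices out of range: {bad}")
    free = np.array([i for i in range(n) if i not in settings.frozen], dtype=int)

    state: dict = {}

    def evaluate(coords: np.ndarray):
        energy, grad = objective(coords)
        e_res, g_res = _restraint_terms(coords, settings.restraints)
        return float(energy) + e_res, np.asarray(grad, dtype=float) + g_res

    e0, g0 = evaluate(coords0)
    gmax, grms = _grad_measures(g0[free])
    if free.size == 0 or (gmax <= settings.max_gradient
                          and grms <= settings.rms_gradient):
        return MinimizationResult(
            structure=Structure(coords0), energies=[e0], converged=True,
            n_iterations=0, message="already converged",
            final_max_gradient=gmax, final_rms_gradient=grms)

    def fun(x: np.ndarray):
        coords = coords0.copy()
        coords[free] = x.reshape(-1, 3)
        energy, grad = evaluate(coords)
        state["energy"] = energy
        state["g_free"] = grad[free]
        return energy, grad[free].ravel()

    energies = [e0]
    n_iter = [0]

    def callback(xk):
        n_iter[0] += 1
        energies.append(state["energy"])
        gmax, grms = _grad_measures(state["g_free"])
        if gmax <= settings.max_gradient and grms <= settings.rms_gradient:
            raise StopIteration

    # L-BFGS-B's ftol test is relative to |f|; treat ``energy_change`` as an
    # absolute threshold, and restart (resetting the Hessian approximation)
    # if the line search stalls before the gradient thresholds are met.
    x = coords0[free].ravel()
    best = np.inf
    result = None
    while n_iter[0] < settings.max_iterations:
        result = _scipy_minimize(
            fun, x, jac=True, method="L-BFGS-B", callback=callback,
            options={"maxiter": settings.max_iterations - n_iter[0],
                     "ftol": settings.energy_change / max(1.0, abs(e0)),
                     "gtol": 1e-14})
        x = result.x
        gmax, grms = _grad_measures(state["g_free"])
        if gmax <= settings.max_gradient and grms <= settings.rms_gradient:
            break
        if result.fun >= best - settings.energy_change:
            break  # a restart gained nothing: genuinely stalled
        best = result.fun

    coords = coords0.copy()
    coords[free] = x.reshape(-1, 3)
    e_final, g_final = evaluate(coords)
    gmax, grms = _grad_measures(g_final[free])
    converged = gmax <= settings.max_gradient and grms <= settings.rms_gradient
    if not energies or energies[-1] != e_final:
        energies.append(e_final)
    message = "converged" if converged else (
        f"not converged after {n_iter[0]} iterations "
        f"(max |g| = {gmax:.3e}, rms g = {grms:.3e}): "
        + (str(result.message) if result is not None else "no iterations run"))
    return MinimizationResult(
        structure=Structure(coords), energies=energies, converged=converged,
        n_iterations=n_iter[0], message=message,
        final_max_gradient=gmax, final_rms_gradient=grms)


# ----------------------------------------------------------------------
# Structure-comparison metrics
# ----------------------------------------------------------------------

def rmsd(
    structure_a: Structure,
    structure_b: Structure,
    atom_subset=None,
    superpose: bool = False,
) -> float:
    """Coordinate RMSD (A) over ``atom_subset`` (all atoms by default).

    With ``superpose`` the optimal rigid-body superposition (rotation +
    translation, Kabsch) of B onto A is applied first; structures sharing a
    frozen-environment frame should be compared without superposition.
    """
    if atom_subset is None:
        idx = np.arange(structure_a.coords.shape[0])
    else:
        idx = np.asarray(sorted(set(int(i) for i in atom_subset)), dtype=int)
    a = structure_a.coords[idx]
    b = structure_b.coords[idx]
    if a.shape != b.shape:
        raise ValueError("subset sizes differ between the two structures")
    if superpose:
        if a.shape[0] < 3:
            raise ValueError("superposition needs at least 3 atoms")
        a_c = a - a.mean(axis=0)
        b_c = b - b.mean(axis=0)
        rot, _ = Rotation.align_vectors(a_c, b_c)
        b = rot.apply(b_c) + a.mean(axis=0)
        a = a_c + a.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _wrap_degrees(delta: float) -> float:
    """Wrap an angle difference into (-180, 180] degrees."""
    out = (delta + 180.0) % 360.0 - 180.0
    if out <= -180.0:
        out = 180.0
    return out


def mad_internal_coordinates(
    structure_a: Structure,
    structure_b: Structure,
    topology: Topology,
) -> dict[str, float]:
    """MAD of bonds (A), angles and dihedrals (degrees) between two structures.

    Term lists come from the topology (which must describe both structures);
    dihedral differences are wrapped into (-180, 180] degrees before taking
    absolute values, so 179 vs -179 degrees contributes 2, not 358.
    """
    ca, cb = structure_a.coords, structure_b.coords
    if ca.shape != cb.shape or ca.shape[0] != topology.n_atoms:
        raise ValueError("structures must match each other and the topology")

    bond_devs = [abs(bond_length(ca, b.i, b.j) - bond_length(cb, b.i, b.j))
                 for b in topology.bonds]
    angle_devs = [abs(np.degrees(bond_angle(ca, a.i, a.j, a.k_atom))
                      - np.degrees(bond_angle(cb, a.i, a.j, a.k_atom)))
                  for a in topology.angles]
    dihedral_devs = []
    seen = set()
    for d in topology.dihedrals:
        quad = (d.i, d.j, d.k_atom, d.l)
        if quad in seen or d.improper:
            continue
        seen.add(quad)
        da = np.degrees(dihedral_angle(ca, *quad))
        db = np.degrees(dihedral_angle(cb, *quad))
        dihedral_devs.append(abs(_wrap_degrees(da - db)))

    def mean(vals):
        return float(np.mean(vals)) if vals else 0.0

    return {"MAD_bond": mean(bond_devs),
            "MAD_angle": mean(angle_devs),
            "MAD_dihedral": mean(dihedral_devs)}
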