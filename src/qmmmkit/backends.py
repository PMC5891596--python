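"""QM-backend contract and backends requiring no external program.

A backend evaluates the truncated QM system (system 1 with hydrogen link
atoms), optionally embedded in a point-charge model of the environment, and
returns energy plus gradients on the QM atoms and on the point charges.  By
contract the reported energy never includes the self-energy of the point
charges, and the QM--point-charge Coulomb interactions are neither excluded
nor 1-4 scaled — a real electronic-structure code cannot scale them, which
is precisely the embedding asymmetry at the junction.

Backends provided here:

* :class:`MMSurrogateBackend` evaluates the truncated system with the MM
  engine.  Because its energy function is then *exactly* the MM model, the
  cancelation identities of the subtractive assemblies can be checked to
  machine precision with no electronic-structure program.
* :class:`SmoothTestBackend` returns an arbitrary smooth function of the
  coordinates (seeded); swapping it in verifies that scheme bookkeeping is
  independent of what the QM code computes.
* :class:`FileExchangeBackend` couples any external program through plain
  text files.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from .charges import PointChargeModel
from .mm import FILTER_ALL, embedding_coulomb, mm_energy
from .topology import Structure, Topology

__all__ = [
    "QMResult",
    "QMBackend",
    "MMSurrogateBackend",
    "SmoothTestBackend",
    "FileExchangeBackend",
    "surrogate_qm_evaluate",
]


@dataclass
class QMResult:
    energy: float                      # kcal/mol
    gradient: np.ndarray               # (n1, 3) on system-1 atoms incl. HL
    pc_gradient: np.ndarray | None     # (m, 3) on point charges, if embedded
    backend: str = "unknown"


class QMBackend(Protocol):
    def evaluate(
        self,
        structure: Structure,
        point_charges: PointChargeModel | None,
    ) -> QMResult:
        """Energy/gradient of system 1 (HL representation), optionally embedded."""
        ...


@dataclass
class MMSurrogateBackend:
    """MM stand-in for the QM program.

    Evaluates the truncated topology with the MM engine (all terms) using
    ``charge_set`` (the topology's own charges by default) and adds unscaled
    Coulomb interactions between every system-1 atom (including HL) and
    every point charge.
    """

    truncated_topology: Topology
    charge_set: np.ndarray | None = None

    def _charges(self) -> np.ndarray:
        if self.charge_set is None:
            return self.truncated_topology.charges
        return np.asarray(getattr(self.charge_set, "values", self.charge_set), dtype=float)

    def evaluate(self, structure: Structure, point_charges=None) -> QMResult:
        rep = mm_energy(self.truncated_topology, structure, FILTER_ALL,
                        charge_set=self._charges())
        energy = rep.total
        grad = rep.gradient
        pc_grad = None
        if point_charges is not None and len(point_charges) > 0:
            e_emb, g_at, pc_grad = embedding_coulomb(
                structure.coords, self._charges(),
                point_charges.positions, point_charges.charges)
            energy += e_emb
            grad = grad + g_at
        elif point_charges is not None:
            pc_grad = np.zeros((0, 3))
        return QMResult(energy=energy, gradient=grad, pc_gradient=pc_grad,
                        backend="mm-surrogate")


def surrogate_qm_evaluate(
    truncated_topology: Topology,
    structure: Structure,
    point_charge_model: PointChargeModel | None,
    surrogate_charge_set=None,
) -> QMResult:
    """Functional form of :class:`MMSurrogateBackend` (single call)."""
    return MMSurrogateBackend(truncated_topology, surrogate_charge_set).evaluate(
        structure, point_charge_model)


@dataclass
class SmoothTestBackend:
    """Deterministic, smooth, physically meaningless energy function.

    ``E = sum_i a_i sin(b_i . r_i) + sum_{i,m} q_m c_i / (1 + |r_i - s_m|^2)``

    with seeded coefficients.  Useful only for asserting that QM/MM assembly
    bookkeeping does not depend on the backend's internals.
    """

    n_atoms: int
    seed: int = 2024
    _a: np.ndarray = field(init=False, repr=False)
    _b: np.ndarray = field(init=False, repr=False)
    _c: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        self._a = rng.uniform(0.5, 2.0, self.n_atoms)
        self._b = rng.uniform(-1.0, 1.0, (self.n_atoms, 3))
        self._c = rng.uniform(-0.5, 0.5, self.n_atoms)

    def evaluate(self, structure: Structure, point_charges=None) -> QMResult:
        r = structure.coords
        if r.shape[0] != self.n_atoms:
            raise ValueError("structure size does not match backend")
        phase = np.einsum("ix,ix->i", self._b, r)
        energy = float(np.sum(self._a * np.sin(phase)))
        grad = (self._a * np.cos(phase))[:, None] * self._b
        pc_grad = None
        if point_charges is not None:
            pos = point_charges.positions
            pc_grad = np.zeros_like(pos)
            if len(point_charges) > 0:
                diff = r[:, None, :] - pos[None, :, :]
                r2 = np.sum(diff * diff, axis=2)
                w = np.outer(self._c, point_charges.charges)
                energy += float(np.sum(w / (1.0 + r2)))
                f = (-2.0 * w / (1.0 + r2) ** 2)[:, :, None] * diff
                grad = grad + f.sum(axis=1)
                pc_grad = -f.sum(axis=0)
        return QMResult(energy=energy, gradient=grad, pc_gradient=pc_grad,
                        backend="smooth-test")


@dataclass
class FileExchangeBackend:
    """Couple an external QM program through plain-text files.

    Wire format, all in ``workdir`` (lengths in A, charges in e, energies in
    kcal/mol, gradients in kcal/mol/A):

    * ``qm_coords.xyz`` — written: one line per system-1 atom, ``el x y z``
      preceded by a count line and a comment line;
    * ``point_charges.txt`` — written: one line per charge, ``x y z q``
      (absent when the calculation is not embedded);
    * ``qm_energy.txt`` — read: a single number;
    * ``qm_gradient.txt`` — read: one ``gx gy gz`` line per system-1 atom,
      same order as written;
    * ``pc_gradient.txt`` — read when embedded: one line per point charge.

    ``command`` (if given) is run in ``workdir`` between writing and reading.
    """

    workdir: str
    elements: list[str]
    command: list[str] | None = None

    def evaluate(self, structure: Structure, point_charges=None) -> QMResult:
        wd = Path(self.workdir)
        wd.mkdir(parents=True, exist_ok=True)
        coords = structure.coords
        with open(wd / "qm_coords.xyz", "w") as fh:
            fh.write(f"{coords.shape[0]}\nqmmmkit QM system\n")
            for el, (x, y, z) in zip(self.elements, coords):
                fh.write(f"{el:<4s} {x:18.10f} {y:18.10f} {z:18.10f}\n")
        embedded = point_charges is not None
        if embedded:
            with open(wd / "point_charges.txt", "w") as fh:
                for (x, y, z), q in zip(point_charges.positions, point_charges.charges):
                    fh.write(f"{x:18.10f} {y:18.10f} {z:18.10f} {q:14.8f}\n")
        if self.command is not None:
            proc = subprocess.run(self.command, cwd=wd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(
                    f"QM backend command failed ({proc.returncode}): {proc.stderr.strip()}")
        energy = float((wd / "qm_energy.txt").read_text().split()[0])
        grad = np.loadtxt(wd / "qm_gradient.txt", ndmin=2)
        if grad.shape != coords.shape:
            raise RuntimeError("QM gradient dimensions do not match the QM system")
        pc_grad = None
        if embedded:
            pc_grad = np.loadtxt(wd / "pc_gradient.txt", ndmin=2)
            if len(point_charges) == 0:
                pc_grad = np.zeros((0, 3))
            elif pc_grad.shape != point_charges.positions.shape:
                raise RuntimeError("point-charge gradient dimensions mismatch")
        return QMResult(energy=energy, gradient=grad, pc_gradient=pc_grad,
                        backend="file-exchange")
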