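# Methods

This document defines the energy model, the provenance and realism of the
built-in fixtures, the numerical choices, and the known limitations.

## Units and conventions

Internal units are kcal/mol, Å, electron charges and radians throughout;
kJ/mol appears only at reporting time (× 4.184). The force field follows
AMBER conventions:

- bonds and angles: `E = k (x − x₀)²` — **no factor ½**; `k` in
  kcal/mol/Å² and kcal/mol/rad²;
- dihedrals: `E = h (1 + cos(n φ − γ))`, one term per (quad, periodicity);
- Lennard-Jones in Rmin/ε form with Lorentz–Berthelot-style combination
  `Rmin,ij = Rmin,i/2 + Rmin,j/2`, `ε_ij = √(ε_i ε_j)`;
- Coulomb constant 332.0522 kcal·Å/(mol·e²);
- nonbonded pairs separated by one or two bonds are excluded; pairs exactly
  three bonds apart are divided by `scee = 1.2` (electrostatics) and
  `scnb = 2.0` (vdW), stored per pair so file round trips preserve them;
- **no nonbonded cutoff** of any kind — a deliberate choice so that energy
  identities are not polluted by switching functions;
- in `prmtop` files charges are stored multiplied by 18.2223 (the square
  root of the Coulomb constant); the reader divides this back out. Do not
  scale twice.

## Regions, junctions and link atoms

A QM selection is given as atom indices; boundary (CL) atoms are detected as
selected atoms bonded to at least one unselected atom. Each CL must have
exactly one QM neighbour that is not itself a boundary atom — its Q1. The
link atom is placed at

```
r_HL = r_Q1 + g (r_CL − r_Q1),   g = r₀(Q1–HL) / r₀(Q1–CL)
```

with `r₀(Q1–CL)` read from the force field and `r₀(Q1–HL)` a user input (in
practice, the QM-optimized bond length of the truncated model). Because `g`
is constant, HL adds no degrees of freedom and a force on HL splits as
`∂E/∂r_CL += g ∂E/∂r_HL`, `∂E/∂r_Q1 += (1−g) ∂E/∂r_HL`. The Q1–HL bond in
the truncated topology gets `r_eq = r₀(Q1–HL)` and
`k_HL = k_CL (r₀_CL / r₀_HL)²`, the unique force constant for which the HL
bond energy equals the CL bond energy at every geometry (checked over a
50-point grid in the tests).

### Truncated-topology generation

The topology of the capped QM system is generated automatically from the
full topology: system-1 atoms in original order, each CL becoming an HL
(element H, mass 1.008, user-chosen LJ type); bonded terms are those whose
atoms all lie in system 1, with angles/dihedrals through the boundary
keeping their …–CL parameters. Nonbonded exclusions and 1-4 classes are
derived from the **full-system** bond graph, restricted to system-1 pairs,
so intra-QM pair scaling is identical in the full and truncated evaluations;
this is exactly what makes the vdW link-atom difference — and nothing
else — survive the subtraction.

### Covalently bonded boundary atoms

When two CL atoms are bonded to each other (the discouraged junction type,
exercised by the `bonded_cl_dithiolene_analogue` fixture), every bonded term
containing both atoms is removed from **all** MM evaluations: the truncated
topologies in both representations, the subtractive full-system term, and
the additive MM term. Removing them only from the truncated topology (a
file-level truncation) would leave an uncancelled remnant in the subtractive
assemblies and break the additive/strict-subtractive equivalence. The
nonbonded exclusions implied by the removed CL–CL bond are kept — dropping
them would create a near-contact H⋯H Lennard-Jones clash between the two
link atoms. This is a deliberate, documented deviation from a naive
file-truncation workflow.

## Scheme assemblies

With `QM1` the (embedded) QM energy of the capped system, `MM12` the full
system and `MM1` the capped system:

| scheme | assembly | small-term representation | charges |
|---|---|---|---|
| `ADD` | `QM1+ptch2 + MM2−1` | — | MM term: MM–MM electrostatics only |
| `SUB_STRICT` | `QM1+ptch2 + MM12 − MM1` | CL atoms/coords/params | QM-region charges zeroed in both MM terms |
| `SUB_VLAC` | same | HL atoms/coords/params | same |
| `ELAC` | same | HL + the same point-charge model as QM1 | QM-derived charges in both MM terms (merged set in MM12) |
| `BLAC` | `SUB_VLAC` + parameter substitution | HL, alternate bonded tables | as `SUB_VLAC` |
| `ME` | `QM1 + MM12 − MM1` (no point charges) | HL, QM-derived charges | MM12 uses the merged set |

The additive MM term keeps: all-QM bonded terms out (the QM calculation
describes them), bonded terms with ≥1 MM atom in; QM–MM electrostatics out
(they live in the embedded QM term), MM–MM in; vdW in unless both atoms are
QM. The point-charge model contains every MM atom with its unmodified MM
charge at its current position — no deletion or redistribution near the
junction — and CL atoms never appear in it (they are system 1).

The mechanical-embedding merge: QM atoms (except CL) take QM-derived
charges; MM atoms keep MM charges; within each unit containing boundary
atoms, a constant offset is added to each CL atom's *original MM* charge so
the unit total returns to its original integer value (split equally over
multiple CLs; a declared external integer charge can be absorbed too). Units
entirely inside the QM region are exempt (charge transfer across the QM
region is allowed); a unit with a non-integer residual and no CL to absorb
it is an error.

## Fixtures: provenance and realism

Fixture geometries are built from idealized z-matrices (NeRF placement) at
force-field equilibrium values, then jittered with seeded Gaussian noise of
0.01 Å per Cartesian component to break exact symmetries, so gradients and
cancellations are tested at generic geometries. Parameters (`toy-1` set) are
GAFF-magnitude values — realistic stiffness ordering (bonds ≫ angles ≫
torsions), hydrogens with small or zero LJ depth, heteroatom
electronegativity reflected in the charges — but they are a self-contained
toy set, not a validated force field.

- `ethanol_methanol`: ethanol, QM = the methanol-like fragment, CL = the
  methyl carbon C2. The charge columns are the published worked example:
  the environment (Set1) column sums to −0.0001 e — a rounding artifact of
  the four-decimal table, reproduced on purpose — which is why the merged
  set restores a total of exactly 0 while the plain Set1 charges do not.
  The merged boundary charge is −0.1935 e. This fixture's hydroxyl hydrogen
  has zero LJ depth, making its vdW link-atom correction exactly zero — a
  deliberate degenerate case.
- `dipeptide_two_junctions`: an N-methylacetamide-like peptide-bond model
  with both flanking carbons as CL atoms: two junctions in one unit, the
  case where the merge must split the residual equally (+0.01 e per CL with
  the shipped charges).
- `bonded_cl_dithiolene_analogue`: a dimethoxyethane-like chain cut so that
  the two central atoms are both boundary atoms and bonded to each other —
  the cross-junction stress case described above.

## Numerical choices

- Analytic gradients everywhere; angle and dihedral gradients use the
  cross-product formulation with a linearity guard (‖u×v‖ < 1e-12 returns a
  zero gradient for that term rather than NaN).
- Finite-difference validation uses central differences with step 1e-5 Å;
  observed agreement is ~3e-8, asserted at ≤1e-6 kcal/mol/Å.
- The minimizer is L-BFGS-B over free atoms only (frozen atoms are excluded
  from the variables, hence bitwise unchanged). Convergence is declared only
  when both the maximum (4.5e-4) and RMS (3.0e-4 kcal/mol/Å) free-gradient
  thresholds hold; because L-BFGS-B's own `ftol` test is relative to |f|,
  the driver treats the configured energy-change threshold as absolute and
  restarts the optimizer (resetting its Hessian approximation) if it stalls
  on function decrease before the gradient targets are met.
- RMSD superposition uses Kabsch via SciPy's `Rotation.align_vectors`
  (requires ≥3 atoms); dihedral deviations are wrapped into (−180°, 180°]
  before averaging so 179° vs −179° counts as 2°.
- The exact `ADD ≡ SUB_STRICT` and ME/ELAC closure identities are pinned at
  1e-10 but hold to ~1e-14 (a few ULPs of totals ~50 kcal/mol); ME's
  QM1−MM1 cancellation is bitwise with the MM surrogate backend.

## Limitations

- The `toy-1` parameter set is invented (GAFF-like magnitudes); no claim of
  chemical accuracy is made. Reproducing published DFT-based numbers would
  require a real electronic-structure backend through
  `FileExchangeBackend` plus properly generated force-field parameters;
  that profile is out of scope for the shipped tests.
- Enzyme-scale systems are out of scope: fixtures are 9–16 atoms, evaluation
  is O(n²) pairs with no cutoff, and the prmtop writer targets small
  single-molecule topologies.
- The `prmtop` text format carries 8 significant figures (`%16.8E`);
  round-tripped parameters agree to ~1e-7 relative and energies to ~1e-5
  kcal/mol, so exact-identity tests use the native dialect.
- The prmtop dihedral section encodes 1-4 pairs via the spanning dihedral;
  a topology with a 1-4 pair but no dihedral spanning it cannot be
  represented faithfully in that dialect (the native dialect stores pairs
  explicitly).
- Point-charge embedding is unpolarizable and unscreened; no periodic
  boundary conditions, no implicit solvent.
- The link-atom model assumes one Q1 per CL and non-zero Q1–CL separation;
  selections where a boundary atom has zero or several eligible QM
  neighbours are rejected rather than guessed at.
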