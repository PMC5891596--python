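# qmmmkit

A small, exact QM/MM coupling framework. It implements the additive and
subtractive energy assemblies with hydrogen link atoms, mechanical and
electrostatic embedding, and the three link-atom correction levels (van der
Waals, electrostatic, bonded) — engineered so that the identities relating
these schemes hold to machine precision and are enforced by the test suite.

Everything is plain Python (NumPy/SciPy) over an AMBER-style force field:
harmonic bonds and angles (`E = k (x − x₀)²`, no ½), cosine dihedrals,
Lennard-Jones in Rmin/ε form, Coulomb with 332.0522 kcal·Å/(mol·e²), 1-4
scaling via explicit per-pair divisors, and no nonbonded cutoff. Topologies
round-trip through a native text dialect and through AMBER `prmtop`.

## The science in brief

A covalent bond cut by the QM/MM boundary defines a *junction* (Q1, CL): the
boundary atom CL belongs to the QM region (system 1) but is replaced in every
QM calculation by a hydrogen link atom HL placed on the Q1→CL ray at the
fixed fraction `g = r₀(Q1–HL)/r₀(Q1–CL)`. Forces on HL map back onto Q1 and
CL by the chain rule. Two ways to assemble a total energy:

- **Additive (`ADD`)** — one QM term plus one cherry-picked MM term that
  keeps only what the QM term omits: bonded terms with at least one MM atom,
  MM–MM electrostatics (QM–MM electrostatics live in the embedded QM
  calculation), and van der Waals pairs that are not QM–QM.
- **Subtractive (`SUB_*`)** — QM(system 1) + MM(whole system, QM charges
  zeroed) − MM(system 1). Every MM term duplicated between the last two
  pieces cancels *unless deliberately made different*:
  - `SUB_STRICT`: the small term uses the real CL atoms, coordinates and
    parameters — everything cancels and the result **equals `ADD` exactly**;
  - `SUB_VLAC`: the small term uses HL atoms — the boundary-atom van der
    Waals pairs survive the subtraction as an implicit *vdW link-atom
    correction*;
  - `ELAC`: additionally, QM-derived charges replace the MM charges of the
    QM system in both MM terms and the subtracted term sees the same
    point-charge model as the QM calculation (*electrostatic* correction);
  - `BLAC`: alternate bonded parameters around the junction, with an
    optional flavour that rescales the Q1–HL bond (`k_HL = k_CL
    (r₀_CL/r₀_HL)²`) so the junction bond drops out of the assembly at every
    geometry (*bonded* correction).
- **Mechanical embedding (`ME`)** — no point charges anywhere; instead one
  merged full-system charge set: QM atoms take QM-derived charges, MM atoms
  keep MM charges, and each boundary atom absorbs a constant offset so every
  biochemical unit keeps its original integer charge.

The package ships three text-only, programmatically generated fixtures:
`ethanol_methanol` (one junction; the classic charge-merge worked example),
`dipeptide_two_junctions` (a peptide-bond model with two junctions in one
unit), and `bonded_cl_dithiolene_analogue` (two *covalently bonded* boundary
atoms — the discouraged case that stresses cross-junction bookkeeping).

## Worked example

Generate the single-junction fixture (ethanol with a methanol-like QM
region; `--seed` jitters the geometry deterministically), then evaluate:

```console
$ qmmmkit fixtures ethanol_methanol -o demo --seed 11
{"fixture": "ethanol_methanol", "seed": 11, "out": "demo"}

$ qmmmkit energy --dir demo --scheme sub-strict | python -c "
import json, sys
d = json.load(sys.stdin)
print(json.dumps({'scheme': d['scheme'], 'total': d['total'], 'assembly': d['assembly']}, indent=2))
"
{
  "scheme": "SUB_STRICT",
  "total": -20.97506359814637,
  "assembly": {
    "qm": -21.376189885215375,
    "mm12": 0.5880896787645772,
    "minus_mm1": -0.1869633916955732
  }
}
```
(The full report also carries the gradient, the per-class MM decomposition,
and metadata including the total in kJ/mol.)

The additive assembly gives the identical total, `-20.97506359814637`, even
though it is computed from entirely different bookkeeping (term filters
instead of a cancellation). The mechanical-embedding charge merge reproduces
the published worked example — the boundary carbon absorbs the residual and
lands on −0.1935 e:

```console
$ qmmmkit charges --dir demo | grep -A 2 '"C2"'
      "name": "C2",
      "region": "QM",
      "charge": -0.1935
```

From Python, with the two-junction fixture:

```pycon
>>> from qmmmkit import build_fixture, SchemeConfig, compute_scheme_energy, scheme_decomposition
>>> f = build_fixture("dipeptide_two_junctions", seed=11)
>>> vlac = compute_scheme_energy(f.topology, f.structure, f.region_map,
...                              f.link_specs, SchemeConfig("SUB_VLAC"))
>>> print(scheme_decomposition(vlac))
scheme: SUB_VLAC
assembly terms:
  qm                 -56.24639545 kcal/mol
  mm12                 8.07184981 kcal/mol
  minus_mm1           -0.19030491 kcal/mol
net components:
  qm                 -56.24639545 kcal/mol
  bond                 0.18720973 kcal/mol
  angle                0.16859850 kcal/mol
  dihedral             1.47176578 kcal/mol
  vdw                 -0.21373149 kcal/mol
  vdw14                1.18665791 kcal/mol
  elec                 5.08104449 kcal/mol
  elec14               0.00000000 kcal/mol
total              -48.36485054 kcal/mol
>>> add = compute_scheme_energy(f.topology, f.structure, f.region_map,
...                             f.link_specs, SchemeConfig("ADD"))
>>> print(f"{vlac.total - add.total:+.6f}")   # the vdW link-atom correction
+0.680296
```

Other subcommands: `truncate` writes the automatically generated topology of
the capped QM system (native or `prmtop`); `optimize` minimizes any scheme
energy with the MM region frozen and optional harmonic distance restraints;
`compare` reports RMSD (optionally after Kabsch superposition) and mean
absolute deviations of bonds/angles/dihedrals between two structures. All
commands accept a YAML `--config` presetting flags per subcommand, and all
errors come out as one machine-readable JSON line on stderr.

By default no electronic-structure code is involved: the QM term is an *MM
surrogate* over the truncated topology, which is exactly what makes the
cancellation identities testable to machine precision. Any real QM program
can be attached through `FileExchangeBackend` (plain-text coordinate /
point-charge / energy / gradient files) or any object with an
`evaluate(structure, point_charges)` method.

## Reproduction

```bash
pip install --no-build-isolation -e .
python -m pytest -q tests/                  # 201 tests, ~20 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
cat results/acceptance.json
# {"t1": {"value": -0.19349999999999995, "n": 9}}
```

`t1` is the merged charge on the boundary carbon of the ethanol example
(−0.1935 e to the four published decimals). It is computed at runtime from
the charge-merge procedure; the value is exact and seed-independent (the
seed only jitters fixture geometry, which the merge does not use).

See `docs/methods.md` for the model definition, parameter provenance,
numerical choices, and limitations.
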