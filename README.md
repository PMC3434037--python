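# compchem

Tooling for the **CompChem convention** of Chemical Markup Language (CML):
a typed document model, a rule-based convention validator, dictionary/QName
resolution, a converter from a synthetic quantum-chemistry log dialect, RDF
export of the implicit semantics, and a rigid-rotor harmonic-oscillator
(RRHO) thermochemistry calculator that consumes the converted documents.

## The problem

Quantum-chemistry programs write their results as free-text log files whose
numbers carry no machine-readable meaning: the units are implied, the
structure varies by program and version, and "what was the input, what was
the output?" is answered by convention in the reader's head. CompChem
addresses this by layering a convention on CML: every calculation is a
`jobList` of `job` modules, each split into `initialization` (inputs),
`calculation` (steps), `finalization` (outputs) and `environment`
(platform metadata); every value is wrapped in a typed container with an
explicit unit reference; and every concept is pinned to a controlled
vocabulary through dictionary references (`dictRef="cc:basis"` points at
the `basis` entry of the dictionary whose namespace the `cc` prefix is
bound to). Placement carries meaning: a molecule under initialization is a
model input, under finalization a model output. Because the semantics are
explicit, documents can be validated mechanically against the convention's
MUST/SHOULD rules, and translated into RDF triples for indexing and query.

The package is aimed at people who curate computational-chemistry results —
archive builders, combustion/thermochemistry modellers, anyone who needs
log-file content to survive as structured, unit-annotated, queryable data.

## What's inside

| module | purpose |
|---|---|
| `compchem.model` | typed document model, container text parsing, molecule placement roles |
| `compchem.geometry` | z-matrix → Cartesian conversion, distance/angle/dihedral measurement |
| `compchem.dictionary` | dictionary loading, QName resolution, reference audit |
| `compchem.cml_io` | lossless XML reader/writer, deterministic serialization, N-Triples export |
| `compchem.validator` | staged validation pipeline with a ~40-rule registry and a negative-fixture mutator |
| `compchem.logfile` | synthetic Gaussian-style log generator and log → CompChem parser |
| `compchem.thermochem` | RRHO S, H−H(0), Cp, Cv with per-motion and per-mode breakdowns |
| `compchem.fixtures` | conforming reference document and randomized corpora |

The thermochemistry follows the standard ideal-gas statistical mechanics:
Sackur–Tetrode translation, classical rigid rotor with external symmetry
number σ, independent harmonic oscillators with vibrational temperatures
θ = hcν̃/k (zero-point energy excluded from H−H(0) by default), and an
R ln g electronic entropy. Cp = Cv + R holds identically. See
`docs/methods.md` for formulas, conventions and limitations.

## Worked example

Generate a two-job (optimization + frequency analysis) log for a bent
TiO₂-like molecule, convert it, validate it, and compute thermochemistry:

```python
from compchem.logfile import SyntheticLogSpec, generate_log

spec = SyntheticLogSpec(
    elements=["Ti", "O", "O"],
    coordinates=[[0.0, 0.0, 0.6], [1.4, 0.0, -0.25], [-1.4, 0.0, -0.25]],
    jobs=["opt", "freq"],
    scf_energies=[-924.5017, -924.5018],   # hartree
    frequencies=[283.0, 935.0, 962.0],     # cm^-1, 3N-6 = 3 modes
)
open("tio2.log", "w").write(generate_log(spec))
```

```sh
$ compchem convert --from log tio2.log --out tio2.cml
$ compchem validate tio2.cml
stage reached: dictionary
no findings
$ compchem thermo tio2.cml --sigma 2
T = 298.15 K, P = 101325 Pa
motion                    S      H-H(0)        Cv        Cp
                    J/mol/K      kJ/mol   J/mol/K   J/mol/K
translational       163.376       6.197    12.472    20.786
rotational           88.927       3.718    12.472    12.472
vibrational           7.305       1.396    10.794    10.794
electronic            0.000       0.000     0.000     0.000
total               259.608      11.312    35.737    44.052
```

Reading the output: translation dominates the entropy (a 79.9 amu ideal
gas at 1 atm), rotation adds R(ln q_rot + 3/2) for this bent (nonlinear,
σ = 2) molecule, and the three vibrational modes — still mostly frozen at
298 K — contribute 7.3 J mol⁻¹ K⁻¹ of entropy and 10.8 J mol⁻¹ K⁻¹ of heat
capacity. Cp − Cv = R = 8.314 J mol⁻¹ K⁻¹ exactly. H−H(0) is the thermal
enthalpy above the vibrational ground state.

The same pipeline is available as a library
(`parse_log`, `validate`, `thermo_from_document`), and
`compchem convert --to rdf` emits the document's implicit structure as
N-Triples. `compchem validate --format json --strict` gives a
machine-readable report that also fails on SHOULD-level warnings.

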