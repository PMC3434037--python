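# Methods

This note records what the package computes, the conventions it fixes where
the format leaves a choice open, and what the synthetic fixtures do and do
not demonstrate.

## The document model and its placement semantics

A CompChem document is a CML `<module>` declaring the
`http://www.xml-cml.org/convention/compchem` convention and containing one
or more `jobList` modules; a `jobList` wraps an ordered chain of `job`
modules, and each job holds up to four kinds of sub-module identified by
`dictRef`: `initialization` (model inputs), `calculation` (optimization /
iteration steps), `finalization` (model outputs) and `environment`
(hardware/software metadata). Molecules are deliberately neither parameters
nor properties: their meaning is implicit in placement — an input under
initialization or calculation, an output under finalization
(`molecule_role` makes this queryable). Parameter and property values are
never bare text; they wrap a typed container (`scalar`, `array`, `matrix`,
`zMatrix`) carrying `dataType` and a units reference, with `si:none`
marking dimensionless quantities explicitly.

The model stores units as declared and never converts them; conversion is a
caller concern via the unit dictionaries. The tokens `xsd:real`, `xsd:float`
and `xsd:double` map to one floating type internally, but the declared token
is kept for serialization fidelity. Foreign-namespace children are retained
as opaque exclusive-canonical-XML blobs ("extras") because the convention
pervasively allows extra children in any namespace; exclusive
canonicalization makes the blob independent of the embedding document's
namespace declarations, which is what makes byte-stable round-trips
possible.

## Dictionaries

Semantics attach through the three-step dictionary mechanism: define an
`<entry>` (unique `@id`) in a dictionary whose `@namespace` names the
vocabulary; construct a QName by binding a prefix to that namespace URI;
apply it via `@dictRef` (or `@units` / `@unitType` against `unitList` /
`unitTypeList` vocabularies). The registry treats namespace URIs as
identifiers only — nothing is fetched. Unknown references are *warnings*,
never errors: user-defined concepts are legal and their dictionaries may
not be at hand. The bundled core dictionary covers the module concepts plus
the handful of parameter/property concepts the converter emits (method,
basis, scfenergy, frequencies, program metadata, hessian, thermochemistry
outputs); the bundled unit lists cover the units the fixtures use.

## Validation

Four stages run in order — XML well-formedness, CML structural checks
(root namespace, convention declaration, resolvable QName prefixes),
convention rules, dictionary audit — and a stage with ERROR findings
reports them all but halts promotion, so convention errors suppress the
(warning-level) dictionary audit. Severity follows an RFC-2119 reading:
MUST → ERROR, SHOULD → WARNING, MAY → unchecked. Two rules cannot be
machine-checked from a single document and are graded INFO: whether the
document order of multiple calculations really is the step order.

Two places in the rule set required a judgement call:

* the environment row's published clauses are self-contradictory (they both
  require a parameterList-or-user-module child and forbid parameterList
  children). We require at least one of {propertyList, user module} (E3)
  and forbid parameter/parameterList children (E4), which is consistent
  with the row's remaining clauses and with what converted documents
  actually contain (program metadata as properties);
* the matrix container's description lists `xsd:boolean` among example
  types yet declares boolean "not suitable" for matrices; we follow the
  exclusion and reject boolean matrices (D9).

`mutate_fixture` produces, for each registry rule, a minimal mutation of a
conforming document that violates exactly that rule; the test suite runs
validate over all rules × the reference fixture and requires the report to
contain precisely the targeted id. The list of "recommended molecular
conventions" is configurable and defaults to the CML molecular convention
URI; only membership is warned about (I1c), since the format does not
enumerate the recommended set.

## Serialization and RDF export

The writer normalizes prefixes (`cc`, `si`, `nonSi`, `convention`, CML as
default), attribute order and indentation, so identical documents serialize
to identical bytes; prefix spelling and in-scope binding maps are therefore
excluded from model equality, whose unit of meaning is the
(namespace URI, local part) pair. Floats serialize via `repr`, which
round-trips IEEE doubles exactly.

RDF export mints one resource per jobList/job/block from a caller-supplied
base URL by positional path (deterministic and collision-free), links them
with `hasJob` / `hasInitialization` / ... predicates in an artifact-local
vocabulary, and emits one statement per parameter or property whose
predicate is the dictionary-reference URI (namespace + local part). Scalars
become typed literals; arrays and matrices become container resources with
`rdf:_n` member triples (plus rows/columns for matrices). The closed-form
triple count used as the test oracle is an independent model walk. Export
refuses documents with ERROR findings.

## Z-matrix engine

Internal coordinates determine a geometry only up to rigid motion, so a
canonical frame is fixed: atom 1 at the origin, atom 2 on +z, atom 3 in the
xz half-plane with x ≥ 0. Dihedrals follow the IUPAC right-hand-rule sign
convention, reported in (−180°, 180°]. Atoms ≥ 4 are placed by the standard
local-frame construction from the bond/angle/torsion reference atoms; a
torsion whose reference triple is collinear (cross-product norm below
1e-10) raises a degenerate-geometry error rather than returning an
arbitrary plane. Round-trip accuracy (re-measuring every declared internal
coordinate from the emitted Cartesians) is tested to 1e-9 over randomized
valid z-matrices with lengths in [0.5, 3.0] Å and angles in [15°, 165°];
observed worst-case error is ~1e-13.

## Synthetic log dialect

The generator emits a compact Gaussian-style dialect — `Program:`/`Start:`
header, route line `# method/basis jobtype`, a `Standard orientation:`
block of `element x y z` rows (Å, ten decimals), `SCF Done: E(method) =
value` (hartree, ten decimals), `Frequencies --` lines three to a row
(cm⁻¹, four decimals), `End:` timestamp and a `Normal termination`
sentinel per job. A job ends at its termination line; trailing content
after the last termination is a truncation error, matching strict archival
intent. The parser maps each section to a job: input molecule plus method/
basis parameters in the initialization, final geometry plus SCF energy and
frequencies in the finalization, program metadata in the environment — all
numeric containers with explicit unit references.

What the dialect emulates: the block structure and information content of a
real optimization + frequency log. What it does not: vendor formatting
variation across program versions, archive blocks, multi-step route
sections, error terminations and imaginary frequencies. Closure (every
generated log parses, every parsed document validates clean, numbers
survive to 1e-6 relative) therefore demonstrates the converter's
correctness on the dialect, not coverage of real Gaussian/GAMESS output.
Randomized specs draw 1–6 atoms from a ten-element pool with a 0.8 Å
minimum separation, SCF energies in [−500, −10] hartree and 3N−6 (or 3N−5
when linear) positive frequencies in [100, 3500] cm⁻¹ — magnitudes typical
of small-molecule DFT runs.

## RRHO thermochemistry

`compute_thermo` implements the standard ideal-gas rigid-rotor
harmonic-oscillator treatment, the only defensible reading of a
geometry-optimization + frequency-analysis workflow that reports S, H, Cp
and Cv:

* translation: Sackur–Tetrode entropy at (T, P); Cv = 3/2 R; the ideal-gas
  PV = RT term is booked under translation, so H_trans = 5/2 RT and
  Cp − Cv = R holds identically with the +R under translation;
* rotation: classical rigid rotor over the principal moments of inertia,
  divided by the caller-supplied external symmetry number σ (default 1;
  point-group detection is out of scope). Linear molecules use the
  single-moment formula; a principal moment below 1e-10 amu·Å² counts as
  zero for linearity classification;
* vibration: independent harmonic modes with vibrational temperature
  θ = hcν̃/k. By default H − H(0) is referenced to the vibrational ground
  state (zero-point energy excluded); `include_zpe=True` adds Rθ/2 per
  mode. Both references are common in quantum-chemistry reports, hence the
  flag. Overflow-safe cutoffs zero a mode's contributions when θ/T exceeds
  ~700 (S, E) or ~350 (Cv), far below double-precision noise;
* electronic: R ln g entropy for a degeneracy-g ground state, no thermal
  population of excited states.

Imaginary or missing frequencies are rejected with the offending mode index
(transition states are out of scope), and the frequency count must match
3N−6/3N−5 for the classified shape. Constants are CODATA via
`scipy.constants`; atomic masses are standard atomic weights bundled for
~30 common elements. The independent test oracle evaluates the vibrational
partition function by direct summation over the first 10⁴ levels per mode
with its own restated constants; agreement is ~1e-13 relative, well inside
the 1e-6 test tolerance. The argon benchmark reproduces the textbook
standard entropy 154.846 J mol⁻¹ K⁻¹ at the 1-bar standard state.

## Problem sizes

The default suite validates ~41 rule mutations, round-trips 50 randomized
documents, closes the log pipeline over 60 random specs, round-trips 200
random z-matrices (N ≤ 12) and cross-checks 20 random molecules against the
level-summation oracle; the whole suite runs in a few seconds, and
`scripts/acceptance.py` recomputes the same quantities in about one second.
These sizes were chosen to exercise every code path and rule many times
over while keeping the feedback loop instant.

## Known limitations

Only the CompChem subset of CML is modeled (no bonds, formulas, isotopes,
reactions or crystallography); full CML XSD validation is out of scope.
Real vendor logs are not parsed. Hindered rotors, anharmonicity, NASA
polynomial fits and multi-species equilibria are beyond the thermochemistry
module. Dictionary handling implements the fields the referencing mechanism
needs (id, term, definition, declared data type / unit type), not the full
dictionary convention.
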