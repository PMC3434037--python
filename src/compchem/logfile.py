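"""Synthetic quantum-chemistry log dialect: generator and CompChem converter.

Real vendor logs are free-text and version-dependent; archiving them means
parsing the route section, geometries, energies and frequencies into a
structured document. This module defines a compact Gaussian-style dialect
(route line ``# method/basis jobtype``, a ``Standard orientation:`` geometry
block, an ``SCF Done:`` energy line, ``Frequencies --`` lines and a
``Normal termination`` sentinel per job) together with a generator and a
parser that are closed over each other: every generated log parses, and
every parsed document validates with zero ERROR findings.

Energies are stored in hartree and frequencies in cm^-1 with explicit unit
references on every numeric container — units that log files habitually
leave implicit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    COMPCHEM_DICT_NS,
    CONVENTION_NS,
    NONSI_UNIT_NS,
    ArrayValue,
    Atom,
    BlockKind,
    CompChemDocument,
    Job,
    JobList,
    ModuleBlock,
    Molecule,
    Parameter,
    Property,
    QNameRef,
    ScalarValue,
)

__all__ = [
    "SyntheticLogSpec",
    "LogParseError",
    "TruncatedLogError",
    "generate_log",
    "parse_log",
    "roundtrip_check",
    "random_spec",
]

_CC = lambda local: QNameRef("cc", local, COMPCHEM_DICT_NS)  # noqa: E731
_NONSI = lambda local: QNameRef("nonSi", local, NONSI_UNIT_NS)  # noqa: E731
_MOLECULAR = QNameRef("convention", "molecular", CONVENTION_NS)


class LogParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class TruncatedLogError(LogParseError):
    """A job section never reached its termination line."""


@dataclass
class SyntheticLogSpec:
    """Inputs for one synthetic log: geometry, job chain and results.

    ``coordinates`` are Cartesian Angstrom, one row per atom. ``jobs`` is an
    ordered subset of {"opt", "freq"}; ``scf_energies`` (hartree) has one
    entry per job and ``frequencies`` (cm^-1) feeds the freq job.
    """

    elements: list[str]
    coordinates: np.ndarray
    jobs: list[str] = field(default_factory=lambda: ["opt"])
    method: str = "B3LYP"
    basis: str = "6-311+G(d,p)"
    scf_energies: list[float] = field(default_factory=list)
    frequencies: list[float] = field(default_factory=list)
    program: str = "SynthQC"
    version: str = "1.0"
    start: str = "2026-01-01T00:00:00"
    end: str = "2026-01-01T00:10:00"
    seed: int = 0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(
            len(self.elements), 3
        )
        if not self.scf_energies:
            self.scf_energies = [-40.0] * len(self.jobs)
        if len(self.scf_energies) != len(self.jobs):
            raise ValueError("need one SCF energy per job")
        for job in self.jobs:
            if job not in ("opt", "freq"):
                raise ValueError(f"unsupported job type {job!r}")
        if not all(np.isfinite(self.scf_energies)):
            raise ValueError("SCF energies must be finite")
        if "freq" in self.jobs:
            n_expected = expected_mode_count(self.elements, self.coordinates)
            if len(self.frequencies) != n_expected:
                raise ValueError(
                    f"freq job needs {n_expected} frequencies for this geometry, "
                    f"got {len(self.frequencies)}"
                )


def expected_mode_count(elements: Sequence[str], coordinates) -> int:
    """3N-6 vibrational modes for a nonlinear molecule, 3N-5 for a linear
    one, 0 for a single atom."""
    from .thermochem import atomic_mass, classify_linearity

    n = len(elements)
    if n == 1:
        return 0
    masses = np.array([atomic_mass(e) for e in elements])
    shape = classify_linearity(masses, coordinates)
    return max(0, 3 * n - (5 if shape == "linear" else 6))


# ---------------------------------------------------------------------------
# Generation

def generate_log(spec: SyntheticLogSpec) -> str:
    """Emit the log text: one section per job, each with route, geometry,
    SCF energy, (frequencies,) and a termination line. Deterministic."""
    lines: list[str] = []
    for job, energy in zip(spec.jobs, spec.scf_energies):
        lines.append(f" Program: {spec.program} {spec.version}")
        lines.append(f" Start: {spec.start}")
        lines.append(f" # {spec.method}/{spec.basis} {job}")
        lines.append(" Standard orientation:")
        for el, (x, y, z) in zip(spec.elements, spec.coordinates):
            lines.append(f"  {el:<3} {x:18.10f} {y:18.10f} {z:18.10f}")
        lines.append("")
        lines.append(f" SCF Done: E({spec.method}) = {energy:.10f}")
        if job == "freq":
            freqs = list(spec.frequencies)
            for i in range(0, len(freqs), 3):
                chunk = "  ".join(f"{v:12.4f}" for v in freqs[i : i + 3])
                lines.append(f" Frequencies -- {chunk}")
        lines.append(f" End: {spec.end}")
        lines.append(" Normal termination")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Parsing

_ROUTE_RE = re.compile(r"^\s*#\s*(\S+)/(\S+)\s+(\S+)\s*$")
_GEOM_RE = re.compile(
    r"^\s*([A-Z][a-z]?)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$"
)
_SCF_RE = re.compile(r"^\s*SCF Done:\s*E\(([^)]*)\)\s*=\s*(-?\d+(?:\.\d+)?)\s*$")
_FREQ_RE = re.compile(r"^\s*Frequencies\s*--\s*(.*)$")
_PROGRAM_RE = re.compile(r"^\s*Program:\s*(\S+)\s+(\S+)\s*$")
_START_RE = re.compile(r"^\s*Start:\s*(\S+)\s*$")
_END_RE = re.compile(r"^\s*End:\s*(\S+)\s*$")
_TERMINATION = "Normal termination"


def _string_param(local: str, text: str) -> Parameter:
    return Parameter(_CC(local), ScalarValue("xsd:string", text))


def _string_prop(local: str, text: str) -> Property:
    return Property(_CC(local), ScalarValue("xsd:string", text))


def _section_to_job(section: list[tuple[int, str]], job_index: int) -> Job:
    method = basis = jobtype = None
    program = version = start = end = None
    energy = None
    freqs: list[float] = []
    atoms: list[Atom] = []
    in_geometry = False
    for lineno, line in section:
        if in_geometry:
            m = _GEOM_RE.match(line)
            if m:
                atoms.append(
                    Atom(
                        id=f"a{len(atoms) + 1}",
                        element=m.group(1),
                        x=float(m.group(2)),
                        y=float(m.group(3)),
                        z=float(m.group(4)),
                    )
                )
                continue
            if line.strip():
                raise LogParseError(
                    f"unparseable geometry row {line.strip()!r}", lineno
                )
            in_geometry = False
            continue
        if "Standard orientation:" in line:
            in_geometry = True
            continue
        for regex, setter in (
            (_ROUTE_RE, "route"),
            (_SCF_RE, "scf"),
            (_FREQ_RE, "freq"),
            (_PROGRAM_RE, "program"),
            (_START_RE, "start"),
            (_END_RE, "end"),
        ):
            m = regex.match(line)
            if not m:
                continue
            if setter == "route":
                method, basis, jobtype = m.group(1), m.group(2), m.group(3)
            elif setter == "scf":
                energy = float(m.group(2))
            elif setter == "freq":
                freqs.extend(float(tok) for tok in m.group(1).split())
            elif setter == "program":
                program, version = m.group(1), m.group(2)
            elif setter == "start":
                start = m.group(1)
            else:
                end = m.group(1)
            break
    if method is None:
        raise LogParseError(f"job section {job_index}: no route line found")
    if not atoms:
        raise LogParseError(f"job section {job_index}: no geometry block found")

    def molecule() -> Molecule:
        return Molecule(
            conventionRef=_MOLECULAR,
            id=f"m{job_index + 1}",
            atoms=[Atom(a.id, a.element, a.x, a.y, a.z) for a in atoms],
        )

    init = ModuleBlock(
        kind=BlockKind.INITIALIZATION,
        molecule=molecule(),
        parameters=[_string_param("method", method), _string_param("basis", basis)],
    )
    properties: list[Property] = []
    if energy is not None:
        properties.append(
            Property(
                _CC("scfenergy"),
                ScalarValue("xsd:double", repr(energy), units=_NONSI("hartree")),
            )
        )
    if freqs:
        properties.append(
            Property(
                _CC("frequencies"),
                ArrayValue(
                    "xsd:double", _NONSI("cm-1"), freqs, size=len(freqs)
                ),
            )
        )
    final = ModuleBlock(
        kind=BlockKind.FINALIZATION,
        molecule=molecule(),
        properties=properties,
    )
    env_props = []
    if program is not None:
        env_props.append(_string_prop("program", program))
        env_props.append(_string_prop("programVersion", version))
    if start is not None:
        env_props.append(_string_prop("startDateTime", start))
    if end is not None:
        env_props.append(_string_prop("endDateTime", end))
    env = ModuleBlock(kind=BlockKind.ENVIRONMENT, properties=env_props) if env_props else None
    return Job(
        title=f"{jobtype} job",
        initialization=init,
        finalization=final,
        environment=env,
    )


def parse_log(text: str) -> CompChemDocument:
    """Convert a synthetic log into a CompChem document.

    One job module per terminated job section; the input molecule, method
    and basis land in the initialization, the final geometry, SCF energy and
    frequencies in the finalization, program metadata in the environment.
    """
    sections: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    terminated = True
    for lineno, line in enumerate(text.splitlines(), start=1):
        if _TERMINATION in line:
            sections.append(current)
            current = []
            terminated = True
            continue
        if line.strip():
            terminated = False
        current.append((lineno, line))
    if not terminated:
        raise TruncatedLogError(
            f"job section {len(sections)} has no termination line"
        )
    if not sections:
        raise LogParseError("no job sections found")
    jobs = [_section_to_job(sec, i) for i, sec in enumerate(sections)]
    doc = CompChemDocument(
        conventionRef=QNameRef("convention", "compchem", CONVENTION_NS),
        jobLists=[JobList(id="joblist1", title="converted log", jobs=jobs)],
    )
    return doc


# ---------------------------------------------------------------------------
# Round trip

@dataclass
class RoundTripResult:
    ok: bool
    diffs: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def _rel_close(a: float, b: float, rtol: float) -> bool:
    return abs(a - b) <= rtol * max(1.0, abs(a), abs(b))


def roundtrip_check(
    spec: SyntheticLogSpec, text: Optional[str] = None, rtol: float = 1e-6
) -> RoundTripResult:
    """generate -> parse and compare method/basis/energies/frequencies/
    geometry against the spec to parsing precision. Pass ``text`` to check
    an externally supplied (possibly corrupted) log against the spec."""
    diffs: list[str] = []
    doc = parse_log(generate_log(spec) if text is None else text)
    jobs = doc.jobLists[0].jobs
    if len(jobs) != len(spec.jobs):
        diffs.append(f"job count: expected {len(spec.jobs)}, got {len(jobs)}")
        return RoundTripResult(False, diffs)
    for ji, (jobtype, job) in enumerate(zip(spec.jobs, jobs)):
        params = {p.dictRef.localPart: p.value.text for p in job.initialization.parameters}
        if params.get("method") != spec.method:
            diffs.append(f"job {ji}: method {params.get('method')!r} != {spec.method!r}")
        if params.get("basis") != spec.basis:
            diffs.append(f"job {ji}: basis {params.get('basis')!r} != {spec.basis!r}")
        props = {p.dictRef.localPart: p.value for p in job.finalization.properties}
        energy = props.get("scfenergy")
        if energy is None or not _rel_close(energy.value, spec.scf_energies[ji], rtol):
            diffs.append(f"job {ji}: SCF energy mismatch")
        mol = job.finalization.molecule
        if [a.element for a in mol.atoms] != list(spec.elements):
            diffs.append(f"job {ji}: element sequence mismatch")
        else:
            got = np.array([[a.x, a.y, a.z] for a in mol.atoms])
            if not np.allclose(got, spec.coordinates, rtol=rtol, atol=rtol):
                diffs.append(f"job {ji}: geometry deviates beyond {rtol}")
        if jobtype == "freq" and spec.frequencies:
            arr = props.get("frequencies")
            if arr is None or len(arr.values) != len(spec.frequencies) or not all(
                _rel_close(a, b, rtol)
                for a, b in zip(arr.values, spec.frequencies)
            ):
                diffs.append(f"job {ji}: frequency mismatch")
        elif jobtype == "opt" and "frequencies" in props:
            diffs.append(f"job {ji}: unexpected frequencies in opt job")
    return RoundTripResult(not diffs, diffs)


# ---------------------------------------------------------------------------
# Randomized specs

_ELEMENT_POOL = ["H", "C", "N", "O", "F", "S", "Cl", "Si", "P", "Ti"]


def random_spec(
    rng: np.random.Generator, n_atoms: Optional[int] = None
) -> SyntheticLogSpec:
    """Draw a random synthetic spec: a geometry with a minimum interatomic
    separation of 0.8 Angstrom, an opt and/or freq job chain, plausible SCF
    energies and positive harmonic frequencies in 100-3500 cm^-1."""
    if n_atoms is None:
        n_atoms = int(rng.integers(1, 7))
    elements = [str(rng.choice(_ELEMENT_POOL)) for _ in range(n_atoms)]
    while True:
        coords = rng.uniform(-2.5, 2.5, size=(n_atoms, 3))
        if n_atoms == 1:
            break
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        if d[np.triu_indices(n_atoms, 1)].min() > 0.8:
            break
    if n_atoms == 1:
        jobs = ["opt"]
    else:
        jobs = [["opt"], ["freq"], ["opt", "freq"]][int(rng.integers(0, 3))]
    n_modes = expected_mode_count(elements, coords)
    freqs = (
        sorted(rng.uniform(100.0, 3500.0, size=n_modes).round(4).tolist())
        if "freq" in jobs
        else []
    )
    energies = (-rng.uniform(10.0, 500.0, size=len(jobs))).round(8).tolist()
    return SyntheticLogSpec(
        elements=elements,
        coordinates=coords.round(10),
        jobs=jobs,
        scf_energies=energies,
        frequencies=freqs,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
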