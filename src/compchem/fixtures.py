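"""Programmatic fixture documents: a fully conforming reference document and
randomized corpora for round-trip and validation testing.

Everything here is synthetic: geometries, energies and frequencies are
generator-defined values with realistic magnitudes, not measurements.
"""

from __future__ import annotations

import numpy as np
from lxml import etree

from .logfile import generate_log, parse_log, random_spec
from .model import (
    COMPCHEM_DICT_NS,
    CONVENTION_NS,
    NONSI_UNIT_NS,
    SI_UNIT_NS,
    ArrayValue,
    Atom,
    BlockKind,
    CompChemDocument,
    Job,
    JobList,
    MatrixValue,
    ModuleBlock,
    Molecule,
    Parameter,
    Property,
    QNameRef,
    ScalarValue,
    ZMatrix,
    ZMatrixRow,
)

__all__ = ["conforming_document", "water_zmatrix", "random_document", "random_corpus"]

_CC = lambda local: QNameRef("cc", local, COMPCHEM_DICT_NS)  # noqa: E731
_NONSI = lambda local: QNameRef("nonSi", local, NONSI_UNIT_NS)  # noqa: E731
_SI_NONE = QNameRef("si", "none", SI_UNIT_NS)
_MOLECULAR = QNameRef("convention", "molecular", CONVENTION_NS)


def water_zmatrix() -> ZMatrix:
    """Bent water: O-H 0.96 Angstrom, H-O-H 104.5 degrees."""
    return ZMatrix(
        rows=[
            ZMatrixRow(element="O"),
            ZMatrixRow(element="H", refs=(1,), length=0.96),
            ZMatrixRow(element="H", refs=(1, 2), length=0.96, angle=104.5),
        ]
    )


def _water_cartesian(mol_id: str) -> Molecule:
    return Molecule(
        conventionRef=_MOLECULAR,
        id=mol_id,
        atoms=[
            Atom("a1", "O", 0.0, 0.0, 0.0),
            Atom("a2", "H", 0.0, 0.0, 0.96),
            Atom("a3", "H", 0.9293284094, 0.0, -0.2404022959),
        ],
    )


def conforming_document() -> CompChemDocument:
    """A document exercising every container kind and all five block kinds,
    valid with zero ERROR and zero WARNING findings against the bundled
    dictionaries."""
    init = ModuleBlock(
        kind=BlockKind.INITIALIZATION,
        molecule=_water_cartesian("m-in"),
        parameters=[
            Parameter(_CC("method"), ScalarValue("xsd:string", "B3LYP")),
            Parameter(_CC("basis"), ScalarValue("xsd:string", "6-311+G(d,p)")),
        ],
    )
    calc = ModuleBlock(
        kind=BlockKind.CALCULATION,
        molecule=Molecule(conventionRef=_MOLECULAR, id="m-z", zmatrix=water_zmatrix()),
        parameters=[Parameter(_CC("jobtype"), ScalarValue("xsd:string", "opt"))],
        properties=[
            Property(
                _CC("scfenergy"),
                ScalarValue("xsd:double", "-76.4089", units=_NONSI("hartree")),
            )
        ],
    )
    final = ModuleBlock(
        kind=BlockKind.FINALIZATION,
        molecule=_water_cartesian("m-out"),
        properties=[
            Property(
                _CC("scfenergy"),
                ScalarValue("xsd:double", "-76.41973", units=_NONSI("hartree")),
            ),
            Property(
                _CC("frequencies"),
                ArrayValue(
                    "xsd:double",
                    _NONSI("cm-1"),
                    [1603.5, 3817.2, 3922.6],
                    size=3,
                ),
            ),
            Property(
                _CC("hessian"),
                MatrixValue(
                    "xsd:double",
                    _NONSI("hartree.bohr-2"),
                    rows=2,
                    columns=2,
                    values=[0.61, -0.05, -0.05, 0.43],
                ),
            ),
        ],
    )
    env = ModuleBlock(
        kind=BlockKind.ENVIRONMENT,
        properties=[
            Property(_CC("program"), ScalarValue("xsd:string", "SynthQC")),
            Property(_CC("programVersion"), ScalarValue("xsd:string", "1.0")),
        ],
    )
    job = Job(
        title="water optimization",
        initialization=init,
        calculations=[calc],
        finalization=final,
        environment=env,
    )
    return CompChemDocument(
        conventionRef=QNameRef("convention", "compchem", CONVENTION_NS),
        jobLists=[JobList(id="joblist1", title="reference job list", jobs=[job])],
    )


# ---------------------------------------------------------------------------
# Randomized corpus

_FOREIGN_NS = "http://example.org/annotations"


def _foreign_extra(rng: np.random.Generator) -> bytes:
    el = etree.Element(f"{{{_FOREIGN_NS}}}note", nsmap={"ann": _FOREIGN_NS})
    el.set("key", f"k{int(rng.integers(0, 1000))}")
    el.text = f"annotation-{int(rng.integers(0, 1000))}"
    if rng.random() < 0.3:
        sub = etree.SubElement(el, f"{{{_FOREIGN_NS}}}detail")
        sub.text = "nested"
    return etree.tostring(el, method="c14n", exclusive=True)


def random_document(rng: np.random.Generator) -> CompChemDocument:
    """A valid random document: a converted random log decorated with
    foreign-namespace extras and optional extra containers."""
    doc = parse_log(generate_log(random_spec(rng)))
    doc.jobLists[0].id = f"joblist{int(rng.integers(1, 10_000))}"
    if rng.random() < 0.5:
        doc.extras.append(_foreign_extra(rng))
    for job in doc.jobLists[0].jobs:
        if rng.random() < 0.4:
            job.extras.append(_foreign_extra(rng))
        if rng.random() < 0.4:
            job.initialization.extras.append(_foreign_extra(rng))
        if rng.random() < 0.3:
            n = int(rng.integers(2, 4))
            job.finalization.properties.append(
                Property(
                    _CC("hessian"),
                    MatrixValue(
                        "xsd:double",
                        _NONSI("hartree.bohr-2"),
                        rows=n,
                        columns=n,
                        values=rng.normal(0, 0.5, size=n * n).round(6).tolist(),
                    ),
                )
            )
        if rng.random() < 0.3:
            job.initialization.parameters.append(
                Parameter(
                    _CC("jobtype"),
                    ScalarValue("xsd:string", str(rng.choice(["opt", "freq"]))),
                )
            )
    return doc


def random_corpus(seed: int, size: int = 50) -> list[CompChemDocument]:
    rng = np.random.default_rng(seed)
    return [random_document(rng) for _ in range(size)]
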