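"""Typed in-memory model of CompChem documents.

The CompChem convention organises a computational-chemistry study as a
``jobList`` of ``job`` modules, each of which may hold an ``initialization``
(model inputs), any number of ``calculation`` steps, a ``finalization``
(model outputs) and an ``environment`` (hardware/software metadata) block.
Values are never bare text: every parameter or property wraps a typed data
container (scalar, array, matrix or z-matrix) carrying an explicit data type
and a units reference.

This module holds only structure and per-container semantics; placement
rules (what a block may contain) are enforced by :mod:`compchem.validator`,
serialization by :mod:`compchem.cml_io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "CML_NS",
    "COMPCHEM_CONVENTION_URI",
    "COMPCHEM_DICT_NS",
    "CONVENTION_NS",
    "MOLECULAR_CONVENTION_URI",
    "SI_UNIT_NS",
    "NONSI_UNIT_NS",
    "XSD_NS",
    "QNameRef",
    "BlockKind",
    "MoleculeRole",
    "ScalarValue",
    "ArrayValue",
    "MatrixValue",
    "ZMatrixRow",
    "ZMatrix",
    "DataContainer",
    "Atom",
    "Molecule",
    "Parameter",
    "Property",
    "ModuleBlock",
    "Job",
    "JobList",
    "CompChemDocument",
    "ContainerParseError",
    "SemanticError",
    "parse_container_text",
    "serialize_container_values",
    "molecule_role",
]

# Published namespace URIs of CML and the CompChem convention.
CML_NS = "http://www.xml-cml.org/schema"
CONVENTION_NS = "http://www.xml-cml.org/convention/"
COMPCHEM_CONVENTION_URI = "http://www.xml-cml.org/convention/compchem"
MOLECULAR_CONVENTION_URI = "http://www.xml-cml.org/convention/molecular"
COMPCHEM_DICT_NS = "http://www.xml-cml.org/dictionary/compchem/"
SI_UNIT_NS = "http://www.xml-cml.org/unit/si/"
NONSI_UNIT_NS = "http://www.xml-cml.org/unit/nonSi/"
XSD_NS = "http://www.w3.org/2001/XMLSchema"


class SemanticError(ValueError):
    """Raised when an operation addresses the model inconsistently."""


class ContainerParseError(ValueError):
    """A container's text does not parse under its declared data type.

    ``index`` is the zero-based position of the offending token.
    """

    def __init__(self, message: str, index: int):
        super().__init__(message)
        self.index = index


@dataclass(frozen=True)
class QNameRef:
    """A resolved qualified-name reference ``prefix:localPart``.

    The (namespaceURI, localPart) pair is the globally unique reference to a
    dictionary entry; the prefix is only the serialization placeholder for
    the namespace URI and does not take part in equality.
    """

    prefix: str = field(compare=False)
    localPart: str
    namespaceURI: str

    def __str__(self) -> str:
        return f"{self.prefix}:{self.localPart}"

    @property
    def pair(self) -> tuple[str, str]:
        return (self.namespaceURI, self.localPart)

    @property
    def uri(self) -> str:
        """Concatenated concept URI (dictionary namespace + entry id)."""
        return self.namespaceURI + self.localPart


class BlockKind(str, Enum):
    INITIALIZATION = "initialization"
    CALCULATION = "calculation"
    FINALIZATION = "finalization"
    ENVIRONMENT = "environment"
    USER_DEFINED = "userDefined"


class MoleculeRole(str, Enum):
    INPUT = "input"
    OUTPUT = "output"


# ---------------------------------------------------------------------------
# Data containers

_FLOAT_TOKENS = {"xsd:double", "xsd:real", "xsd:float"}
_PRIMITIVE_TOKENS = _FLOAT_TOKENS | {"xsd:integer", "xsd:boolean", "xsd:string", "xsd:date"}

_BOOL_LEXICAL = {"true": True, "false": False, "1": True, "0": False}


def _parse_token(token: str, dataType: str, index: int):
    if dataType == "xsd:integer":
        try:
            return int(token)
        except ValueError:
            raise ContainerParseError(
                f"token {token!r} at index {index} is not an xsd:integer", index
            ) from None
    if dataType in _FLOAT_TOKENS:
        try:
            value = float(token)
        except ValueError:
            raise ContainerParseError(
                f"token {token!r} at index {index} is not an {dataType}", index
            ) from None
        if value != value or value in (float("inf"), float("-inf")):
            raise ContainerParseError(
                f"token {token!r} at index {index} is not finite", index
            )
        return value
    if dataType == "xsd:boolean":
        try:
            return _BOOL_LEXICAL[token]
        except KeyError:
            raise ContainerParseError(
                f"token {token!r} at index {index} is not an xsd:boolean", index
            ) from None
    if dataType == "xsd:string":
        return token
    if dataType == "xsd:date":
        if not re.match(r"^\d{4}-\d{2}-\d{2}", token):
            raise ContainerParseError(
                f"token {token!r} at index {index} is not an xsd:date", index
            )
        return token
    raise ContainerParseError(f"unsupported dataType {dataType!r}", index)


def parse_container_text(
    text: str, dataType: str, delimiter: Optional[str] = None
) -> list:
    """Split and type a container's text content.

    Without a declared delimiter the entries are whitespace-separated; with
    one, the text is split on that exact token and empty entries are a parse
    error. Unparseable tokens raise :class:`ContainerParseError` carrying the
    token index.
    """
    if dataType not in _PRIMITIVE_TOKENS:
        raise ContainerParseError(f"dataType {dataType!r} is not a primitive type", 0)
    if delimiter is None:
        tokens = text.split()
    else:
        if delimiter == "":
            raise ContainerParseError("delimiter must be a non-empty token", 0)
        stripped = text.strip()
        tokens = stripped.split(delimiter) if stripped else []
        for i, tok in enumerate(tokens):
            if tok.strip() == "":
                raise ContainerParseError(
                    f"empty token at index {i} under delimiter {delimiter!r}", i
                )
        tokens = [t.strip() for t in tokens]
    return [_parse_token(tok, dataType, i) for i, tok in enumerate(tokens)]


def _serialize_value(value, dataType: str) -> str:
    if dataType == "xsd:boolean":
        return "true" if value else "false"
    if dataType in _FLOAT_TOKENS:
        return repr(float(value))
    return str(value)


def serialize_container_values(
    values: Sequence, dataType: str, delimiter: Optional[str] = None
) -> str:
    """Inverse of :func:`parse_container_text` for typed sequences."""
    sep = " " if delimiter is None else delimiter
    return sep.join(_serialize_value(v, dataType) for v in values)


@dataclass
class ScalarValue:
    """A single typed value; numeric scalars always carry a units reference
    (``si:none`` for dimensionless), string scalars never do."""

    dataType: str
    text: str
    units: Optional[QNameRef] = None
    unitType: Optional[QNameRef] = None

    @property
    def value(self):
        return _parse_token(self.text, self.dataType, 0)


@dataclass
class ArrayValue:
    dataType: str
    units: Optional[QNameRef]
    values: list
    size: Optional[int] = None
    delimiter: Optional[str] = None

    def __post_init__(self):
        if self.size is not None and self.size != len(self.values):
            raise ContainerParseError(
                f"declared size {self.size} != parsed count {len(self.values)}",
                len(self.values),
            )

    @property
    def text(self) -> str:
        return serialize_container_values(self.values, self.dataType, self.delimiter)


@dataclass
class MatrixValue:
    dataType: str
    units: Optional[QNameRef]
    rows: int
    columns: int
    values: list  # row-major
    delimiter: Optional[str] = None

    def __post_init__(self):
        if self.rows < 1 or self.columns < 1:
            raise ContainerParseError("rows and columns must be >= 1", 0)
        if len(self.values) != self.rows * self.columns:
            raise ContainerParseError(
                f"{len(self.values)} values for {self.rows}x{self.columns} matrix",
                len(self.values),
            )

    @property
    def text(self) -> str:
        return serialize_container_values(self.values, self.dataType, self.delimiter)


@dataclass
class ZMatrixRow:
    """One internal-coordinate record.

    ``refs`` are 1-based indices of previously placed atoms: the bond
    partner, the angle partner and the torsion partner, in that order.
    ``length`` is in Angstrom, ``angle`` and ``torsion`` in degrees.
    """

    element: str
    refs: tuple[int, ...] = ()
    length: Optional[float] = None
    angle: Optional[float] = None
    torsion: Optional[float] = None


@dataclass
class ZMatrix:
    rows: list[ZMatrixRow] = field(default_factory=list)

    def validate(self) -> None:
        for k, row in enumerate(self.rows, start=1):
            expected = min(k - 1, 3)
            given = sum(
                x is not None for x in (row.length, row.angle, row.torsion)
            )
            if given != expected or len(row.refs) != expected:
                raise SemanticError(
                    f"z-matrix row {k} must define exactly {expected} internal "
                    f"coordinate(s) referencing earlier atoms"
                )
            for ref in row.refs:
                if not (1 <= ref < k):
                    raise SemanticError(
                        f"z-matrix row {k} references atom {ref}, outside 1..{k - 1}"
                    )
            if len(set(row.refs)) != len(row.refs):
                raise SemanticError(f"z-matrix row {k} repeats a reference atom")
            if row.length is not None and row.length <= 0:
                raise SemanticError(f"z-matrix row {k}: length must be > 0")
            if row.angle is not None and not (0.0 < row.angle < 180.0):
                raise SemanticError(
                    f"z-matrix row {k}: angle must lie strictly in (0, 180) degrees"
                )


DataContainer = Union[ScalarValue, ArrayValue, MatrixValue, ZMatrix]


# ---------------------------------------------------------------------------
# Molecules and modules

@dataclass
class Atom:
    id: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class Molecule:
    """Molecular geometry with exactly one representation populated.

    Coordinates are stored in Angstrom as declared; the model never converts
    units. ``conventionRef`` is required on molecules placed inside CompChem
    modules.
    """

    conventionRef: Optional[QNameRef] = None
    id: Optional[str] = None
    atoms: list[Atom] = field(default_factory=list)
    zmatrix: Optional[ZMatrix] = None
    charge: Optional[int] = None
    spinMultiplicity: Optional[int] = None

    def validate(self) -> None:
        has_cart = bool(self.atoms)
        has_z = self.zmatrix is not None
        if has_cart == has_z:
            raise SemanticError(
                "molecule must hold exactly one geometry representation "
                "(Cartesian atoms or a z-matrix)"
            )
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise SemanticError("atom ids must be unique within a molecule")
        if has_z:
            self.zmatrix.validate()


@dataclass
class Parameter:
    dictRef: QNameRef
    value: DataContainer


@dataclass
class Property:
    dictRef: QNameRef
    value: DataContainer


@dataclass
class ModuleBlock:
    kind: BlockKind
    dictRef: Optional[QNameRef] = None
    molecule: Optional[Molecule] = None
    parameters: Optional[list[Parameter]] = None
    properties: Optional[list[Property]] = None
    userModules: list["ModuleBlock"] = field(default_factory=list)
    extras: list[bytes] = field(default_factory=list)  # canonical-XML foreign children

    def __post_init__(self):
        if self.dictRef is None and self.kind != BlockKind.USER_DEFINED:
            self.dictRef = QNameRef("cc", self.kind.value, COMPCHEM_DICT_NS)


@dataclass
class Job:
    title: Optional[str] = None
    initialization: Optional[ModuleBlock] = None
    calculations: list[ModuleBlock] = field(default_factory=list)
    finalization: Optional[ModuleBlock] = None
    environment: Optional[ModuleBlock] = None
    extras: list[bytes] = field(default_factory=list)

    def blocks(self) -> Iterable[ModuleBlock]:
        if self.initialization is not None:
            yield self.initialization
        yield from self.calculations
        if self.finalization is not None:
            yield self.finalization
        if self.environment is not None:
            yield self.environment


@dataclass
class JobList:
    id: str
    title: Optional[str] = None
    jobs: list[Job] = field(default_factory=list)
    extras: list[bytes] = field(default_factory=list)


@dataclass
class CompChemDocument:
    """Root of a CompChem document: the convention declaration plus one or
    more jobLists.  ``namespaceBindings`` records prefix -> URI bindings in
    scope at the root."""

    conventionRef: QNameRef
    jobLists: list[JobList] = field(default_factory=list)
    # prefix bindings are serialization detail, not semantic content
    namespaceBindings: dict[str, str] = field(default_factory=dict, compare=False)
    extras: list[bytes] = field(default_factory=list)

    def validate(self) -> None:
        if not self.jobLists:
            raise SemanticError("document must contain at least one jobList")
        ids = [jl.id for jl in self.jobLists]
        if len(set(ids)) != len(ids):
            raise SemanticError("jobList ids must be unique within the document")


def molecule_role(
    doc: CompChemDocument, jobIndex: int, blockKind: Union[BlockKind, str]
) -> MoleculeRole:
    """Implicit semantics of molecule placement.

    A molecule under ``initialization`` or ``calculation`` is a model input
    (a parameter); under ``finalization`` it is a model output (a property).
    ``environment`` carries no molecule semantics.
    """
    kind = BlockKind(blockKind)
    jobs = [job for jl in doc.jobLists for job in jl.jobs]
    if not (0 <= jobIndex < len(jobs)):
        raise SemanticError(f"no job at index {jobIndex}")
    job = jobs[jobIndex]
    if kind == BlockKind.INITIALIZATION:
        block = job.initialization
    elif kind == BlockKind.CALCULATION:
        block = next((b for b in job.calculations if b.molecule is not None), None)
    elif kind == BlockKind.FINALIZATION:
        block = job.finalization
    elif kind == BlockKind.ENVIRONMENT:
        raise SemanticError("environment blocks carry no molecule semantics")
    else:
        raise SemanticError(f"no molecule semantics for block kind {kind.value!r}")
    if block is None or block.molecule is None:
        raise SemanticError(
            f"job {jobIndex} has no molecule in its {kind.value} block"
        )
    if kind == BlockKind.FINALIZATION:
        return MoleculeRole.OUTPUT
    return MoleculeRole.INPUT
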