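"""Staged rule-based validation of CompChem documents.

Validation proceeds through four stages — XML well-formedness, CML
structural checks, CompChem convention rules, dictionary-reference audit —
in order; a stage that produces ERROR findings reports them all but halts
promotion to the next stage. Severities follow the RFC-2119 reading of the
convention's keywords: MUST -> ERROR, SHOULD -> WARNING, MAY -> no check.

The convention-rule registry covers the jobList/job/initialization/
calculation/finalization/environment placement rules and the scalar/array/
matrix/zMatrix data-container rules. The rules are implemented natively on
the parsed tree (no XSLT): each finding carries the rule id, severity and
an XPath location addressing the offending node.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Optional, Union

from lxml import etree

from .dictionary import (
    DictionaryRegistry,
    QNameResolutionError,
    builtin_registry,
    resolve_qname,
)
from .model import (
    CML_NS,
    COMPCHEM_CONVENTION_URI,
    COMPCHEM_DICT_NS,
    MOLECULAR_CONVENTION_URI,
    CompChemDocument,
    ContainerParseError,
    parse_container_text,
)

__all__ = [
    "Severity",
    "Finding",
    "ValidationReport",
    "Rule",
    "RULES",
    "validate",
    "mutate_fixture",
    "UnsupportedMutationError",
]

_PRIMITIVES = {
    "xsd:integer",
    "xsd:double",
    "xsd:real",
    "xsd:float",
    "xsd:boolean",
    "xsd:string",
    "xsd:date",
}

#: Conventions accepted by the SHOULD-level molecular-convention check.
RECOMMENDED_MOLECULAR_CONVENTIONS = (MOLECULAR_CONVENTION_URI,)


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"
    INFO = "INFO"


class Stage(str, Enum):
    WELLFORMED = "wellformed"
    STRUCTURAL = "structural"
    CONVENTION = "convention"
    DICTIONARY = "dictionary"


@dataclass(frozen=True)
class Finding:
    ruleId: str
    severity: Severity
    location: str
    message: str


@dataclass
class ValidationReport:
    stageReached: Stage
    findings: list[Finding] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(f.severity == Severity.ERROR for f in self.findings)

    @property
    def clean(self) -> bool:
        return not any(
            f.severity in (Severity.ERROR, Severity.WARNING) for f in self.findings
        )

    def rule_ids(self) -> set[str]:
        return {f.ruleId for f in self.findings}

    def summary(self) -> str:
        lines = [f"stage reached: {self.stageReached.value}"]
        for f in self.findings:
            lines.append(f"{f.severity.value:7} {f.ruleId:5} {f.location}: {f.message}")
        if not self.findings:
            lines.append("no findings")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "stageReached": self.stageReached.value,
            "valid": self.valid,
            "findings": [
                {
                    "ruleId": f.ruleId,
                    "severity": f.severity.value,
                    "location": f.location,
                    "message": f.message,
                }
                for f in self.findings
            ],
        }


@dataclass(frozen=True)
class Rule:
    id: str
    scope: str
    severity: Severity
    description: str


def _r(id, scope, sev, desc) -> Rule:
    return Rule(id, scope, Severity(sev), desc)


RULES: dict[str, Rule] = {
    r.id: r
    for r in [
        _r("W1", "document", "ERROR", "document must be well-formed XML"),
        _r("S1", "document", "ERROR", "root element must be in the CML namespace"),
        _r("S2", "document", "ERROR",
           "root module must declare the compchem convention"),
        _r("S3", "document", "ERROR",
           "every QName attribute must use a bound namespace prefix"),
        _r("JL1", "jobList", "ERROR",
           "jobList must have an id unique within the convention module"),
        _r("JL2", "jobList", "ERROR", "jobList must contain at least one job"),
        _r("JL3", "jobList", "WARNING",
           "jobList should have a non-empty title"),
        _r("J1", "job", "ERROR", "job must contain exactly one initialization"),
        _r("J2", "job", "INFO",
           "calculation order is taken to be step order (not machine-checkable)"),
        _r("J3", "job", "ERROR", "job must contain at most one finalization"),
        _r("J4", "job", "ERROR", "job must contain at most one environment"),
        _r("J6", "job", "ERROR",
           "a job with a calculation must also contain a finalization"),
        _r("J7", "job", "WARNING", "job should have a non-empty title"),
        _r("I1", "initialization", "ERROR",
           "initialization must contain at most one molecule"),
        _r("I1b", "initialization", "ERROR",
           "molecule in a CompChem module must declare a convention"),
        _r("I1c", "initialization", "WARNING",
           "molecule convention should be a recommended molecular convention"),
        _r("I2", "initialization", "ERROR",
           "initialization must contain at most one parameterList"),
        _r("I4", "initialization", "ERROR",
           "initialization must contain a molecule, parameterList or user module"),
        _r("I5", "initialization", "ERROR",
           "initialization must not contain property or propertyList children"),
        _r("C1", "calculation", "ERROR",
           "calculation must contain at most one molecule, with a convention"),
        _r("C2", "calculation", "ERROR",
           "calculation must contain at most one parameterList"),
        _r("C3", "calculation", "ERROR",
           "calculation must contain at most one propertyList"),
        _r("C4", "calculation", "ERROR",
           "calculation must contain a molecule, parameterList, propertyList "
           "or user module"),
        _r("F1", "finalization", "ERROR",
           "finalization must contain at most one molecule, with a convention"),
        _r("F2", "finalization", "ERROR",
           "finalization must contain at most one propertyList"),
        _r("F3", "finalization", "ERROR",
           "finalization must contain a molecule, propertyList or user module"),
        _r("F4", "finalization", "ERROR",
           "finalization must not contain parameter or parameterList children"),
        _r("E1", "environment", "ERROR",
           "environment must contain at most one propertyList"),
        _r("E2", "environment", "ERROR",
           "environment property elements must sit inside a propertyList"),
        _r("E3", "environment", "ERROR",
           "environment must contain a propertyList or user module"),
        _r("E4", "environment", "ERROR",
           "environment must not contain parameter or parameterList children"),
        _r("D1", "scalar", "ERROR", "scalar requires a dataType attribute"),
        _r("D2", "scalar", "ERROR", "scalar dataType must be a primitive type"),
        _r("D3", "scalar", "ERROR",
           "non-string scalar must carry units (si:none when dimensionless)"),
        _r("D4", "scalar", "ERROR",
           "string scalar must not carry units or unitType"),
        _r("D5", "array", "ERROR",
           "array dataType must be a non-string, non-date primitive and the "
           "entries must parse under it"),
        _r("D6", "array", "ERROR", "array must carry units"),
        _r("D7", "array", "ERROR",
           "declared array size must be >= 1 and equal the entry count"),
        _r("D8", "array", "ERROR",
           "a declared delimiter must split the content into non-empty entries"),
        _r("D9", "matrix", "ERROR",
           "matrix dataType must be a primitive other than string, date or "
           "boolean, and the entries must parse under it"),
        _r("D10", "matrix", "ERROR", "matrix must carry units"),
        _r("D11", "matrix", "ERROR",
           "matrix requires rows and columns attributes with values >= 1"),
        _r("D12", "matrix", "ERROR",
           "matrix entry count must equal rows x columns"),
        _r("D13", "zMatrix", "WARNING",
           "zMatrix should be the child of a molecule in a molecular convention"),
        _r("P1", "parameter/property", "ERROR",
           "parameter and property values must be wrapped in a data container, "
           "never bare text"),
        _r("DICT1", "document", "WARNING",
           "dictionary reference does not resolve to a loaded dictionary entry"),
    ]
}


# ---------------------------------------------------------------------------
# Tree helpers

def _localname(el) -> Optional[str]:
    if not isinstance(el.tag, str):
        return None
    q = etree.QName(el)
    return q.localname if q.namespace == CML_NS else None


def _bindings(el) -> dict[str, str]:
    return {p: u for p, u in el.nsmap.items() if p is not None}


def _resolve_pair(token: str, el) -> Optional[tuple[str, str]]:
    try:
        return resolve_qname(token, _bindings(el))
    except QNameResolutionError:
        return None


def _module_kind(el) -> Optional[str]:
    """Resolved CompChem local part of a module's dictRef, if any."""
    token = el.get("dictRef")
    if _localname(el) != "module" or not token:
        return None
    pair = _resolve_pair(token, el)
    if pair and pair[0] == COMPCHEM_DICT_NS:
        return pair[1]
    return None


_BLOCK_KINDS = {"initialization", "calculation", "finalization", "environment"}


class _TreeValidator:
    def __init__(self, root, reg: Optional[DictionaryRegistry],
                 recommended: tuple[str, ...]):
        self.root = root
        self.tree = root.getroottree()
        self.reg = reg
        self.recommended = recommended
        self.findings: list[Finding] = []
        self.order = {el: i for i, el in enumerate(root.iter())}

    def emit(self, rule_id: str, el, message: str) -> None:
        rule = RULES[rule_id]
        self.findings.append(
            Finding(rule_id, rule.severity, self.tree.getpath(el), message)
        )

    def _sorted(self) -> list[Finding]:
        path_order = {self.tree.getpath(el): i for el, i in self.order.items()}
        return sorted(
            self.findings,
            key=lambda f: (path_order.get(f.location, 1 << 30), f.ruleId),
        )

    def has_errors(self) -> bool:
        return any(f.severity == Severity.ERROR for f in self.findings)

    # -- structural stage --------------------------------------------------

    def structural(self) -> None:
        root = self.root
        if not isinstance(root.tag, str) or etree.QName(root).namespace != CML_NS:
            self.emit("S1", root, "root element is not in the CML namespace")
            return
        conv = root.get("convention")
        if not conv:
            self.emit("S2", root, "root module carries no @convention")
        else:
            pair = _resolve_pair(conv, root)
            if pair is None:
                self.emit("S3", root, f"convention QName {conv!r} has an unbound prefix")
            elif pair[0] + pair[1] != COMPCHEM_CONVENTION_URI:
                self.emit(
                    "S2", root,
                    f"convention resolves to {pair[0] + pair[1]!r}, "
                    f"not {COMPCHEM_CONVENTION_URI!r}",
                )
        for el in root.iter():
            if not isinstance(el.tag, str):
                continue
            for attr in ("dictRef", "units", "unitType", "convention"):
                token = el.get(attr)
                if token and _resolve_pair(token, el) is None:
                    self.emit(
                        "S3", el,
                        f"@{attr}={token!r} uses an unbound or malformed prefix",
                    )

    # -- convention stage --------------------------------------------------

    def convention(self) -> None:
        seen_ids: set[str] = set()
        for el in self.root:
            if _module_kind(el) == "jobList":
                self._joblist(el, seen_ids)
        for el in self.root.iter():
            name = _localname(el)
            if name == "scalar":
                self._scalar(el)
            elif name == "array":
                self._array(el)
            elif name == "matrix":
                self._matrix(el)
            elif name == "zMatrix":
                self._zmatrix(el)
            elif name in ("parameter", "property"):
                self._wrapped(el)

    def _joblist(self, el, seen_ids: set[str]) -> None:
        jid = el.get("id")
        if not jid:
            self.emit("JL1", el, "jobList has no @id")
        elif jid in seen_ids:
            self.emit("JL1", el, f"duplicate jobList id {jid!r}")
        else:
            seen_ids.add(jid)
        jobs = [c for c in el if _module_kind(c) == "job"]
        if not jobs:
            self.emit("JL2", el, "jobList contains no job module")
        if not (el.get("title") or "").strip():
            self.emit("JL3", el, "jobList has no non-empty @title")
        for job in jobs:
            self._job(job)

    def _job(self, el) -> None:
        kinds: dict[str, list] = {k: [] for k in _BLOCK_KINDS}
        for c in el:
            k = _module_kind(c)
            if k in kinds:
                kinds[k].append(c)
        n_init = len(kinds["initialization"])
        if n_init != 1:
            self.emit("J1", el, f"job has {n_init} initialization modules, needs exactly 1")
        if len(kinds["calculation"]) > 1:
            self.emit(
                "J2", el,
                f"{len(kinds['calculation'])} calculation modules present; their "
                "document order is taken as the calculation-step order",
            )
        if len(kinds["finalization"]) > 1:
            self.emit("J3", el, "job has more than one finalization module")
        if len(kinds["environment"]) > 1:
            self.emit("J4", el, "job has more than one environment module")
        if kinds["calculation"] and not kinds["finalization"]:
            self.emit("J6", el, "calculation present but no finalization module")
        if not (el.get("title") or "").strip():
            self.emit("J7", el, "job has no non-empty @title")
        for block in kinds["initialization"]:
            self._block_common(block, "initialization")
        for block in kinds["calculation"]:
            self._block_common(block, "calculation")
        for block in kinds["finalization"]:
            self._block_common(block, "finalization")
        for block in kinds["environment"]:
            self._environment(block)

    def _children(self, el, name: str) -> list:
        return [c for c in el if _localname(c) == name]

    def _user_modules(self, el) -> list:
        return [
            c for c in el
            if _localname(c) == "module" and _module_kind(c) not in _BLOCK_KINDS
        ]

    def _check_molecule_convention(self, mol, rule_missing: str,
                                   warn_recommended: bool) -> None:
        conv = mol.get("convention")
        if not conv:
            self.emit(rule_missing, mol, "molecule has no @convention")
            return
        if warn_recommended:
            pair = _resolve_pair(conv, mol)
            uri = pair[0] + pair[1] if pair else conv
            if uri not in self.recommended:
                self.emit(
                    "I1c", mol,
                    f"molecule convention {uri!r} is not a recommended "
                    "molecular convention",
                )

    def _block_common(self, el, kind: str) -> None:
        molecules = self._children(el, "molecule")
        plists = self._children(el, "parameterList")
        prlists = self._children(el, "propertyList")
        users = self._user_modules(el)
        if kind == "initialization":
            if len(molecules) > 1:
                self.emit("I1", el, f"{len(molecules)} molecule children, at most 1 allowed")
            for mol in molecules:
                self._check_molecule_convention(mol, "I1b", warn_recommended=True)
            if len(plists) > 1:
                self.emit("I2", el, "more than one parameterList")
            if not (molecules or plists or users):
                self.emit("I4", el, "initialization is empty of molecule, "
                                    "parameterList and user modules")
            if prlists or self._children(el, "property"):
                self.emit("I5", el, "initialization contains property content")
        elif kind == "calculation":
            if len(molecules) > 1 or any(not m.get("convention") for m in molecules):
                self.emit("C1", el, "calculation molecule rule violated "
                                    "(at most one, with @convention)")
            for mol in molecules:
                if mol.get("convention"):
                    self._check_molecule_convention(mol, "C1", warn_recommended=True)
            if len(plists) > 1:
                self.emit("C2", el, "more than one parameterList")
            if len(prlists) > 1:
                self.emit("C3", el, "more than one propertyList")
            if not (molecules or plists or prlists or users):
                self.emit("C4", el, "calculation has no molecule, parameterList, "
                                    "propertyList or user module")
        elif kind == "finalization":
            if len(molecules) > 1 or any(not m.get("convention") for m in molecules):
                self.emit("F1", el, "finalization molecule rule violated "
                                    "(at most one, with @convention)")
            for mol in molecules:
                if mol.get("convention"):
                    self._check_molecule_convention(mol, "F1", warn_recommended=True)
            if len(prlists) > 1:
                self.emit("F2", el, "more than one propertyList")
            if not (molecules or prlists or users):
                self.emit("F3", el, "finalization has no molecule, propertyList "
                                    "or user module")
            if plists or self._children(el, "parameter"):
                self.emit("F4", el, "finalization contains parameter content")

    def _environment(self, el) -> None:
        prlists = self._children(el, "propertyList")
        users = self._user_modules(el)
        if len(prlists) > 1:
            self.emit("E1", el, "more than one propertyList")
        if self._children(el, "property"):
            self.emit("E2", el, "bare property child outside a propertyList")
        if not (prlists or users):
            self.emit("E3", el, "environment has no propertyList or user module")
        if self._children(el, "parameterList") or self._children(el, "parameter"):
            self.emit("E4", el, "environment contains parameter content")

    # -- data containers ---------------------------------------------------

    def _scalar(self, el) -> None:
        dt = el.get("dataType")
        if dt is None:
            self.emit("D1", el, "scalar without @dataType")
            return
        if dt not in _PRIMITIVES:
            self.emit("D2", el, f"dataType {dt!r} is not a primitive type")
            return
        has_units = el.get("units") is not None
        if dt == "xsd:string":
            if has_units or el.get("unitType") is not None:
                self.emit("D4", el, "string scalar carries units/unitType")
        elif not has_units:
            self.emit("D3", el, "numeric scalar without units")

    def _parse(self, el, dt: str):
        try:
            return parse_container_text(el.text or "", dt, el.get("delimiter"))
        except ContainerParseError as exc:
            return exc

    def _array(self, el) -> None:
        dt = el.get("dataType")
        if dt is None or dt not in _PRIMITIVES or dt in ("xsd:string", "xsd:date"):
            self.emit("D5", el, f"array dataType {dt!r} missing or disallowed")
            return
        values = self._parse(el, dt)
        if isinstance(values, ContainerParseError):
            if el.get("delimiter") is not None and "empty token" in str(values):
                self.emit("D8", el, str(values))
            else:
                self.emit("D5", el, str(values))
            return
        if el.get("units") is None:
            self.emit("D6", el, "array without units")
        size = el.get("size")
        if size is not None:
            try:
                n = int(size)
            except ValueError:
                n = -1
            if n < 1 or n != len(values):
                self.emit(
                    "D7", el,
                    f"declared size {size!r} inconsistent with {len(values)} entries",
                )

    def _matrix(self, el) -> None:
        dt = el.get("dataType")
        if (dt is None or dt not in _PRIMITIVES
                or dt in ("xsd:string", "xsd:date", "xsd:boolean")):
            self.emit("D9", el, f"matrix dataType {dt!r} missing or disallowed")
            return
        values = self._parse(el, dt)
        if isinstance(values, ContainerParseError):
            self.emit("D9", el, str(values))
            return
        if el.get("units") is None:
            self.emit("D10", el, "matrix without units")
        dims = []
        for attr in ("rows", "columns"):
            raw = el.get(attr)
            try:
                n = int(raw) if raw is not None else None
            except ValueError:
                n = None
            dims.append(n)
        if any(n is None or n < 1 for n in dims):
            self.emit("D11", el, "rows/columns missing or < 1")
            return
        if dims[0] * dims[1] != len(values):
            self.emit(
                "D12", el,
                f"{len(values)} entries for a {dims[0]}x{dims[1]} matrix",
            )

    def _zmatrix(self, el) -> None:
        parent = el.getparent()
        ok = parent is not None and _localname(parent) == "molecule"
        if ok:
            conv = parent.get("convention")
            pair = _resolve_pair(conv, parent) if conv else None
            uri = pair[0] + pair[1] if pair else None
            ok = uri in self.recommended
        if not ok:
            self.emit("D13", el, "zMatrix is not inside a molecule in a "
                                 "molecular convention")

    def _wrapped(self, el) -> None:
        has_container = any(isinstance(c.tag, str) for c in el)
        bare_text = (el.text or "").strip() != ""
        if bare_text or not has_container:
            self.emit("P1", el, f"{_localname(el)} value is not wrapped in a "
                                "data container")

    # -- dictionary stage --------------------------------------------------

    def dictionary(self) -> None:
        if self.reg is None:
            return
        for el in self.root.iter():
            if not isinstance(el.tag, str):
                continue
            for attr in ("dictRef", "units", "unitType"):
                token = el.get(attr)
                if not token:
                    continue
                pair = _resolve_pair(token, el)
                if pair is not None and self.reg.lookup(*pair) is None:
                    self.emit(
                        "DICT1", el,
                        f"@{attr}={token!r} has no entry in the loaded dictionaries",
                    )


def _as_tree(source):
    if isinstance(source, CompChemDocument):
        from .cml_io import write_compchem

        return etree.fromstring(write_compchem(source))
    if isinstance(source, etree._Element):
        return source
    if isinstance(source, str):
        source = source.encode()
    if isinstance(source, bytes):
        return etree.fromstring(source)
    return etree.parse(source).getroot()


def validate(
    source: Union[str, bytes, IO, CompChemDocument, "etree._Element"],
    reg: Optional[DictionaryRegistry] = None,
    recommended_conventions: tuple[str, ...] = RECOMMENDED_MOLECULAR_CONVENTIONS,
) -> ValidationReport:
    """Run the staged validation pipeline and return the graded report.

    All problems are findings; only I/O failures raise. When ``reg`` is None
    the bundled core dictionaries are used for the dictionary-audit stage.
    """
    try:
        root = _as_tree(source)
    except etree.XMLSyntaxError as exc:
        return ValidationReport(
            Stage.WELLFORMED,
            [Finding("W1", Severity.ERROR, "/", f"not well-formed XML: {exc}")],
        )
    if reg is None:
        reg = builtin_registry()
    v = _TreeValidator(root, reg, tuple(recommended_conventions))
    v.structural()
    if v.has_errors():
        return ValidationReport(Stage.STRUCTURAL, v._sorted())
    v.convention()
    if v.has_errors():
        return ValidationReport(Stage.CONVENTION, v._sorted())
    v.dictionary()
    return ValidationReport(Stage.DICTIONARY, v._sorted())


# ---------------------------------------------------------------------------
# Negative-fixture generation

class UnsupportedMutationError(ValueError):
    """The requested rule cannot be violated on the given base document."""


def _xp(root, expr):
    hits = root.xpath(expr, namespaces={"c": CML_NS})
    if not hits:
        raise UnsupportedMutationError(f"no node matches {expr!r} in the base document")
    return hits


_MOD = "c:module"


def _module_by_ref(root, local, nth=0):
    for el in root.iter(f"{{{CML_NS}}}module"):
        if _module_kind(el) == local:
            if nth == 0:
                return el
            nth -= 1
    raise UnsupportedMutationError(f"no {local} module in the base document")


def _duplicate(el):
    el.getparent().append(copy.deepcopy(el))


def _first(el, name):
    for c in el:
        if _localname(c) == name:
            return c
    raise UnsupportedMutationError(f"no <{name}> child to mutate")


def _scalar_with(root, predicate, what):
    for el in root.iter(f"{{{CML_NS}}}scalar"):
        if predicate(el):
            return el
    raise UnsupportedMutationError(f"no scalar {what} in the base document")


def mutate_fixture(base: Union[bytes, str, CompChemDocument], rule_id: str) -> bytes:
    """Return a copy of ``base`` violating exactly the targeted rule.

    Useful for exercising the validator: ``validate(mutate_fixture(doc, R))``
    must report R while ``validate(doc)`` must not.
    """
    if rule_id not in RULES:
        raise UnsupportedMutationError(f"unknown rule id {rule_id!r}")
    root = _as_tree(base)
    root = copy.deepcopy(root)

    def joblist():
        return _module_by_ref(root, "jobList")

    def job():
        return _module_by_ref(root, "job")

    def block(kind):
        return _module_by_ref(root, kind)

    if rule_id == "JL1":
        del joblist().attrib["id"]
    elif rule_id == "JL2":
        jl = joblist()
        for c in list(jl):
            if _module_kind(c) == "job":
                jl.remove(c)
    elif rule_id == "JL3":
        del joblist().attrib["title"]
    elif rule_id == "J1":
        el = block("initialization")
        el.getparent().remove(el)
    elif rule_id == "J2":
        _duplicate(block("calculation"))
    elif rule_id == "J3":
        _duplicate(block("finalization"))
    elif rule_id == "J4":
        _duplicate(block("environment"))
    elif rule_id == "J6":
        block("calculation")  # applicability check
        el = block("finalization")
        el.getparent().remove(el)
    elif rule_id == "J7":
        del job().attrib["title"]
    elif rule_id == "I1":
        init = block("initialization")
        init.append(copy.deepcopy(_first(init, "molecule")))
    elif rule_id == "I1b":
        del _first(block("initialization"), "molecule").attrib["convention"]
    elif rule_id == "I1c":
        _first(block("initialization"), "molecule").set(
            "convention", "cc:unratifiedMolecular"
        )
    elif rule_id == "I2":
        _duplicate(_first(block("initialization"), "parameterList"))
    elif rule_id == "I4":
        init = block("initialization")
        for c in list(init):
            init.remove(c)
    elif rule_id == "I5":
        src = _first(block("finalization"), "propertyList")
        block("initialization").append(copy.deepcopy(src))
    elif rule_id == "C1":
        calc = block("calculation")
        calc.append(copy.deepcopy(_first(calc, "molecule")))
    elif rule_id == "C2":
        _duplicate(_first(block("calculation"), "parameterList"))
    elif rule_id == "C3":
        _duplicate(_first(block("calculation"), "propertyList"))
    elif rule_id == "C4":
        calc = block("calculation")
        for c in list(calc):
            calc.remove(c)
    elif rule_id == "F1":
        fin = block("finalization")
        fin.append(copy.deepcopy(_first(fin, "molecule")))
    elif rule_id == "F2":
        _duplicate(_first(block("finalization"), "propertyList"))
    elif rule_id == "F3":
        fin = block("finalization")
        for c in list(fin):
            fin.remove(c)
    elif rule_id == "F4":
        src = _first(block("initialization"), "parameterList")
        block("finalization").append(copy.deepcopy(src))
    elif rule_id == "E1":
        _duplicate(_first(block("environment"), "propertyList"))
    elif rule_id == "E2":
        env = block("environment")
        prop = _first(_first(env, "propertyList"), "property")
        env.append(copy.deepcopy(prop))
    elif rule_id == "E3":
        env = block("environment")
        env.remove(_first(env, "propertyList"))
    elif rule_id == "E4":
        src = _first(block("initialization"), "parameterList")
        block("environment").append(copy.deepcopy(src))
    elif rule_id in ("D1", "D2", "D3"):
        el = _scalar_with(
            root, lambda e: e.get("dataType") not in (None, "xsd:string"),
            "with a numeric dataType",
        )
        if rule_id == "D1":
            del el.attrib["dataType"]
        elif rule_id == "D2":
            el.set("dataType", "xsd:anyURI")
        else:
            if el.get("units") is None:
                raise UnsupportedMutationError("scalar has no units to strip")
            del el.attrib["units"]
    elif rule_id == "D4":
        el = _scalar_with(
            root, lambda e: e.get("dataType") == "xsd:string", "of string type"
        )
        el.set("units", "si:none")
    elif rule_id in ("D5", "D6", "D7", "D8"):
        el = next(root.iter(f"{{{CML_NS}}}array"), None)
        if el is None:
            raise UnsupportedMutationError("no array in the base document")
        if rule_id == "D5":
            el.set("dataType", "xsd:string")
        elif rule_id == "D6":
            del el.attrib["units"]
        elif rule_id == "D7":
            n = len((el.text or "").split())
            el.set("size", str(n + 1))
        else:
            el.set("delimiter", "|")
            el.text = "700.0||810.5"
    elif rule_id in ("D9", "D10", "D11", "D12"):
        el = next(root.iter(f"{{{CML_NS}}}matrix"), None)
        if el is None:
            raise UnsupportedMutationError("no matrix in the base document")
        if rule_id == "D9":
            el.set("dataType", "xsd:boolean")
            el.text = "true false true false"
        elif rule_id == "D10":
            del el.attrib["units"]
        elif rule_id == "D11":
            del el.attrib["rows"]
        else:
            el.set("rows", str(int(el.get("rows")) + 1))
    elif rule_id == "D13":
        el = next(root.iter(f"{{{CML_NS}}}zMatrix"), None)
        if el is None:
            raise UnsupportedMutationError("no zMatrix in the base document")
        mol = el.getparent()
        module = mol.getparent()
        mol.remove(el)
        module.append(el)
    elif rule_id == "P1":
        el = _scalar_with(root, lambda e: True, "at all")
        param = el.getparent()
        text = (el.text or "").strip()
        param.remove(el)
        param.text = text or "bare"
    else:
        raise UnsupportedMutationError(
            f"rule {rule_id!r} has no mutation (stage or audit rule)"
        )
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


#: Rules exercisable through :func:`mutate_fixture` on a rich base fixture.
MUTABLE_RULES = [
    rid for rid in RULES
    if rid not in ("W1", "S1", "S2", "S3", "DICT1")
]
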