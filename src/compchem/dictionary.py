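"""CML dictionaries and the three-step referencing mechanism.

Semantics reach a CompChem document in three steps: (1) a concept is
*defined* as an ``<entry>`` of a dictionary whose ``@namespace`` gives the
vocabulary a globally unique URI; (2) a QName such as ``cc:job`` is
*constructed* by binding a prefix to that URI and using the entry id as the
local part; (3) the QName is *applied* to a container through ``@dictRef``
(and, for units, ``@units``/``@unitType`` against ``<unitList>`` /
``<unitTypeList>`` vocabularies).

Dictionaries are loaded from local files only: the namespace URIs are
identifiers, never fetched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterator, Optional, Union

from lxml import etree

from .model import (
    CML_NS,
    CompChemDocument,
    ArrayValue,
    MatrixValue,
    ModuleBlock,
    QNameRef,
    ScalarValue,
)

__all__ = [
    "DictEntry",
    "Dictionary",
    "DictionaryRegistry",
    "DictionaryError",
    "QNameResolutionError",
    "resolve_qname",
    "load_dictionary",
    "lookup",
    "audit_dictrefs",
    "builtin_registry",
]

_QNAME_LEXICAL = re.compile(r"^([A-Za-z_][\w.\-]*):(\S+)$")

_KINDS = {"dictionary": "concept", "unitList": "unit", "unitTypeList": "unitType"}


class DictionaryError(ValueError):
    """Invalid dictionary document (missing @namespace, duplicate ids...)."""


class QNameResolutionError(ValueError):
    """A serialized QName cannot be resolved against the in-scope bindings."""


@dataclass
class DictEntry:
    id: str
    term: str = ""
    definition: str = ""
    declaredDataType: Optional[str] = None
    declaredUnitType: Optional[str] = None


@dataclass
class Dictionary:
    namespaceURI: str
    title: str = ""
    kind: str = "concept"  # concept | unit | unitType
    entries: dict[str, DictEntry] = field(default_factory=dict)


def resolve_qname(ref: str, bindings: dict[str, str]) -> tuple[str, str]:
    """Resolve ``prefix:localPart`` against a prefix->URI binding map.

    Returns the (namespaceURI, localPart) pair — the globally unique concept
    reference.
    """
    m = _QNAME_LEXICAL.match(ref)
    if not m:
        raise QNameResolutionError(f"{ref!r} is not a valid prefix:localPart QName")
    prefix, local = m.group(1), m.group(2)
    try:
        uri = bindings[prefix]
    except KeyError:
        raise QNameResolutionError(
            f"prefix {prefix!r} has no in-scope namespace binding"
        ) from None
    return uri, local


def resolve_qname_ref(ref: str, bindings: dict[str, str]) -> QNameRef:
    uri, local = resolve_qname(ref, bindings)
    return QNameRef(ref.split(":", 1)[0], local, uri)


def load_dictionary(source: Union[str, bytes, IO]) -> Dictionary:
    """Load a ``<dictionary>``, ``<unitList>`` or ``<unitTypeList>`` document.

    The dictionary element itself lives in the CML XML namespace regardless
    of the vocabulary URI carried by ``@namespace``.
    """
    if isinstance(source, str):
        source = source.encode()
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(source).getroot()
    local = etree.QName(root).localname
    if local not in _KINDS:
        raise DictionaryError(
            f"expected dictionary/unitList/unitTypeList root, got <{local}>"
        )
    ns = root.get("namespace")
    if not ns:
        raise DictionaryError("dictionary is missing the required @namespace")
    d = Dictionary(namespaceURI=ns, title=root.get("title", ""), kind=_KINDS[local])
    child_names = {"dictionary": "entry", "unitList": "unit", "unitTypeList": "unitType"}
    want = child_names[local]
    for el in root:
        if not isinstance(el.tag, str) or etree.QName(el).localname != want:
            continue
        eid = el.get("id")
        if not eid:
            raise DictionaryError(f"<{want}> without an @id")
        if eid in d.entries:
            raise DictionaryError(f"duplicate entry id {eid!r} in dictionary {ns}")
        definition = ""
        for sub in el:
            if isinstance(sub.tag, str) and etree.QName(sub).localname == "definition":
                definition = (sub.text or "").strip()
        d.entries[eid] = DictEntry(
            id=eid,
            term=el.get("term", ""),
            definition=definition,
            declaredDataType=el.get("dataType"),
            declaredUnitType=el.get("unitType"),
        )
    return d


def serialize_dictionary(d: Dictionary) -> bytes:
    root_name = {"concept": "dictionary", "unit": "unitList", "unitType": "unitTypeList"}[d.kind]
    child_name = {"concept": "entry", "unit": "unit", "unitType": "unitType"}[d.kind]
    root = etree.Element(f"{{{CML_NS}}}{root_name}", nsmap={None: CML_NS})
    root.set("namespace", d.namespaceURI)
    if d.title:
        root.set("title", d.title)
    for entry in d.entries.values():
        el = etree.SubElement(root, f"{{{CML_NS}}}{child_name}")
        el.set("id", entry.id)
        if entry.term:
            el.set("term", entry.term)
        if entry.declaredDataType:
            el.set("dataType", entry.declaredDataType)
        if entry.declaredUnitType:
            el.set("unitType", entry.declaredUnitType)
        if entry.definition:
            dfn = etree.SubElement(el, f"{{{CML_NS}}}definition")
            dfn.text = entry.definition
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


class DictionaryRegistry:
    """Loaded vocabularies keyed by namespace URI, partitioned by kind."""

    def __init__(self) -> None:
        self._by_kind: dict[str, dict[str, Dictionary]] = {
            "concept": {},
            "unit": {},
            "unitType": {},
        }

    def add(self, d: Dictionary) -> None:
        kindmap = self._by_kind[d.kind]
        if d.namespaceURI in kindmap:
            raise DictionaryError(
                f"a {d.kind} dictionary for {d.namespaceURI} is already registered"
            )
        kindmap[d.namespaceURI] = d

    def load(self, source) -> Dictionary:
        d = load_dictionary(source)
        self.add(d)
        return d

    def dictionaries(self) -> Iterator[Dictionary]:
        for kindmap in self._by_kind.values():
            yield from kindmap.values()

    def lookup(self, namespaceURI: str, localPart: str) -> Optional[DictEntry]:
        for kindmap in self._by_kind.values():
            d = kindmap.get(namespaceURI)
            if d is not None and localPart in d.entries:
                return d.entries[localPart]
        return None


def lookup(
    ref: tuple[str, str], reg: DictionaryRegistry
) -> Optional[DictEntry]:
    """Apply a resolved (namespaceURI, localPart) reference.

    Unknown references return ``None`` rather than raising: user-defined
    concepts whose dictionaries are not at hand are legal.
    """
    return reg.lookup(*ref)


def builtin_registry() -> DictionaryRegistry:
    """Registry preloaded with the bundled CompChem core dictionary and the
    SI / non-SI unit lists used by the fixture corpus."""
    reg = DictionaryRegistry()
    for name in ("compchem-core.xml", "si-units.xml", "nonsi-units.xml"):
        with resources.files("compchem.data").joinpath(name).open("rb") as fh:
            reg.load(fh)
    return reg


# ---------------------------------------------------------------------------
# Reference audit

def _container_refs(value, path: str):
    if isinstance(value, (ScalarValue, ArrayValue, MatrixValue)):
        if value.units is not None:
            yield (f"{path}/@units", value.units)
        if isinstance(value, ScalarValue) and value.unitType is not None:
            yield (f"{path}/@unitType", value.unitType)


def _block_refs(block: ModuleBlock, path: str):
    if block.dictRef is not None:
        yield (f"{path}/@dictRef", block.dictRef)
    for i, p in enumerate(block.parameters or []):
        ppath = f"{path}/parameter[{i}]"
        yield (f"{ppath}/@dictRef", p.dictRef)
        yield from _container_refs(p.value, ppath)
    for i, p in enumerate(block.properties or []):
        ppath = f"{path}/property[{i}]"
        yield (f"{ppath}/@dictRef", p.dictRef)
        yield from _container_refs(p.value, ppath)
    for i, sub in enumerate(block.userModules):
        yield from _block_refs(sub, f"{path}/module[{i}]")


def iter_references(doc: CompChemDocument):
    """Every QName reference in the document, in document order, as
    (slash-path location, QNameRef) pairs."""
    for li, jl in enumerate(doc.jobLists):
        lpath = f"/jobList[{li}]"
        for ji, job in enumerate(jl.jobs):
            jpath = f"{lpath}/job[{ji}]"
            named = [("initialization", job.initialization)] + [
                (f"calculation[{ci}]", c) for ci, c in enumerate(job.calculations)
            ] + [("finalization", job.finalization), ("environment", job.environment)]
            for name, block in named:
                if block is not None:
                    yield from _block_refs(block, f"{jpath}/{name}")


def audit_dictrefs(
    doc: CompChemDocument, reg: DictionaryRegistry
) -> list[tuple[str, str]]:
    """Report every @dictRef/@units/@unitType that does not resolve to a
    loaded dictionary entry, in document order. Pure report: unknown
    references are legal user-defined concepts, merely unverifiable."""
    out = []
    for location, ref in iter_references(doc):
        if reg.lookup(ref.namespaceURI, ref.localPart) is None:
            out.append((location, str(ref)))
    return out
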