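"""Lossless CompChem XML reader/writer and RDF export.

The writer is deterministic: a fixed namespace-prefix table, fixed attribute
order and fixed indentation make two writes of the same document
byte-identical, so golden-file comparisons are possible. Foreign-namespace
children ("extras") are preserved as opaque canonical-XML subtrees in
document order — the convention explicitly allows extra children in any
namespace, so dropping them would be lossy.

RDF export translates the implicit semantics of element placement into
explicit subject-predicate-object triples: one resource per jobList, job and
block, hierarchy predicates (hasJob, hasInitialization, ...) minted under
the caller's base URL, and one statement per parameter/property whose
predicate is the dictionary-reference URI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Optional, Union

from lxml import etree
from rdflib import Graph, Literal, Namespace, RDF, URIRef, XSD

from .dictionary import resolve_qname
from .model import (
    CML_NS,
    COMPCHEM_CONVENTION_URI,
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
    SemanticError,
    ZMatrix,
    ZMatrixRow,
    parse_container_text,
    serialize_container_values,
)

__all__ = [
    "CMLReadError",
    "CMLWriteError",
    "SerializationProfile",
    "read_compchem",
    "write_compchem",
    "export_rdf",
    "rdf_triple_count",
]

_CML = f"{{{CML_NS}}}"

_KIND_BY_LOCAL = {
    "initialization": BlockKind.INITIALIZATION,
    "calculation": BlockKind.CALCULATION,
    "finalization": BlockKind.FINALIZATION,
    "environment": BlockKind.ENVIRONMENT,
}


class CMLReadError(ValueError):
    pass


class CMLWriteError(ValueError):
    pass


@dataclass
class SerializationProfile:
    """Namespace-prefix preferences and layout policy for the writer."""

    indent: str = "  "
    prefixes: dict[str, str] = field(
        default_factory=lambda: {
            CONVENTION_NS: "convention",
            COMPCHEM_DICT_NS: "cc",
            SI_UNIT_NS: "si",
            NONSI_UNIT_NS: "nonSi",
        }
    )


# ---------------------------------------------------------------------------
# Reading

def _bindings(el) -> dict[str, str]:
    return {p: u for p, u in el.nsmap.items() if p is not None}


def _resolve(token: str, el) -> QNameRef:
    uri, local = resolve_qname(token, _bindings(el))
    return QNameRef(token.split(":", 1)[0], local, uri)


def _c14n(el) -> bytes:
    # exclusive c14n keeps the blob independent of the embedding context's
    # namespace declarations, so extras round-trip byte-stably
    return etree.tostring(el, method="c14n", exclusive=True)


def _local(el) -> Optional[str]:
    if not isinstance(el.tag, str):
        return None
    q = etree.QName(el)
    return q.localname if q.namespace == CML_NS else None


def _read_scalar(el) -> ScalarValue:
    return ScalarValue(
        dataType=el.get("dataType", ""),
        text=(el.text or "").strip(),
        units=_resolve(el.get("units"), el) if el.get("units") else None,
        unitType=_resolve(el.get("unitType"), el) if el.get("unitType") else None,
    )


def _read_array(el) -> ArrayValue:
    data_type = el.get("dataType", "")
    delimiter = el.get("delimiter")
    values = parse_container_text(el.text or "", data_type, delimiter)
    size = el.get("size")
    return ArrayValue(
        dataType=data_type,
        units=_resolve(el.get("units"), el) if el.get("units") else None,
        values=values,
        size=int(size) if size is not None else None,
        delimiter=delimiter,
    )


def _read_matrix(el) -> MatrixValue:
    data_type = el.get("dataType", "")
    delimiter = el.get("delimiter")
    values = parse_container_text(el.text or "", data_type, delimiter)
    return MatrixValue(
        dataType=data_type,
        units=_resolve(el.get("units"), el) if el.get("units") else None,
        rows=int(el.get("rows", "0")),
        columns=int(el.get("columns", "0")),
        values=values,
        delimiter=delimiter,
    )


def _read_zmatrix(el, atom_ids: list[str], elements: dict[str, str]) -> ZMatrix:
    index = {aid: i + 1 for i, aid in enumerate(atom_ids)}
    rows = [ZMatrixRow(element=elements[aid]) for aid in atom_ids]
    for sub in el:
        name = _local(sub)
        if name not in ("length", "angle", "torsion"):
            continue
        refs_attr = {"length": "atomRefs2", "angle": "atomRefs3", "torsion": "atomRefs4"}[name]
        refs = (sub.get(refs_attr) or "").split()
        if not refs or refs[0] not in index:
            raise CMLReadError(f"<{name}> with missing or unknown {refs_attr}")
        k = index[refs[0]]
        row = rows[k - 1]
        value = float((sub.text or "0").strip())
        ref_idx = tuple(index[r] for r in refs[1:])
        if name == "length":
            row.length = value
            row.refs = ref_idx + row.refs[len(ref_idx):]
        elif name == "angle":
            row.angle = value
            if len(ref_idx) == 2:
                row.refs = (row.refs[0] if row.refs else ref_idx[0],) + (ref_idx[1],)
        else:
            row.torsion = value
            if len(ref_idx) == 3:
                row.refs = row.refs[:2] + (ref_idx[2],)
    return ZMatrix(rows=rows)


def _read_molecule(el) -> Molecule:
    conv = el.get("convention")
    mol = Molecule(
        conventionRef=_resolve(conv, el) if conv else None,
        id=el.get("id"),
        charge=int(el.get("formalCharge")) if el.get("formalCharge") else None,
        spinMultiplicity=int(el.get("spinMultiplicity")) if el.get("spinMultiplicity") else None,
    )
    atom_ids: list[str] = []
    elements: dict[str, str] = {}
    cartesian = False
    zmatrix_el = None
    for child in el:
        name = _local(child)
        if name == "atomArray":
            for a in child:
                if _local(a) != "atom":
                    continue
                aid = a.get("id") or f"a{len(atom_ids) + 1}"
                atom_ids.append(aid)
                elements[aid] = a.get("elementType", "")
                if a.get("x3") is not None:
                    cartesian = True
                    mol.atoms.append(
                        Atom(
                            id=aid,
                            element=a.get("elementType", ""),
                            x=float(a.get("x3")),
                            y=float(a.get("y3")),
                            z=float(a.get("z3")),
                        )
                    )
        elif name == "zMatrix":
            zmatrix_el = child
    if zmatrix_el is not None and not cartesian:
        mol.zmatrix = _read_zmatrix(zmatrix_el, atom_ids, elements)
    return mol


def _read_param_like(el, cls):
    dict_ref = el.get("dictRef")
    container = None
    for child in el:
        name = _local(child)
        if name == "scalar":
            container = _read_scalar(child)
        elif name == "array":
            container = _read_array(child)
        elif name == "matrix":
            container = _read_matrix(child)
        if container is not None:
            break
    if dict_ref is None or container is None:
        return None  # invalid; caller keeps the raw element as an extra
    return cls(dictRef=_resolve(dict_ref, el), value=container)


def _read_block(el, kind: BlockKind) -> ModuleBlock:
    dict_ref = el.get("dictRef")
    block = ModuleBlock(
        kind=kind, dictRef=_resolve(dict_ref, el) if dict_ref else None
    )
    for child in el:
        name = _local(child)
        if name == "molecule" and block.molecule is None:
            block.molecule = _read_molecule(child)
        elif name == "parameterList" and block.parameters is None:
            block.parameters = []
            for p in child:
                if _local(p) == "parameter":
                    parsed = _read_param_like(p, Parameter)
                    if parsed is not None:
                        block.parameters.append(parsed)
                        continue
                block.extras.append(_c14n(p))
        elif name == "propertyList" and block.properties is None:
            block.properties = []
            for p in child:
                if _local(p) == "property":
                    parsed = _read_param_like(p, Property)
                    if parsed is not None:
                        block.properties.append(parsed)
                        continue
                block.extras.append(_c14n(p))
        elif name == "module":
            block.userModules.append(_read_block(child, BlockKind.USER_DEFINED))
        else:
            block.extras.append(_c14n(child))
    return block


def _read_job(el) -> Job:
    job = Job(title=el.get("title"))
    for child in el:
        kind = None
        if _local(child) == "module" and child.get("dictRef"):
            try:
                ref = _resolve(child.get("dictRef"), child)
            except Exception:
                ref = None
            if ref is not None and ref.namespaceURI == COMPCHEM_DICT_NS:
                kind = _KIND_BY_LOCAL.get(ref.localPart)
        if kind is None:
            job.extras.append(_c14n(child))
            continue
        block = _read_block(child, kind)
        if kind == BlockKind.INITIALIZATION and job.initialization is None:
            job.initialization = block
        elif kind == BlockKind.CALCULATION:
            job.calculations.append(block)
        elif kind == BlockKind.FINALIZATION and job.finalization is None:
            job.finalization = block
        elif kind == BlockKind.ENVIRONMENT and job.environment is None:
            job.environment = block
        else:
            job.extras.append(_c14n(child))
    return job


def _read_joblist(el) -> JobList:
    jl = JobList(id=el.get("id") or "", title=el.get("title"))
    for child in el:
        is_job = False
        if _local(child) == "module" and child.get("dictRef"):
            try:
                ref = _resolve(child.get("dictRef"), child)
                is_job = ref.pair == (COMPCHEM_DICT_NS, "job")
            except Exception:
                is_job = False
        if is_job:
            jl.jobs.append(_read_job(child))
        else:
            jl.extras.append(_c14n(child))
    return jl


def read_compchem(source: Union[str, bytes, IO]) -> CompChemDocument:
    """Parse a CompChem XML document into the typed model.

    Module kinds are assigned from resolved ``dictRef`` values; modules with
    unrecognized dictRefs become user-defined or opaque extras. Structural
    rule violations are left for the validator — reading is permissive.
    """
    if isinstance(source, str):
        source = source.encode()
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise CMLReadError(f"not well-formed XML: {exc}") from exc
    if not isinstance(root.tag, str) or etree.QName(root).namespace != CML_NS:
        raise CMLReadError(
            f"root element is not in the CML namespace {CML_NS}"
        )
    conv = root.get("convention")
    if not conv:
        raise CMLReadError("root module carries no @convention declaration")
    conv_ref = _resolve(conv, root)
    doc = CompChemDocument(
        conventionRef=conv_ref, namespaceBindings=_bindings(root)
    )
    for child in root:
        is_joblist = False
        if _local(child) == "module" and child.get("dictRef"):
            try:
                ref = _resolve(child.get("dictRef"), child)
                is_joblist = ref.pair == (COMPCHEM_DICT_NS, "jobList")
            except Exception:
                is_joblist = False
        if is_joblist:
            doc.jobLists.append(_read_joblist(child))
        else:
            doc.extras.append(_c14n(child))
    return doc


# ---------------------------------------------------------------------------
# Writing

class _Writer:
    def __init__(self, doc: CompChemDocument, profile: SerializationProfile):
        self.doc = doc
        self.profile = profile
        self.uri_to_prefix = dict(profile.prefixes)
        self.extra_nodes: list[tuple[etree._Element, bytes]] = []
        self._collect_prefixes()

    def _collect_prefixes(self) -> None:
        n = 0
        for ref in self._all_refs():
            if ref.namespaceURI not in self.uri_to_prefix:
                prefix = ref.prefix
                while prefix in self.uri_to_prefix.values():
                    n += 1
                    prefix = f"ns{n}"
                self.uri_to_prefix[ref.namespaceURI] = prefix

    def _all_refs(self):
        yield self.doc.conventionRef
        from .dictionary import iter_references

        for _, ref in iter_references(self.doc):
            yield ref
        for jl in self.doc.jobLists:
            for job in jl.jobs:
                for block in job.blocks():
                    if block.molecule is not None and block.molecule.conventionRef:
                        yield block.molecule.conventionRef

    def qname(self, ref: QNameRef) -> str:
        try:
            return f"{self.uri_to_prefix[ref.namespaceURI]}:{ref.localPart}"
        except KeyError:
            raise CMLWriteError(
                f"no prefix available for namespace {ref.namespaceURI}"
            ) from None

    def build(self) -> etree._Element:
        nsmap = {None: CML_NS}
        for uri, prefix in sorted(self.uri_to_prefix.items(), key=lambda kv: kv[1]):
            nsmap[prefix] = uri
        root = etree.Element(f"{_CML}module", nsmap=nsmap)
        root.set("convention", self.qname(self.doc.conventionRef))
        for jl in self.doc.jobLists:
            root.append(self._joblist(jl))
        self._append_extras(root, self.doc.extras)
        return root

    def _append_extras(self, el, extras: list[bytes]) -> None:
        for blob in extras:
            node = etree.fromstring(blob)
            el.append(node)
            self.extra_nodes.append((node, blob))

    def _joblist(self, jl: JobList) -> etree._Element:
        el = etree.Element(f"{_CML}module")
        el.set("dictRef", self.qname(QNameRef("cc", "jobList", COMPCHEM_DICT_NS)))
        el.set("id", jl.id)
        if jl.title is not None:
            el.set("title", jl.title)
        for job in jl.jobs:
            el.append(self._job(job))
        self._append_extras(el, jl.extras)
        return el

    def _job(self, job: Job) -> etree._Element:
        el = etree.Element(f"{_CML}module")
        el.set("dictRef", self.qname(QNameRef("cc", "job", COMPCHEM_DICT_NS)))
        if job.title is not None:
            el.set("title", job.title)
        for block in job.blocks():
            el.append(self._block(block))
        self._append_extras(el, job.extras)
        return el

    def _block(self, block: ModuleBlock) -> etree._Element:
        el = etree.Element(f"{_CML}module")
        ref = block.dictRef
        if ref is None and block.kind != BlockKind.USER_DEFINED:
            ref = QNameRef("cc", block.kind.value, COMPCHEM_DICT_NS)
        if ref is not None:
            el.set("dictRef", self.qname(ref))
        if block.molecule is not None:
            el.append(self._molecule(block.molecule))
        if block.parameters is not None:
            plist = etree.SubElement(el, f"{_CML}parameterList")
            for p in block.parameters:
                plist.append(self._param_like(p, "parameter"))
        if block.properties is not None:
            plist = etree.SubElement(el, f"{_CML}propertyList")
            for p in block.properties:
                plist.append(self._param_like(p, "property"))
        for sub in block.userModules:
            el.append(self._block(sub))
        self._append_extras(el, block.extras)
        return el

    def _molecule(self, mol: Molecule) -> etree._Element:
        el = etree.Element(f"{_CML}molecule")
        if mol.conventionRef is not None:
            el.set("convention", self.qname(mol.conventionRef))
        if mol.id is not None:
            el.set("id", mol.id)
        if mol.charge is not None:
            el.set("formalCharge", str(mol.charge))
        if mol.spinMultiplicity is not None:
            el.set("spinMultiplicity", str(mol.spinMultiplicity))
        array = etree.SubElement(el, f"{_CML}atomArray")
        if mol.zmatrix is not None:
            ids = [f"a{i + 1}" for i in range(len(mol.zmatrix.rows))]
            for aid, row in zip(ids, mol.zmatrix.rows):
                a = etree.SubElement(array, f"{_CML}atom")
                a.set("id", aid)
                a.set("elementType", row.element)
            zel = etree.SubElement(el, f"{_CML}zMatrix")
            for k, row in enumerate(mol.zmatrix.rows, start=1):
                if row.length is not None:
                    sub = etree.SubElement(zel, f"{_CML}length")
                    sub.set("atomRefs2", f"a{k} a{row.refs[0]}")
                    sub.text = repr(row.length)
                if row.angle is not None:
                    sub = etree.SubElement(zel, f"{_CML}angle")
                    sub.set("atomRefs3", f"a{k} a{row.refs[0]} a{row.refs[1]}")
                    sub.text = repr(row.angle)
                if row.torsion is not None:
                    sub = etree.SubElement(zel, f"{_CML}torsion")
                    sub.set(
                        "atomRefs4",
                        f"a{k} a{row.refs[0]} a{row.refs[1]} a{row.refs[2]}",
                    )
                    sub.text = repr(row.torsion)
        else:
            for atom in mol.atoms:
                a = etree.SubElement(array, f"{_CML}atom")
                a.set("id", atom.id)
                a.set("elementType", atom.element)
                a.set("x3", repr(atom.x))
                a.set("y3", repr(atom.y))
                a.set("z3", repr(atom.z))
        return el

    def _param_like(self, p, name: str) -> etree._Element:
        el = etree.Element(f"{_CML}{name}")
        el.set("dictRef", self.qname(p.dictRef))
        v = p.value
        if isinstance(v, ScalarValue):
            sub = etree.SubElement(el, f"{_CML}scalar")
            sub.set("dataType", v.dataType)
            if v.units is not None:
                sub.set("units", self.qname(v.units))
            if v.unitType is not None:
                sub.set("unitType", self.qname(v.unitType))
            sub.text = v.text
        elif isinstance(v, ArrayValue):
            sub = etree.SubElement(el, f"{_CML}array")
            sub.set("dataType", v.dataType)
            if v.size is not None:
                sub.set("size", str(v.size))
            if v.delimiter is not None:
                sub.set("delimiter", v.delimiter)
            if v.units is not None:
                sub.set("units", self.qname(v.units))
            sub.text = v.text
        elif isinstance(v, MatrixValue):
            sub = etree.SubElement(el, f"{_CML}matrix")
            sub.set("dataType", v.dataType)
            sub.set("rows", str(v.rows))
            sub.set("columns", str(v.columns))
            if v.delimiter is not None:
                sub.set("delimiter", v.delimiter)
            if v.units is not None:
                sub.set("units", self.qname(v.units))
            sub.text = v.text
        else:
            raise CMLWriteError(f"unsupported container type {type(v).__name__}")
        return el


def write_compchem(
    doc: CompChemDocument, profile: Optional[SerializationProfile] = None
) -> bytes:
    """Serialize the model to CompChem XML; deterministic for a fixed
    profile, and ``read(write(doc)) == doc`` on all semantic content."""
    profile = profile or SerializationProfile()
    writer = _Writer(doc, profile)
    root = writer.build()
    etree.indent(root, space=profile.indent)
    # indenting must not reformat inside opaque extras: restore the blobs
    for node, blob in writer.extra_nodes:
        pristine = etree.fromstring(blob)
        pristine.tail = node.tail
        node.getparent().replace(node, pristine)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# RDF export

_XSD_LITERAL = {
    "xsd:integer": XSD.integer,
    "xsd:double": XSD.double,
    "xsd:real": XSD.double,
    "xsd:float": XSD.double,
    "xsd:boolean": XSD.boolean,
    "xsd:string": XSD.string,
    "xsd:date": XSD.date,
}

_BLOCK_PREDICATE = {
    BlockKind.INITIALIZATION: "hasInitialization",
    BlockKind.CALCULATION: "hasCalculation",
    BlockKind.FINALIZATION: "hasFinalization",
    BlockKind.ENVIRONMENT: "hasEnvironment",
}


def _container_triples(g, voc, subject, predicate, container, res_uri):
    if isinstance(container, ScalarValue):
        g.add((subject, predicate, Literal(
            container.text, datatype=_XSD_LITERAL.get(container.dataType)
        )))
        return
    node = URIRef(res_uri)
    g.add((subject, predicate, node))
    if isinstance(container, (ArrayValue, MatrixValue)):
        dtype = _XSD_LITERAL.get(container.dataType)
        for i, v in enumerate(container.values, start=1):
            g.add((node, URIRef(str(RDF) + f"_{i}"), Literal(str(v), datatype=dtype)))
    if isinstance(container, MatrixValue):
        g.add((node, voc.rows, Literal(container.rows, datatype=XSD.integer)))
        g.add((node, voc.columns, Literal(container.columns, datatype=XSD.integer)))


def _expansion_count(container) -> int:
    """Closed-form triple count contributed by one parameter/property."""
    if isinstance(container, ScalarValue):
        return 1
    if isinstance(container, ArrayValue):
        return 1 + len(container.values)
    if isinstance(container, MatrixValue):
        return 1 + len(container.values) + 2
    return 0


def rdf_triple_count(doc: CompChemDocument) -> int:
    """Closed-form count of the triples :func:`export_rdf` will emit:
    hierarchy edges plus per-container expansions, by a model walk."""
    n = 0
    for jl in doc.jobLists:
        for job in jl.jobs:
            n += 1  # jobList -> job
            for block in job.blocks():
                n += 1  # job -> block
                for p in (block.parameters or []) + (block.properties or []):
                    n += _expansion_count(p.value)
    return n


def export_rdf(doc: CompChemDocument, base_url: str) -> str:
    """Export the document's implicit semantics as N-Triples text.

    Refuses documents that do not validate at ERROR level; resource URIs are
    minted from ``base_url`` by positional path (jobList id / job index /
    block kind), which is deterministic and collision-free.
    """
    from .validator import validate  # deferred: validator imports this module

    report = validate(doc)
    if not report.valid:
        raise SemanticError(
            "refusing RDF export of an invalid document:\n" + report.summary()
        )
    base = base_url.rstrip("/")
    voc = Namespace(base + "/vocab#")
    g = Graph()
    for jl in doc.jobLists:
        jl_res = URIRef(f"{base}/jobList/{jl.id}")
        for ji, job in enumerate(jl.jobs):
            job_res = URIRef(f"{jl_res}/job/{ji}")
            g.add((jl_res, voc.hasJob, job_res))
            counters = {BlockKind.CALCULATION: 0}
            for block in job.blocks():
                if block.kind == BlockKind.CALCULATION:
                    idx = counters[BlockKind.CALCULATION]
                    counters[BlockKind.CALCULATION] += 1
                    block_res = URIRef(f"{job_res}/calculation/{idx}")
                else:
                    block_res = URIRef(f"{job_res}/{block.kind.value}")
                g.add((job_res, voc[_BLOCK_PREDICATE[block.kind]], block_res))
                items = [("parameter", p) for p in (block.parameters or [])]
                items += [("property", p) for p in (block.properties or [])]
                for i, (tag, p) in enumerate(items):
                    _container_triples(
                        g,
                        voc,
                        block_res,
                        URIRef(p.dictRef.uri),
                        p.value,
                        f"{block_res}/{tag}/{i}",
                    )
    return g.serialize(format="nt")
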