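"""Dictionary loading, QName resolution and the document reference audit."""

import pytest

from compchem.dictionary import (
    DictionaryError,
    DictionaryRegistry,
    QNameResolutionError,
    audit_dictrefs,
    builtin_registry,
    load_dictionary,
    lookup,
    resolve_qname,
    serialize_dictionary,
)
from compchem.model import (
    COMPCHEM_DICT_NS,
    Parameter,
    QNameRef,
    ScalarValue,
)

CC_BINDING = {"cc": COMPCHEM_DICT_NS}

MINIMAL_DICT = f"""<?xml version="1.0"?>
<dictionary xmlns="http://www.xml-cml.org/schema"
            namespace="{COMPCHEM_DICT_NS}" title="mini">
  <entry id="job" term="job">
    <definition>A computational job.</definition>
  </entry>
</dictionary>"""


class TestResolveQName:
    def test_worked_reference(self):
        # the canonical construction: entry id "job" + prefix "cc" bound to
        # the CompChem dictionary namespace
        assert resolve_qname("cc:job", CC_BINDING) == (COMPCHEM_DICT_NS, "job")

    def test_basis_reference(self):
        assert resolve_qname("cc:basis", CC_BINDING) == (COMPCHEM_DICT_NS, "basis")

    def test_unbound_prefix_names_the_prefix(self):
        with pytest.raises(QNameResolutionError, match="zz"):
            resolve_qname("zz:job", CC_BINDING)

    def test_malformed_token(self):
        with pytest.raises(QNameResolutionError):
            resolve_qname("nocolon", CC_BINDING)

    def test_injective_per_binding(self):
        pairs = {
            resolve_qname(t, {"a": "http://x/", "b": "http://y/"})
            for t in ("a:p", "a:q", "b:p", "b:q")
        }
        assert len(pairs) == 4


class TestLoadDictionary:
    def test_minimal_dictionary(self):
        d = load_dictionary(MINIMAL_DICT)
        assert d.namespaceURI == COMPCHEM_DICT_NS
        assert list(d.entries) == ["job"]
        assert d.entries["job"].definition == "A computational job."

    def test_duplicate_id_conflict(self):
        xml = MINIMAL_DICT.replace(
            "</dictionary>",
            '<entry id="job" term="again"/></dictionary>',
        )
        with pytest.raises(DictionaryError, match="duplicate"):
            load_dictionary(xml)

    def test_missing_namespace_invalid(self):
        xml = MINIMAL_DICT.replace(f'namespace="{COMPCHEM_DICT_NS}"', "")
        with pytest.raises(DictionaryError, match="namespace"):
            load_dictionary(xml)

    def test_empty_dictionary_is_valid(self):
        xml = f'<dictionary xmlns="http://www.xml-cml.org/schema" namespace="{COMPCHEM_DICT_NS}"/>'
        assert load_dictionary(xml).entries == {}

    def test_load_serialize_load_identity(self):
        d = load_dictionary(MINIMAL_DICT)
        d2 = load_dictionary(serialize_dictionary(d))
        assert d2.namespaceURI == d.namespaceURI
        assert set(d2.entries) == set(d.entries)


class TestLookup:
    def test_known_entry(self, registry):
        entry = lookup((COMPCHEM_DICT_NS, "job"), registry)
        assert entry is not None and entry.id == "job"

    def test_unknown_entry_is_a_value(self, registry):
        assert lookup((COMPCHEM_DICT_NS, "nonexistent"), registry) is None

    def test_empty_registry(self):
        assert lookup((COMPCHEM_DICT_NS, "job"), DictionaryRegistry()) is None

    def test_unit_entries_resolvable(self, registry):
        assert registry.lookup("http://www.xml-cml.org/unit/si/", "none") is not None


class TestAudit:
    def test_conforming_document_audits_clean(self, reference_doc, registry):
        assert audit_dictrefs(reference_doc, registry) == []

    def test_planted_unknown_ref_reported_once(self, reference_doc, registry):
        bad = QNameRef("cc", "mystery", COMPCHEM_DICT_NS)
        block = reference_doc.jobLists[0].jobs[0].initialization
        block.parameters.append(Parameter(bad, ScalarValue("xsd:string", "?")))
        report = audit_dictrefs(reference_doc, registry)
        assert len(report) == 1
        assert report[0][1] == "cc:mystery"
        assert "parameter" in report[0][0]

    def test_same_unknown_ref_twice_in_document_order(self, reference_doc, registry):
        bad = QNameRef("cc", "mystery", COMPCHEM_DICT_NS)
        job = reference_doc.jobLists[0].jobs[0]
        job.initialization.parameters.insert(
            0, Parameter(bad, ScalarValue("xsd:string", "?"))
        )
        job.finalization.properties.append(
            __import__("compchem.model", fromlist=["Property"]).Property(
                bad, ScalarValue("xsd:string", "?")
            )
        )
        report = audit_dictrefs(reference_doc, registry)
        assert len(report) == 2
        assert "initialization" in report[0][0]
        assert "finalization" in report[1][0]

    def test_adding_a_dictionary_never_grows_the_report(self, reference_doc):
        empty = DictionaryRegistry()
        before = audit_dictrefs(reference_doc, empty)
        assert len(before) > 0
        assert len(audit_dictrefs(reference_doc, builtin_registry())) <= len(before)
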