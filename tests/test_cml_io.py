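"""XML round-trip fidelity, namespace discipline and RDF export."""

import numpy as np
import pytest
from lxml import etree
from rdflib import Graph

from compchem.cml_io import (
    CMLReadError,
    read_compchem,
    rdf_triple_count,
    export_rdf,
    write_compchem,
)
from compchem.fixtures import conforming_document, random_corpus
from compchem.model import CML_NS, ScalarValue, SI_UNIT_NS


@pytest.fixture(scope="module")
def corpus():
    return random_corpus(seed=20260928, size=50)


class TestReading:
    def test_minimal_document(self, reference_doc):
        doc = read_compchem(write_compchem(reference_doc))
        assert len(doc.jobLists) == 1
        assert len(doc.jobLists[0].jobs) == 1
        job = doc.jobLists[0].jobs[0]
        assert job.initialization is not None
        assert len(job.calculations) == 1
        assert job.finalization is not None

    def test_mismatched_tags_raise_parse_error(self):
        with pytest.raises(CMLReadError, match="well-formed"):
            read_compchem(b"<module><job></module>")

    def test_non_cml_root_rejected(self):
        with pytest.raises(CMLReadError, match="CML namespace"):
            read_compchem(b'<module xmlns="http://example.org/"/>')


class TestWriting:
    def test_writes_are_deterministic(self, reference_doc):
        assert write_compchem(reference_doc) == write_compchem(reference_doc)

    def test_dimensionless_scalar_carries_si_none(self, reference_doc):
        block = reference_doc.jobLists[0].jobs[0].finalization
        prop = block.properties[0]
        from compchem.model import Property, QNameRef

        block.properties.append(
            Property(
                prop.dictRef,
                ScalarValue("xsd:double", "1.5", units=QNameRef("si", "none", SI_UNIT_NS)),
            )
        )
        xml = write_compchem(reference_doc)
        assert b'units="si:none"' in xml

    def test_string_scalar_has_no_units_attribute(self, reference_doc):
        root = etree.fromstring(write_compchem(reference_doc))
        for scalar in root.iter(f"{{{CML_NS}}}scalar"):
            if scalar.get("dataType") == "xsd:string":
                assert scalar.get("units") is None

    def test_emitted_elements_stay_in_cml_namespace(self, reference_doc):
        root = etree.fromstring(write_compchem(reference_doc))
        for el in root.iter():
            if isinstance(el.tag, str) and "example.org" not in el.tag:
                assert etree.QName(el).namespace == CML_NS


class TestRoundTrip:
    def test_corpus_read_write_read_identity(self, corpus):
        for doc in corpus:
            xml = write_compchem(doc)
            assert read_compchem(xml) == doc

    def test_corpus_write_idempotence(self, corpus):
        for doc in corpus:
            xml = write_compchem(doc)
            assert write_compchem(read_compchem(xml)) == xml

    def test_foreign_extras_survive_in_order(self, corpus):
        seen = 0
        for doc in corpus:
            if doc.extras:
                seen += 1
                assert read_compchem(write_compchem(doc)).extras == doc.extras
        assert seen > 0


class TestRdfExport:
    def test_two_parameters_yield_two_hierarchy_plus_two_statements(self):
        doc = conforming_document()
        job = doc.jobLists[0].jobs[0]
        job.calculations.clear()
        job.finalization.properties = job.finalization.properties[:0]
        job.environment = None
        # jobList->job, job->initialization, job->finalization + 2 parameters
        nt = export_rdf(doc, "http://example.org/repo")
        triples = [line for line in nt.splitlines() if line.strip()]
        assert len(triples) == 3 + 2
        assert rdf_triple_count(doc) == 5

    def test_counts_match_model_walk_on_corpus(self, corpus):
        for doc in corpus[:25]:
            nt = export_rdf(doc, "http://example.org/repo")
            assert len(Graph().parse(data=nt, format="nt")) == rdf_triple_count(doc)

    def test_two_jobs_share_joblist_resource(self, corpus):
        doc = next(d for d in corpus if len(d.jobLists[0].jobs) > 1)
        g = Graph().parse(
            data=export_rdf(doc, "http://example.org/repo"), format="nt"
        )
        subjects = {s for s, p, o in g if p.endswith("hasJob")}
        assert len(subjects) == 1

    def test_invalid_document_refused(self, reference_doc):
        reference_doc.jobLists[0].jobs[0].initialization.molecule.conventionRef = None
        from compchem.model import SemanticError

        with pytest.raises(SemanticError, match="I1b"):
            export_rdf(reference_doc, "http://example.org/repo")
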