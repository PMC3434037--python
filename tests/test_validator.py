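"""Convention-rule validation: staging, soundness/completeness of the rule
registry against generated violations, and monotonicity under optional
content."""

import pytest
from lxml import etree

from compchem.cml_io import write_compchem
from compchem.fixtures import conforming_document
from compchem.model import CML_NS
from compchem.validator import (
    MUTABLE_RULES,
    RULES,
    Severity,
    UnsupportedMutationError,
    mutate_fixture,
    validate,
)


@pytest.fixture(scope="module")
def base_xml():
    return write_compchem(conforming_document())


class TestStaging:
    def test_not_wellformed_halts_at_first_stage(self):
        report = validate(b"<module><oops></module>")
        assert report.stageReached.value == "wellformed"
        assert report.rule_ids() == {"W1"}
        assert not report.valid

    def test_wrong_root_namespace_halts_structural(self):
        report = validate(b'<module xmlns="http://example.org/x"/>')
        assert report.stageReached.value == "structural"
        assert "S1" in report.rule_ids()

    def test_convention_stage_errors_suppress_dictionary_stage(self, base_xml):
        mutated = mutate_fixture(base_xml, "J1")
        report = validate(mutated)
        assert report.stageReached.value == "convention"
        assert not any(f.ruleId == "DICT1" for f in report.findings)

    def test_clean_document_reaches_dictionary_stage(self, base_xml):
        report = validate(base_xml)
        assert report.stageReached.value == "dictionary"
        assert report.valid and report.clean

    def test_unknown_refs_are_dictionary_warnings(self, base_xml):
        root = etree.fromstring(base_xml)
        scalar = next(root.iter(f"{{{CML_NS}}}scalar"))
        scalar.getparent().set("dictRef", "cc:notInAnyDictionary")
        report = validate(etree.tostring(root))
        assert report.valid  # warnings only
        dict_findings = [f for f in report.findings if f.ruleId == "DICT1"]
        assert len(dict_findings) == 1
        assert dict_findings[0].severity is Severity.WARNING


class TestExamples:
    def test_job_without_initialization(self, base_xml):
        assert validate(mutate_fixture(base_xml, "J1")).rule_ids() == {"J1"}

    def test_calculation_without_finalization(self, base_xml):
        assert validate(mutate_fixture(base_xml, "J6")).rule_ids() == {"J6"}

    def test_property_list_in_initialization(self, base_xml):
        assert validate(mutate_fixture(base_xml, "I5")).rule_ids() == {"I5"}

    def test_array_size_mismatch(self, base_xml):
        report = validate(mutate_fixture(base_xml, "D7"))
        assert report.rule_ids() == {"D7"}

    def test_findings_carry_real_locations(self, base_xml):
        mutated = mutate_fixture(base_xml, "I5")
        report = validate(mutated)
        root = etree.fromstring(mutated)
        tree = root.getroottree()
        for f in report.findings:
            assert tree.xpath(f.location), f.location


class TestRuleCoverage:
    def test_registry_severities(self):
        assert RULES["J1"].severity is Severity.ERROR
        assert RULES["JL3"].severity is Severity.WARNING
        assert RULES["J2"].severity is Severity.INFO
        assert RULES["D13"].severity is Severity.WARNING

    @pytest.mark.parametrize("rule_id", MUTABLE_RULES)
    def test_each_rule_fires_exactly_once_on_its_violation(self, base_xml, rule_id):
        mutated = mutate_fixture(base_xml, rule_id)
        assert validate(mutated).rule_ids() == {rule_id}
        # and the unmutated base stays clean
        assert rule_id not in validate(base_xml).rule_ids()

    def test_unsupported_mutation_reported(self, base_xml):
        with pytest.raises(UnsupportedMutationError):
            mutate_fixture(base_xml, "W1")
        with pytest.raises(UnsupportedMutationError):
            mutate_fixture(base_xml, "NOPE")


class TestMonotonicity:
    def test_conforming_optional_content_adds_no_errors(self, base_xml):
        root = etree.fromstring(base_xml)
        # foreign-namespace child anywhere is always allowed
        for el in list(root.iter(f"{{{CML_NS}}}module"))[:4]:
            extra = etree.SubElement(el, "{http://example.org/x}annotation")
            extra.text = "free-form"
        report = validate(etree.tostring(root))
        assert report.valid

    def test_identical_input_identical_report(self, base_xml):
        mutated = mutate_fixture(base_xml, "I5")
        assert validate(mutated).to_dict() == validate(mutated).to_dict()
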