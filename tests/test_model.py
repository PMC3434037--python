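"""Document-model semantics: container text parsing, molecule placement
roles and structural invariants."""

import pytest
from hypothesis import given, settings, strategies as st

from compchem.fixtures import conforming_document
from compchem.model import (
    ArrayValue,
    BlockKind,
    ContainerParseError,
    MatrixValue,
    MoleculeRole,
    SemanticError,
    ZMatrix,
    ZMatrixRow,
    molecule_role,
    parse_container_text,
    serialize_container_values,
)


class TestParseContainerText:
    @pytest.mark.parametrize(
        "text,dtype,delim,expected",
        [
            ("1 2 3", "xsd:integer", None, [1, 2, 3]),
            ("1.0|2.5", "xsd:double", "|", [1.0, 2.5]),
            ("true false 1 0", "xsd:boolean", None, [True, False, True, False]),
            ("", "xsd:double", None, []),
            ("  7  ", "xsd:integer", None, [7]),
            ("a,b c,d", "xsd:string", ",", ["a", "b c", "d"]),
        ],
    )
    def test_typed_splitting(self, text, dtype, delim, expected):
        assert parse_container_text(text, dtype, delim) == expected

    def test_bad_token_reports_index(self):
        with pytest.raises(ContainerParseError) as err:
            parse_container_text("1 x 3", "xsd:integer", None)
        assert err.value.index == 1

    def test_empty_token_under_declared_delimiter(self):
        with pytest.raises(ContainerParseError):
            parse_container_text("1.0||2.0", "xsd:double", "|")

    def test_non_primitive_datatype_rejected(self):
        with pytest.raises(ContainerParseError):
            parse_container_text("x", "xsd:anyURI", None)

    @settings(deadline=None, max_examples=60)
    @given(
        values=st.lists(
            st.floats(allow_nan=False, allow_infinity=False, width=64),
            max_size=12,
        )
    )
    def test_roundtrip_is_identity_for_doubles(self, values):
        text = serialize_container_values(values, "xsd:double")
        assert parse_container_text(text, "xsd:double") == values

    @settings(deadline=None, max_examples=60)
    @given(values=st.lists(st.integers(-10**12, 10**12), max_size=12))
    def test_roundtrip_is_identity_for_integers(self, values):
        text = serialize_container_values(values, "xsd:integer")
        assert parse_container_text(text, "xsd:integer") == values


class TestContainers:
    def test_array_size_must_match_count(self):
        with pytest.raises(ContainerParseError):
            ArrayValue("xsd:double", None, [1.0, 2.0, 3.0], size=4)

    def test_matrix_count_must_match_dimensions(self):
        with pytest.raises(ContainerParseError):
            MatrixValue("xsd:double", None, rows=2, columns=2, values=[1.0])

    def test_zmatrix_row_coordinate_arity(self):
        z = ZMatrix(rows=[ZMatrixRow("O"), ZMatrixRow("H", (1,), 0.96, angle=90.0)])
        with pytest.raises(SemanticError):
            z.validate()

    def test_zmatrix_forward_reference_rejected(self):
        z = ZMatrix(rows=[ZMatrixRow("O"), ZMatrixRow("H", (2,), 0.96)])
        with pytest.raises(SemanticError):
            z.validate()

    def test_zmatrix_angle_domain(self):
        z = ZMatrix(
            rows=[
                ZMatrixRow("O"),
                ZMatrixRow("H", (1,), 0.96),
                ZMatrixRow("H", (1, 2), 0.96, angle=180.0),
            ]
        )
        with pytest.raises(SemanticError):
            z.validate()


class TestMoleculeRole:
    def test_initialization_molecule_is_input(self, reference_doc):
        assert molecule_role(reference_doc, 0, "initialization") is MoleculeRole.INPUT

    def test_calculation_molecule_is_input(self, reference_doc):
        assert molecule_role(reference_doc, 0, "calculation") is MoleculeRole.INPUT

    def test_finalization_molecule_is_output(self, reference_doc):
        assert molecule_role(reference_doc, 0, "finalization") is MoleculeRole.OUTPUT

    def test_environment_has_no_molecule_semantics(self, reference_doc):
        with pytest.raises(SemanticError):
            molecule_role(reference_doc, 0, BlockKind.ENVIRONMENT)

    def test_missing_job_is_a_semantic_error(self, reference_doc):
        with pytest.raises(SemanticError):
            molecule_role(reference_doc, 5, "initialization")


def test_document_requires_a_joblist():
    doc = conforming_document()
    doc.jobLists.clear()
    with pytest.raises(SemanticError):
        doc.validate()


def test_joblist_ids_unique():
    doc = conforming_document()
    doc.jobLists.append(doc.jobLists[0])
    with pytest.raises(SemanticError):
        doc.validate()
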