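"""Classification, UI-to-semantic remodeling, and its exact reversibility."""

import pytest
from hypothesis import given, strategies as st

from dak2fhir.dictionary import DictionaryEntry
from dak2fhir.errors import RemodelError
from dak2fhir.remodel import (RemodelConfig, UIElement, classify_entry,
                              remodel, revert)
from dak2fhir.terminology import SNOMED_URI, parse_code_text


def _entry(answer_type="boolean", path="Condition.code", label="Hypertension",
           codes="SNOMED: 38341003 (maps to Hypertension)", **kw):
    kw.setdefault("element_id", "e1")
    kw.setdefault("target_profile_id", "P")
    return DictionaryEntry(label=label, answer_type=answer_type,
                           fhir_resource_path=path, semantic_code_text=codes, **kw)


class TestClassify:
    @pytest.mark.parametrize("path,answer_type,expected", [
        ("Condition.code", "boolean", "condition_presence"),
        ("Observation.value", "quantity", "quantity_observation"),
        ("Observation.value", "boolean", "coded_observation"),
        ("Observation.value", "choice", "coded_observation"),
        ("Observation.value", "date", "date_observation"),
        ("MedicationStatement.medication", "boolean", "medication_statement"),
        ("Procedure.code", "text", "procedure"),
        ("Patient.gender", "choice", "passthrough"),
        ("", "boolean", "passthrough"),
    ])
    def test_rule_table(self, path, answer_type, expected):
        e = _entry(answer_type=answer_type, path=path,
                   value_set_binding="vs" if answer_type in ("choice", "multi-choice") else "")
        assert classify_entry(e).pattern == expected

    def test_override_wins(self):
        cfg = RemodelConfig(overrides={"e1": "passthrough"})
        assert classify_entry(_entry(), cfg).pattern == "passthrough"

    def test_deterministic(self):
        e = _entry()
        assert classify_entry(e) == classify_entry(e)


class TestRemodel:
    def test_condition_presence_binds_concept_codes(self):
        e = _entry()
        out = remodel(e)
        assert out.fhir_resource_path == "Condition.code"
        assert out.value_set_binding  # presence semantics replace the boolean
        assert out.ui_metadata["answer_type"] == "boolean"

    def test_condition_without_codes_rejected(self):
        e = _entry(codes="")
        with pytest.raises(RemodelError):
            remodel(e)

    def test_passthrough_is_identity(self):
        e = _entry(path="Patient.gender", answer_type="text", codes="")
        assert remodel(e) is e

    def test_boolean_observation_gets_standard_yes_no_codes(self):
        e = _entry(path="Observation.value", label="Smoker",
                   codes="SNOMED: 77176002 (maps to Smoker)")
        out = remodel(e)
        codings, _ = parse_code_text(out.semantic_code_text)
        codes = {c.code for c in codings if c.system == SNOMED_URI}
        assert {"373066001", "373067005"} <= codes
        # the question concept is fixed on the code element, not dropped
        assert any("77176002" in a for a in out.additional_fhir_attributes)

    def test_codes_never_dropped(self):
        e = _entry()
        out = remodel(e)
        before, _ = parse_code_text(e.semantic_code_text)
        after, _ = parse_code_text(out.semantic_code_text)
        assert set(c.key() for c in before) <= set(c.key() for c in after)


@st.composite
def entries(draw):
    answer_type = draw(st.sampled_from(
        ["boolean", "choice", "quantity", "date", "text"]))
    rtype = draw(st.sampled_from(
        ["Condition", "Observation", "MedicationStatement", "Procedure",
         "Patient", "Encounter"]))
    label = draw(st.text(alphabet="abcdefgh ", min_size=1, max_size=12).filter(str.strip))
    n_opts = draw(st.integers(1, 3)) if answer_type == "choice" else 0
    options = [f"{label} opt {i}" for i in range(n_opts)]
    path = {"Condition": "Condition.code", "Observation": "Observation.value",
            "MedicationStatement": "MedicationStatement.medication",
            "Procedure": "Procedure.code", "Patient": "Patient.gender",
            "Encounter": "Encounter.type"}[rtype]
    return DictionaryEntry(
        element_id="h1", label=label, answer_type=answer_type,
        answer_options=options, fhir_resource_path=path,
        target_profile_id="P",
        semantic_code_text="SNOMED: 38341003 (maps to X)")


class TestRevert:
    @given(entries())
    def test_revert_after_remodel_is_identity_on_ui_projection(self, entry):
        out = remodel(entry)
        assert revert(out) == UIElement(question_label=entry.label,
                                        answer_type=entry.answer_type,
                                        answer_options=tuple(entry.answer_options))

    def test_passthrough_projects_stored_fields(self):
        e = _entry(path="Patient.gender", answer_type="text", codes="")
        assert revert(e) == UIElement("Hypertension", "text", ())

    def test_every_fixture_entry_round_trips(self, fixture_dictionary, compiled):
        by_id = {e.element_id: e for e in fixture_dictionary.entries}
        for out in compiled.remodeled.entries:
            src = by_id[out.element_id]
            assert revert(out) == UIElement(
                question_label=src.label,
                answer_type=src.answer_type,
                answer_options=tuple(src.answer_options)), out.element_id
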