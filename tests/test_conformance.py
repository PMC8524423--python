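"""Path/attribute parsing, value-set reuse, profile building and emission."""

import pytest

from dak2fhir.conformance import (EmitConfig, ValueSetRegistry, build_profile,
                                  build_value_set, content_hash,
                                  emit_structure_definition, emit_value_set,
                                  parse_fhir_path, parse_fixed_attribute,
                                  to_json_bytes)
from dak2fhir.dictionary import DictionaryEntry
from dak2fhir.errors import (AttributeParseError, EmptyValueSetError,
                             GroupingError, PathError)
from dak2fhir.terminology import SNOMED_URI, Coding


class TestParseFhirPath:
    def test_simple_path(self):
        assert parse_fhir_path("AllergyIntolerance.code") == \
            [("AllergyIntolerance", "code")]

    def test_bare_resource_is_profile_level(self):
        assert parse_fhir_path("Observation") == [("Observation", "")]

    def test_unsupported_type(self):
        with pytest.raises(PathError) as exc:
            parse_fhir_path("Foo.bar")
        assert exc.value.resource_type == "Foo"

    def test_multiple_paths(self):
        assert parse_fhir_path("Observation.value, Observation.code") == \
            [("Observation", "value"), ("Observation", "code")]


class TestParseFixedAttribute:
    def test_worked_example(self):
        c = parse_fixed_attribute("AllergyIntolerance.category = medication")
        assert (c.path, c.fixed_value) == ("category", "medication")

    def test_status_fixation(self):
        c = parse_fixed_attribute("Observation.status = final")
        assert (c.path, c.fixed_value) == ("status", "final")

    def test_system_qualified_value(self):
        c = parse_fixed_attribute(f"Observation.code = {SNOMED_URI}|12345678")
        assert (c.fixed_system, c.fixed_value) == (SNOMED_URI, "12345678")

    @pytest.mark.parametrize("text", ["Observation.status", "a = b = c", " = x"])
    def test_malformed_rejected(self, text):
        with pytest.raises(AttributeParseError):
            parse_fixed_attribute(text)


def _choice_entry(eid, label, options_with_codes, **kw):
    segments = [f"SNOMED: {code} (maps to {opt})" for opt, code in options_with_codes]
    kw.setdefault("target_profile_id", "P")
    return DictionaryEntry(element_id=eid, label=label, answer_type="choice",
                           answer_options=[o for o, _ in options_with_codes],
                           fhir_resource_path="Observation.value",
                           semantic_code_text="\n".join(segments), **kw)


class TestBuildValueSet:
    def test_fhir_coded_options_use_declared_system_no_local_cs(self):
        reg = ValueSetRegistry("http://example.org/fhir")
        e = DictionaryEntry(
            element_id="g", label="Gender", answer_type="choice",
            answer_options=["Female", "Male"], target_profile_id="P",
            fhir_resource_path="Patient.gender",
            fhir_code_system="http://hl7.org/fhir/administrative-gender",
            fhir_code="female")
        vs = build_value_set([e], reg)
        assert {c.code for c in vs.codings} == {"female", "male"}
        assert all(c.system == "http://hl7.org/fhir/administrative-gender"
                   for c in vs.codings)
        assert vs.local_code_system is None

    def test_identical_content_registered_once(self):
        reg = ValueSetRegistry("http://example.org/fhir")
        e1 = _choice_entry("a", "Q1", [("Yes", "37306600"), ("No", "37306700")])
        e2 = _choice_entry("b", "Q2", [("Yes", "37306600"), ("No", "37306700")])
        vs1 = build_value_set([e1], reg)
        vs2 = build_value_set([e2], reg)
        assert vs1 is vs2
        assert len(reg) == 1
        assert reg.reference_count(vs1.id) == 2

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_k_coded_options_yield_k_codings(self, k):
        reg = ValueSetRegistry("http://example.org/fhir")
        pairs = [(f"opt{i}", str(10000000 + i)) for i in range(k)]
        vs = build_value_set([_choice_entry("e", f"Q{k}", pairs)], reg)
        # brute-force dedup oracle over the option -> coding map
        oracle = {(SNOMED_URI, code) for _, code in pairs}
        assert {c.key() for c in vs.codings} == oracle

    def test_uncoded_options_get_local_code_system(self):
        reg = ValueSetRegistry("http://example.org/fhir")
        e = DictionaryEntry(element_id="x", label="Mood", answer_type="choice",
                            answer_options=["Happy", "Sad"],
                            fhir_resource_path="Observation.value",
                            target_profile_id="P")
        vs = build_value_set([e], reg)
        assert vs.local_code_system is not None
        assert {lc.code for lc in vs.local_code_system.codes} == {"happy", "sad"}

    def test_zero_resolvable_options_rejected(self):
        reg = ValueSetRegistry("http://example.org/fhir")
        e = DictionaryEntry(element_id="x", label="Empty",
                            fhir_resource_path="Condition.code",
                            target_profile_id="P")
        with pytest.raises(EmptyValueSetError):
            build_value_set([e], reg)

    def test_content_hash_is_order_insensitive(self):
        a = [Coding(SNOMED_URI, "1111111"), Coding(SNOMED_URI, "2222222")]
        assert content_hash(a) == content_hash(list(reversed(a)))


class TestBuildProfile:
    def test_drug_allergy_profile_has_two_constraints(self):
        e = DictionaryEntry(
            element_id="da", label="Drug Allergies",
            fhir_resource_path="AllergyIntolerance.code",
            additional_fhir_attributes=["AllergyIntolerance.category = medication"],
            target_profile_id="WHO-Core AllergyIntolerance (Drug Allergies)")
        p = build_profile([e])
        assert p.name == "WHO-Core AllergyIntolerance (Drug Allergies)"
        assert p.id == "who-core-allergyintolerance-drug-allergies"
        assert len(p.constraints) == 2
        fixed = next(c for c in p.constraints if c.fixed_value)
        assert (fixed.path, fixed.fixed_value) == ("category", "medication")

    def test_single_entry_single_constraint(self):
        e = DictionaryEntry(element_id="x", label="X",
                            fhir_resource_path="Observation.value",
                            target_profile_id="P")
        assert len(build_profile([e]).constraints) == 1

    def test_existing_canonical_binding_kept_verbatim(self):
        url = "http://hl7.org/fhir/ValueSet/communication-not-done-reason"
        e = DictionaryEntry(element_id="x", label="X", answer_type="choice",
                            fhir_resource_path="Communication.statusReason",
                            value_set_binding=url, target_profile_id="P")
        p = build_profile([e])
        (c,) = p.constraints
        assert c.binding_url == url and c.binding_strength == "required"

    def test_mixed_resource_types_rejected(self):
        e1 = DictionaryEntry(element_id="a", label="A",
                             fhir_resource_path="Observation.value",
                             target_profile_id="P")
        e2 = DictionaryEntry(element_id="b", label="B",
                             fhir_resource_path="Condition.code",
                             target_profile_id="P")
        with pytest.raises(GroupingError) as exc:
            build_profile([e1, e2])
        assert {"a", "b"} <= set(exc.value.element_ids)

    def test_unknown_path_becomes_generated_extension(self):
        e = DictionaryEntry(element_id="x", label="Tribal Affiliation",
                            fhir_resource_path="Patient.tribalAffiliation",
                            target_profile_id="P")
        p = build_profile([e])
        (c,) = p.constraints
        assert c.is_extension and c.type == "Extension"


class TestEmission:
    def test_version_and_derivation_pins(self, compiled):
        doc = emit_structure_definition(compiled.packages[0].profiles[0])
        assert doc["fhirVersion"] == "4.0.1"
        assert doc["derivation"] == "constraint"
        assert doc["kind"] == "resource"

    def test_profile_level_mapping_emits_root_only(self):
        e = DictionaryEntry(element_id="x", label="Patient profile",
                            fhir_resource_path="Patient",
                            target_profile_id="WHO-STI Patient")
        doc = emit_structure_definition(build_profile([e]))
        assert [el["path"] for el in doc["differential"]["element"]] == ["Patient"]

    def test_byte_identical_across_runs(self):
        e = DictionaryEntry(element_id="x", label="X",
                            fhir_resource_path="Observation.value",
                            target_profile_id="P")
        a = to_json_bytes(emit_structure_definition(build_profile([e])))
        b = to_json_bytes(emit_structure_definition(build_profile([e.model_copy()])))
        assert a == b

    def test_pattern_style_fixation_on_coded_element(self):
        c = parse_fixed_attribute("AllergyIntolerance.category = medication")
        e = DictionaryEntry(element_id="x", label="X",
                            fhir_resource_path="AllergyIntolerance.code",
                            additional_fhir_attributes=[
                                "AllergyIntolerance.category = medication"],
                            target_profile_id="P")
        doc = emit_structure_definition(build_profile([e]))
        el = next(el for el in doc["differential"]["element"]
                  if el["path"] == "AllergyIntolerance.category")
        assert el["patternCode"] == "medication"
        exact = emit_structure_definition(build_profile([e]),
                                          EmitConfig(use_pattern=False))
        el2 = next(el for el in exact["differential"]["element"]
                   if el["path"] == "AllergyIntolerance.category")
        assert el2["fixedCode"] == "medication"

    def test_value_set_groups_codings_by_system(self, compiled):
        vs = next(v for pkg in compiled.packages for v in pkg.value_sets
                  if v.id == "amenorrhea-codes")
        doc = emit_value_set(vs)
        systems = [inc["system"] for inc in doc["compose"]["include"]]
        assert systems == sorted(systems) and len(systems) == 2
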