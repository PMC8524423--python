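"""Built-in fixture dictionaries: the published worked examples plus
seed-controlled synthetic dictionaries for property-based testing.

:func:`published_fixture` reconstructs the published FP/STI mapping exercise at
desk scale: it contains one row for each of the worked mapping examples
(amenorrhea with its ICD-10 and SNOMED codes, number-of-pregnancies with its
LOINC code, azithromycin with its RxNorm code, drug allergies with a fixed
category, the administrative-gender FHIR coding, and the
communication-not-done-reason binding) and one row per profile of the
published Core/FP/STI inventory.  The inventory gives profile *names* only,
so rows behind the non-worked profiles are synthetic: one plausible element
path per profile's resource type, with clearly-marked synthetic codes where
a pattern requires them.

:func:`random_dictionary` generates reproducible random dictionaries whose
codes all satisfy the per-system format rules, for fuzz and oracle tests.
"""

from __future__ import annotations

import random
import zlib

from pydantic import BaseModel, Field, model_validator

from .dictionary import DataDictionary, DictionaryEntry
from .errors import FixtureSpecError
from .naming import slugify

# ---------------------------------------------------------------------------
# the published profile inventory (Core / FP / STI)

CORE_PROFILES = [
    "WHO-Core AllergyIntolerance",
    "WHO-Core AllergyIntolerance (Drug Allergies)",
    "WHO-Core Appointment (Return Visit)",
    "WHO-Core Appointment (Visit)",
    "WHO-Core CarePlan (Follow-up)",
    "WHO-Core CarePlan (Intake Contraceptive Method)",
    "WHO-Core CarePlan (Prior Contraceptive Methods)",
    "WHO-Core Coverage (Insurance)",
    "WHO-Core DeviceUseStatement (Intake Contraceptive Method)",
    "WHO-Core DeviceUseStatement (Prior Contraceptive Methods)",
    "WHO-Core MedicationStatement (Current Contraceptive Methods)",
    "WHO-Core MedicationStatement (Current Medication)",
    "WHO-Core MedicationStatement (Prior Contraceptive Methods)",
    "WHO-Core Observation (BMI)",
    "WHO-Core Observation (Body Height)",
    "WHO-Core Observation (Body Weight)",
    "WHO-Core Observation (Breastfeeding)",
    "WHO-Core Observation (Clinical Observations)",
    "WHO-Core Observation (Date of Delivery)",
    "WHO-Core Observation (Days since Unprotected Sex)",
    "WHO-Core Observation (Gender-based Violence Risk Factors)",
    "WHO-Core Observation (Gender-based Violence Victim)",
    "WHO-Core Observation (HIV Care Enrollment)",
    "WHO-Core Observation (HIV Stage)",
    "WHO-Core Observation (HIV Status)",
    "WHO-Core Observation (HIV Test)",
    "WHO-Core Observation (Last Normal Menses)",
    "WHO-Core Observation (Miscarriage or Abortion)",
    "WHO-Core Observation (Never used contraception)",
    "WHO-Core Observation (Number of births)",
    "WHO-Core Observation (Number of Pregnancies)",
    "WHO-Core Observation (Postpartum)",
    "WHO-Core Observation (Pregnancy Status)",
    "WHO-Core Observation (PrEP Status)",
    "WHO-Core Observation (Reason for no contraceptive method at intake)",
    "WHO-Core Observation (Recent Sexual History)",
    "WHO-Core Observation (Sexual History)",
    "WHO-Core Observation (Sexually Active)",
    "WHO-Core Observation (STI Risk Factors)",
    "WHO-Core Observation (Temperature)",
    "WHO-Core Observation (Time Postpartum)",
    "WHO-Core Patient",
    "WHO-Core Practitioner",
    "WHO-Core Procedure (Intake Contraceptive Method)",
    "WHO-Core Procedure (Prior Contraceptive Methods)",
    "WHO-Core ServiceRequest (Referral)",
]

FP_PROFILES = [
    "WHO-FP CarePlan (Backup Contraceptive Method)",
    "WHO-FP CarePlan (Exit Contraceptive Method)",
    "WHO-FP CarePlan (Recommendation)",
    "WHO-FP CarePlan (Requested Contraceptive Method)",
    "WHO-FP Condition (Medical Eligibility)",
    "WHO-FP Consent",
    "WHO-FP DeviceUseStatement (Exit Contraceptive Method)",
    "WHO-FP DeviceUseStatement (Requested Contraceptive Method)",
    "WHO-FP Encounter",
    "WHO-FP Encounter (Contraception Issues and Concerns)",
    "WHO-FP HealthcareService",
    "WHO-FP MedicationStatement (Current Medication)",
    "WHO-FP MedicationStatement (Exit Contraceptive Method)",
    "WHO-FP MedicationStatement (Requested Contraceptive Method)",
    "WHO-FP Observation (Breastfeeding Status)",
    "WHO-FP Observation (Days since Last Normal Menses)",
    "WHO-FP Observation (Intercourse since Last Normal Menses)",
    "WHO-FP Observation (Medical eligibility number)",
    "WHO-FP Observation (Medical eligibility text)",
    "WHO-FP Observation (Medical Eligibility)",
    "WHO-FP Observation (Missed or Late Menses)",
    "WHO-FP Observation (Pregnancy Intention)",
    "WHO-FP Observation (Reason for no contraceptive method at exit)",
    "WHO-FP Observation (Reason for Stopping Contraception)",
    "WHO-FP Observation (Smoking Status)",
    "WHO-FP Observation (Test Results)",
    "WHO-FP Procedure (Exit Contraceptive Method)",
    "WHO-FP Procedure (Requested Contraceptive Method)",
    "WHO-FP Procedure (Service Provided)",
]

STI_PROFILES = [
    "WHO-STI CarePlan (Recommendation)",
    "WHO-STI Communication (Partner)",
    "WHO-STI Condition (Diagnosis)",
    "WHO-STI Condition (HIV)",
    "WHO-STI Condition (STI History)",
    "WHO-STI Medication",
    "WHO-STI MedicationAdministration",
    "WHO-STI MedicationStatement (Current Medication)",
    "WHO-STI MedicationStatement (Medication History)",
    "WHO-STI Observation (Current STI Treatment)",
    "WHO-STI Observation (Disease Exposure)",
    "WHO-STI Observation (External Genital Examination)",
    "WHO-STI Observation (Increased STI Risk)",
    "WHO-STI Observation (LGV Follow-up)",
    "WHO-STI Observation (Partner HIV Status)",
    "WHO-STI Observation (Partner Symptoms)",
    "WHO-STI Observation (Past STI Treatment)",
    "WHO-STI Observation (Recent Abortion or Miscarriage)",
    "WHO-STI Observation (Recent Syphilis Treatment)",
    "WHO-STI Observation (Reported Symptoms)",
    "WHO-STI Observation (Risk Assessment)",
    "WHO-STI Observation (Signs of Fever)",
    "WHO-STI Observation (Signs of Shock)",
    "WHO-STI Observation (Speculum Examination)",
    "WHO-STI Observation (STI Screening)",
    "WHO-STI Observation (Syphilis Stage)",
    "WHO-STI Observation (Trauma History)",
    "WHO-STI Patient",
    "WHO-STI Procedure (Service Provided)",
    "WHO-STI Specimen",
]

INVENTORY = {"core": CORE_PROFILES, "fp": FP_PROFILES, "sti": STI_PROFILES}

#: profiles realized by a worked-example row rather than a synthetic one
_EXEMPLAR_PROFILES = {
    "WHO-FP Condition (Medical Eligibility)",
    "WHO-Core Observation (Number of Pregnancies)",
    "WHO-STI MedicationStatement (Current Medication)",
    "WHO-Core AllergyIntolerance (Drug Allergies)",
    "WHO-Core Patient",
    "WHO-STI Communication (Partner)",
}

_DEFAULT_PATH = {
    "AllergyIntolerance": "AllergyIntolerance.code",
    "Appointment": "Appointment.start",
    "CarePlan": "CarePlan.category",
    "Communication": "Communication.topic",
    "Condition": "Condition.code",
    "Consent": "Consent.category",
    "Coverage": "Coverage.type",
    "DeviceUseStatement": "DeviceUseStatement.reasonCode",
    "Encounter": "Encounter.type",
    "HealthcareService": "HealthcareService.type",
    "Medication": "Medication.code",
    "MedicationAdministration": "MedicationAdministration.medication",
    "MedicationStatement": "MedicationStatement.medication",
    "Observation": "Observation.value",
    "Patient": "Patient",
    "Practitioner": "Practitioner.name",
    "Procedure": "Procedure.code",
    "ServiceRequest": "ServiceRequest.code",
    "Specimen": "Specimen.type",
}

_QUANTITY_LABELS = {"BMI", "Body Height", "Body Weight", "Temperature",
                    "Number of births", "Days since Unprotected Sex",
                    "Time Postpartum", "Medical eligibility number",
                    "Days since Last Normal Menses"}
_DATE_LABELS = {"Date of Delivery", "Last Normal Menses"}
_TEXT_LABELS = {"Clinical Observations", "Medical eligibility text",
                "Test Results", "Reported Symptoms"}


def _profile_parts(profile_name: str) -> tuple[str, str, str]:
    """Split an inventory name into (program, resource_type, concept label)."""
    prefix, _, rest = profile_name.partition(" ")
    program = prefix.split("-")[1].lower()
    if "(" in rest:
        rtype, _, label = rest.partition(" (")
        return program, rtype.strip(), label.rstrip(")")
    return program, rest.strip(), rest.strip()


def _synthetic_snomed(label: str) -> str:
    """Deterministic, clearly-synthetic SNOMED-format code for a label."""
    return str(10000000 + zlib.crc32(slugify(label).encode()) % 80000000)


def _exemplar_entries() -> list[DictionaryEntry]:
    """The six worked mapping examples, verbatim where the source prints them."""
    return [
        DictionaryEntry(
            element_id="fp-amenorrhea",
            label="Amenorrhea",
            description="Client currently has amenorrhea (no menstrual bleeding)",
            answer_type="boolean",
            fhir_resource_path="Condition.code",
            target_profile_id="WHO-FP Condition (Medical Eligibility)",
            semantic_code_text=("ICD-10: N91.2 (maps to Amenorrhea)\n"
                                "SNOMED: 14,302,001 (maps to Amenorrhea)"),
            program="fp",
            validation_status="validated"),
        DictionaryEntry(
            element_id="core-number-of-pregnancies",
            label="Number of Pregnancies",
            description="Total number of pregnancies, including the current one",
            answer_type="quantity",
            fhir_resource_path="Observation.value",
            target_profile_id="WHO-Core Observation (Number of Pregnancies)",
            semantic_code_text="LOINC: 11996–6 (maps to Number of Pregnancies)",
            program="core",
            validation_status="validated"),
        DictionaryEntry(
            element_id="sti-azithromycin",
            label="Azithromycin",
            description="Client is currently taking azithromycin",
            answer_type="boolean",
            fhir_resource_path="MedicationStatement.medication",
            target_profile_id="WHO-STI MedicationStatement (Current Medication)",
            semantic_code_text="RxNorm: 18,631 (maps to azithromycin)",
            program="sti",
            validation_status="validated"),
        DictionaryEntry(
            element_id="core-drug-allergies",
            label="Drug Allergies",
            description="Known drug allergies of the client",
            answer_type="text",
            fhir_resource_path="AllergyIntolerance.code",
            additional_fhir_attributes=["AllergyIntolerance.category = medication"],
            target_profile_id="WHO-Core AllergyIntolerance (Drug Allergies)",
            program="core",
            validation_status="validated"),
        DictionaryEntry(
            element_id="core-gender",
            label="Gender",
            description="Administrative gender of the client",
            answer_type="choice",
            answer_options=["Female", "Male"],
            fhir_resource_path="Patient.gender",
            target_profile_id="WHO-Core Patient",
            fhir_code_system="http://hl7.org/fhir/administrative-gender",
            fhir_code="female",
            program="core",
            validation_status="validated"),
        DictionaryEntry(
            element_id="sti-partner-communication-reason",
            label="Reason partner not notified",
            description="Reason the partner notification was not performed",
            answer_type="choice",
            fhir_resource_path="Communication.statusReason",
            value_set_binding="http://hl7.org/fhir/ValueSet/communication-not-done-reason",
            target_profile_id="WHO-STI Communication (Partner)",
            program="sti",
            validation_status="validated"),
    ]


def _synthetic_entry(profile_name: str) -> DictionaryEntry:
    program, rtype, label = _profile_parts(profile_name)
    path = _DEFAULT_PATH[rtype]
    answer_type = "text"
    semantic = ""
    description = f"{label} (synthetic element content behind the published profile name)"
    if rtype == "Observation":
        if label in _QUANTITY_LABELS:
            answer_type = "quantity"
        elif label in _DATE_LABELS:
            answer_type = "date"
        elif label in _TEXT_LABELS:
            answer_type = "text"
        else:
            answer_type = "boolean"
    elif rtype == "Appointment":
        answer_type = "date"
    elif rtype == "Condition":
        answer_type = "boolean"
        semantic = f"SNOMED: {_synthetic_snomed(profile_name)} (maps to {label})"
        description += "; synthetic SNOMED-format code"
    return DictionaryEntry(
        element_id=slugify(profile_name),
        label=label,
        description=description,
        answer_type=answer_type,
        fhir_resource_path=path,
        target_profile_id=profile_name,
        semantic_code_text=semantic,
        program=program,  # type: ignore[arg-type]
        validation_status="mapped")


def published_fixture() -> DataDictionary:
    """The desk-scale reconstruction of the published mapping exercise."""
    entries = _exemplar_entries()
    for program in ("core", "fp", "sti"):
        for profile_name in INVENTORY[program]:
            if profile_name in _EXEMPLAR_PROFILES:
                continue
            entries.append(_synthetic_entry(profile_name))
    return DataDictionary(entries=entries, source_sheets=["published-fixture"])


def single_entry_fixture(element_id: str) -> DataDictionary:
    """One-row dictionary holding a single worked example (by element id)."""
    for e in _exemplar_entries():
        if e.element_id == element_id:
            return DataDictionary(entries=[e], source_sheets=["single"])
    raise KeyError(element_id)


# ---------------------------------------------------------------------------
# random dictionaries

class FixtureSpec(BaseModel):
    """Parameters of a synthetic random dictionary."""

    seed: int = 0
    n_entries: int = 20
    program_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # core, fp, sti
    fraction_choice: float = 0.25
    fraction_quantity: float = 0.2
    fraction_boolean: float = 0.3
    codes_per_option: tuple[int, int] = (1, 1)
    duplicate_rate: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        if abs(sum(self.program_mix) - 1.0) > 1e-9:
            raise FixtureSpecError("program_mix must sum to 1")
        for name in ("fraction_choice", "fraction_quantity",
                     "fraction_boolean", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureSpecError(f"{name} must be in [0, 1]")
        if self.fraction_choice + self.fraction_quantity + self.fraction_boolean > 1.0 + 1e-9:
            raise FixtureSpecError("answer-type fractions exceed 1")
        if self.n_entries == 0 and self.duplicate_rate > 0:
            raise FixtureSpecError("cannot duplicate rows in an empty dictionary")
        if self.n_entries < 0:
            raise FixtureSpecError("n_entries must be >= 0")
        return self


_RANDOM_RESOURCES = ["Observation", "Condition", "MedicationStatement",
                     "Procedure", "Encounter", "Specimen"]


def random_dictionary(spec: FixtureSpec) -> DataDictionary:
    """Reproducible random dictionary respecting the spec's proportions.

    The last ``round(n_entries * duplicate_rate)`` rows are deliberate
    duplicates of earlier rows (same label, mapping and profile, fresh
    element id, marked in notes) so consolidation has something to find.
    Every generated code satisfies its system's format rule.
    """
    rng = random.Random(spec.seed)
    n_dup = round(spec.n_entries * spec.duplicate_rate)
    if spec.n_entries > 0:
        n_dup = min(n_dup, spec.n_entries - 1)  # at least one original to copy
    n_unique = spec.n_entries - n_dup
    entries: list[DictionaryEntry] = []
    for i in range(n_unique):
        label = f"Concept {spec.seed:03d}-{i:04d}"
        program = rng.choices(["core", "fp", "sti"], weights=spec.program_mix)[0]
        u = rng.random()
        if u < spec.fraction_choice:
            answer_type = "choice"
        elif u < spec.fraction_choice + spec.fraction_quantity:
            answer_type = "quantity"
        elif u < spec.fraction_choice + spec.fraction_quantity + spec.fraction_boolean:
            answer_type = "boolean"
        else:
            answer_type = "text"
        rtype = rng.choice(_RANDOM_RESOURCES)
        if answer_type in ("quantity", "choice"):
            rtype = "Observation"  # value[x] carries the answer
        path = _DEFAULT_PATH[rtype]
        options: list[str] = []
        segments: list[str] = []
        if rtype == "Condition":
            segments.append(f"SNOMED: {rng.randrange(10**7, 10**8)} (maps to {label})")
        if answer_type == "choice":
            k = rng.randint(2, 4)
            options = [f"{label} option {j}" for j in range(k)]
            for opt in options:
                for _ in range(rng.randint(*spec.codes_per_option)):
                    segments.append(f"SNOMED: {rng.randrange(10**7, 10**8)} (maps to {opt})")
        entries.append(DictionaryEntry(
            element_id=f"gen-{spec.seed}-{i:04d}",
            label=label,
            answer_type=answer_type,
            answer_options=options,
            fhir_resource_path=path,
            target_profile_id=f"Gen {program.upper()} {rtype} ({label})",
            semantic_code_text="\n".join(segments),
            program=program,  # type: ignore[arg-type]
            validation_status="mapped"))
    for j in range(n_dup):
        src = entries[rng.randrange(n_unique)]
        dup = src.model_copy(deep=True)
        dup.element_id = f"gen-{spec.seed}-dup-{j:04d}"
        dup.notes = f"deliberate duplicate of {src.element_id}"
        entries.append(dup)
    return DataDictionary(entries=entries,
                          source_sheets=[f"random-{spec.seed}"])
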