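"""Regenerate src/dak2fhir/data/fhir_r4_base.json.

Maintainer script: the element tables below are transcribed from the
published FHIR R4 (4.0.1) resource definitions, restricted to top-level
elements plus the handful of nested paths profiles commonly constrain.
Running it rewrites the vendored data file deterministically; it is not
needed at test or run time.
"""

from __future__ import annotations

import json
from pathlib import Path

# (path, types, min, max); "[x]" marks choice elements.
# max is "1" or "*".
R4: dict[str, list[tuple[str, list[str], int, str]]] = {
    "AllergyIntolerance": [
        ("identifier", ["Identifier"], 0, "*"),
        ("clinicalStatus", ["CodeableConcept"], 0, "1"),
        ("verificationStatus", ["CodeableConcept"], 0, "1"),
        ("type", ["code"], 0, "1"),
        ("category", ["code"], 0, "*"),
        ("criticality", ["code"], 0, "1"),
        ("code", ["CodeableConcept"], 0, "1"),
        ("patient", ["Reference"], 1, "1"),
        ("encounter", ["Reference"], 0, "1"),
        ("onset[x]", ["dateTime", "Age", "Period", "Range", "string"], 0, "1"),
        ("recordedDate", ["dateTime"], 0, "1"),
        ("recorder", ["Reference"], 0, "1"),
        ("asserter", ["Reference"], 0, "1"),
        ("lastOccurrence", ["dateTime"], 0, "1"),
        ("note", ["Annotation"], 0, "*"),
        ("reaction", ["BackboneElement"], 0, "*"),
        ("reaction.substance", ["CodeableConcept"], 0, "1"),
        ("reaction.manifestation", ["CodeableConcept"], 1, "*"),
        ("reaction.severity", ["code"], 0, "1"),
    ],
    "Appointment": [
        ("identifier", ["Identifier"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("cancelationReason", ["CodeableConcept"], 0, "1"),
        ("serviceCategory", ["CodeableConcept"], 0, "*"),
        ("serviceType", ["CodeableConcept"], 0, "*"),
        ("specialty", ["CodeableConcept"], 0, "*"),
        ("appointmentType", ["CodeableConcept"], 0, "1"),
        ("reasonCode", ["CodeableConcept"], 0, "*"),
        ("reasonReference", ["Reference"], 0, "*"),
        ("priority", ["unsignedInt"], 0, "1"),
        ("description", ["string"], 0, "1"),
        ("supportingInformation", ["Reference"], 0, "*"),
        ("start", ["instant"], 0, "1"),
        ("end", ["instant"], 0, "1"),
        ("minutesDuration", ["positiveInt"], 0, "1"),
        ("slot", ["Reference"], 0, "*"),
        ("created", ["dateTime"], 0, "1"),
        ("comment", ["string"], 0, "1"),
        ("patientInstruction", ["string"], 0, "1"),
        ("basedOn", ["Reference"], 0, "*"),
        ("participant", ["BackboneElement"], 1, "*"),
        ("participant.type", ["CodeableConcept"], 0, "*"),
        ("participant.actor", ["Reference"], 0, "1"),
        ("participant.status", ["code"], 1, "1"),
        ("requestedPeriod", ["Period"], 0, "*"),
    ],
    "CarePlan": [
        ("identifier", ["Identifier"], 0, "*"),
        ("instantiatesCanonical", ["canonical"], 0, "*"),
        ("instantiatesUri", ["uri"], 0, "*"),
        ("basedOn", ["Reference"], 0, "*"),
        ("replaces", ["Reference"], 0, "*"),
        ("partOf", ["Reference"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("intent", ["code"], 1, "1"),
        ("category", ["CodeableConcept"], 0, "*"),
        ("title", ["string"], 0, "1"),
        ("description", ["string"], 0, "1"),
        ("subject", ["Reference"], 1, "1"),
        ("encounter", ["Reference"], 0, "1"),
        ("period", ["Period"], 0, "1"),
        ("created", ["dateTime"], 0, "1"),
        ("author", ["Reference"], 0, "1"),
        ("contributor", ["Reference"], 0, "*"),
        ("careTeam", ["Reference"], 0, "*"),
        ("addresses", ["Reference"], 0, "*"),
        ("supportingInfo", ["Reference"], 0, "*"),
        ("goal", ["Reference"], 0, "*"),
        ("activity", ["BackboneElement"], 0, "*"),
        ("activity.outcomeCodeableConcept", ["CodeableConcept"], 0, "*"),
        ("activity.detail", ["BackboneElement"], 0, "1"),
        ("activity.detail.code", ["CodeableConcept"], 0, "1"),
        ("activity.detail.status", ["code"], 1, "1"),
        ("note", ["Annotation"], 0, "*"),
    ],
    "Communication": [
        ("identifier", ["Identifier"], 0, "*"),
        ("instantiatesCanonical", ["canonical"], 0, "*"),
        ("instantiatesUri", ["uri"], 0, "*"),
        ("basedOn", ["Reference"], 0, "*"),
        ("partOf", ["Reference"], 0, "*"),
        ("inResponseTo", ["Reference"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("statusReason", ["CodeableConcept"], 0, "1"),
        ("category", ["CodeableConcept"], 0, "*"),
        ("priority", ["code"], 0, "1"),
        ("medium", ["CodeableConcept"], 0, "*"),
        ("subject", ["Reference"], 0, "1"),
        ("topic", ["CodeableConcept"], 0, "1"),
        ("about", ["Reference"], 0, "*"),
        ("encounter", ["Reference"], 0, "1"),
        ("sent", ["dateTime"], 0, "1"),
        ("received", ["dateTime"], 0, "1"),
        ("recipient", ["Reference"], 0, "*"),
        ("sender", ["Reference"], 0, "1"),
        ("reasonCode", ["CodeableConcept"], 0, "*"),
        ("reasonReference", ["Reference"], 0, "*"),
        ("payload", ["BackboneElement"], 0, "*"),
        ("note", ["Annotation"], 0, "*"),
    ],
    "Condition": [
        ("identifier", ["Identifier"], 0, "*"),
        ("clinicalStatus", ["CodeableConcept"], 0, "1"),
        ("verificationStatus", ["CodeableConcept"], 0, "1"),
        ("category", ["CodeableConcept"], 0, "*"),
        ("severity", ["CodeableConcept"], 0, "1"),
        ("code", ["CodeableConcept"], 0, "1"),
        ("bodySite", ["CodeableConcept"], 0, "*"),
        ("subject", ["Reference"], 1, "1"),
        ("encounter", ["Reference"], 0, "1"),
        ("onset[x]", ["dateTime", "Age", "Period", "Range", "string"], 0, "1"),
        ("abatement[x]", ["dateTime", "Age", "Period", "Range", "string"], 0, "1"),
        ("recordedDate", ["dateTime"], 0, "1"),
        ("recorder", ["Reference"], 0, "1"),
        ("asserter", ["Reference"], 0, "1"),
        ("stage", ["BackboneElement"], 0, "*"),
        ("stage.summary", ["CodeableConcept"], 0, "1"),
        ("evidence", ["BackboneElement"], 0, "*"),
        ("evidence.code", ["CodeableConcept"], 0, "*"),
        ("note", ["Annotation"], 0, "*"),
    ],
    "Consent": [
        ("identifier", ["Identifier"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("scope", ["CodeableConcept"], 1, "1"),
        ("category", ["CodeableConcept"], 1, "*"),
        ("patient", ["Reference"], 0, "1"),
        ("dateTime", ["dateTime"], 0, "1"),
        ("performer", ["Reference"], 0, "*"),
        ("organization", ["Reference"], 0, "*"),
        ("source[x]", ["Attachment", "Reference"], 0, "1"),
        ("policy", ["BackboneElement"], 0, "*"),
        ("policyRule", ["CodeableConcept"], 0, "1"),
        ("verification", ["BackboneElement"], 0, "*"),
        ("provision", ["BackboneElement"], 0, "1"),
    ],
    "Coverage": [
        ("identifier", ["Identifier"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("type", ["CodeableConcept"], 0, "1"),
        ("policyHolder", ["Reference"], 0, "1"),
        ("subscriber", ["Reference"], 0, "1"),
        ("subscriberId", ["string"], 0, "1"),
        ("beneficiary", ["Reference"], 1, "1"),
        ("dependent", ["string"], 0, "1"),
        ("relationship", ["CodeableConcept"], 0, "1"),
        ("period", ["Period"], 0, "1"),
        ("payor", ["Reference"], 1, "*"),
        ("class", ["BackboneElement"], 0, "*"),
        ("order", ["positiveInt"], 0, "1"),
        ("network", ["string"], 0, "1"),
        ("costToBeneficiary", ["BackboneElement"], 0, "*"),
        ("subrogation", ["boolean"], 0, "1"),
        ("contract", ["Reference"], 0, "*"),
    ],
    "DeviceUseStatement": [
        ("identifier", ["Identifier"], 0, "*"),
        ("basedOn", ["Reference"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("subject", ["Reference"], 1, "1"),
        ("derivedFrom", ["Reference"], 0, "*"),
        ("timing[x]", ["Timing", "Period", "dateTime"], 0, "1"),
        ("recordedOn", ["dateTime"], 0, "1"),
        ("source", ["Reference"], 0, "1"),
        ("device", ["Reference"], 1, "1"),
        ("reasonCode", ["CodeableConcept"], 0, "*"),
        ("reasonReference", ["Reference"], 0, "*"),
        ("bodySite", ["CodeableConcept"], 0, "1"),
        ("note", ["Annotation"], 0, "*"),
    ],
    "Encounter": [
        ("identifier", ["Identifier"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("statusHistory", ["BackboneElement"], 0, "*"),
        ("class", ["Coding"], 1, "1"),
        ("classHistory", ["BackboneElement"], 0, "*"),
        ("type", ["CodeableConcept"], 0, "*"),
        ("serviceType", ["CodeableConcept"], 0, "1"),
        ("priority", ["CodeableConcept"], 0, "1"),
        ("subject", ["Reference"], 0, "1"),
        ("episodeOfCare", ["Reference"], 0, "*"),
        ("basedOn", ["Reference"], 0, "*"),
        ("participant", ["BackboneElement"], 0, "*"),
        ("appointment", ["Reference"], 0, "*"),
        ("period", ["Period"], 0, "1"),
        ("length", ["Duration"], 0, "1"),
        ("reasonCode", ["CodeableConcept"], 0, "*"),
        ("reasonReference", ["Reference"], 0, "*"),
        ("diagnosis", ["BackboneElement"], 0, "*"),
        ("account", ["Reference"], 0, "*"),
        ("hospitalization", ["BackboneElement"], 0, "1"),
        ("location", ["BackboneElement"], 0, "*"),
        ("serviceProvider", ["Reference"], 0, "1"),
        ("partOf", ["Reference"], 0, "1"),
    ],
    "HealthcareService": [
        ("identifier", ["Identifier"], 0, "*"),
        ("active", ["boolean"], 0, "1"),
        ("providedBy", ["Reference"], 0, "1"),
        ("category", ["CodeableConcept"], 0, "*"),
        ("type", ["CodeableConcept"], 0, "*"),
        ("specialty", ["CodeableConcept"], 0, "*"),
        ("location", ["Reference"], 0, "*"),
        ("name", ["string"], 0, "1"),
        ("comment", ["string"], 0, "1"),
        ("extraDetails", ["markdown"], 0, "1"),
        ("photo", ["Attachment"], 0, "1"),
        ("telecom", ["ContactPoint"], 0, "*"),
        ("coverageArea", ["Reference"], 0, "*"),
        ("serviceProvisionCode", ["CodeableConcept"], 0, "*"),
        ("eligibility", ["BackboneElement"], 0, "*"),
        ("program", ["CodeableConcept"], 0, "*"),
        ("characteristic", ["CodeableConcept"], 0, "*"),
        ("communication", ["CodeableConcept"], 0, "*"),
        ("referralMethod", ["CodeableConcept"], 0, "*"),
        ("appointmentRequired", ["boolean"], 0, "1"),
        ("availableTime", ["BackboneElement"], 0, "*"),
        ("notAvailable", ["BackboneElement"], 0, "*"),
        ("availabilityExceptions", ["string"], 0, "1"),
        ("endpoint", ["Reference"], 0, "*"),
    ],
    "Medication": [
        ("identifier", ["Identifier"], 0, "*"),
        ("code", ["CodeableConcept"], 0, "1"),
        ("status", ["code"], 0, "1"),
        ("manufacturer", ["Reference"], 0, "1"),
        ("form", ["CodeableConcept"], 0, "1"),
        ("amount", ["Ratio"], 0, "1"),
        ("ingredient", ["BackboneElement"], 0, "*"),
        ("ingredient.item[x]", ["CodeableConcept", "Reference"], 1, "1"),
        ("batch", ["BackboneElement"], 0, "1"),
    ],
    "MedicationAdministration": [
        ("identifier", ["Identifier"], 0, "*"),
        ("instantiates", ["uri"], 0, "*"),
        ("partOf", ["Reference"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("statusReason", ["CodeableConcept"], 0, "*"),
        ("category", ["CodeableConcept"], 0, "1"),
        ("medication[x]", ["CodeableConcept", "Reference"], 1, "1"),
        ("subject", ["Reference"], 1, "1"),
        ("context", ["Reference"], 0, "1"),
        ("supportingInformation", ["Reference"], 0, "*"),
        ("effective[x]", ["dateTime", "Period"], 1, "1"),
        ("performer", ["BackboneElement"], 0, "*"),
        ("reasonCode", ["CodeableConcept"], 0, "*"),
        ("reasonReference", ["Reference"], 0, "*"),
        ("request", ["Reference"], 0, "1"),
        ("device", ["Reference"], 0, "*"),
        ("note", ["Annotation"], 0, "*"),
        ("dosage", ["BackboneElement"], 0, "1"),
        ("dosage.route", ["CodeableConcept"], 0, "1"),
        ("dosage.dose", ["Quantity"], 0, "1"),
        ("eventHistory", ["Reference"], 0, "*"),
    ],
    "MedicationStatement": [
        ("identifier", ["Identifier"], 0, "*"),
        ("basedOn", ["Reference"], 0, "*"),
        ("partOf", ["Reference"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("statusReason", ["CodeableConcept"], 0, "*"),
        ("category", ["CodeableConcept"], 0, "1"),
        ("medication[x]", ["CodeableConcept", "Reference"], 1, "1"),
        ("subject", ["Reference"], 1, "1"),
        ("context", ["Reference"], 0, "1"),
        ("effective[x]", ["dateTime", "Period"], 0, "1"),
        ("dateAsserted", ["dateTime"], 0, "1"),
        ("informationSource", ["Reference"], 0, "1"),
        ("derivedFrom", ["Reference"], 0, "*"),
        ("reasonCode", ["CodeableConcept"], 0, "*"),
        ("reasonReference", ["Reference"], 0, "*"),
        ("note", ["Annotation"], 0, "*"),
        ("dosage", ["Dosage"], 0, "*"),
    ],
    "Observation": [
        ("identifier", ["Identifier"], 0, "*"),
        ("basedOn", ["Reference"], 0, "*"),
        ("partOf", ["Reference"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("category", ["CodeableConcept"], 0, "*"),
        ("code", ["CodeableConcept"], 1, "1"),
        ("subject", ["Reference"], 0, "1"),
        ("focus", ["Reference"], 0, "*"),
        ("encounter", ["Reference"], 0, "1"),
        ("effective[x]", ["dateTime", "Period", "Timing", "instant"], 0, "1"),
        ("issued", ["instant"], 0, "1"),
        ("performer", ["Reference"], 0, "*"),
        ("value[x]", ["Quantity", "CodeableConcept", "string", "boolean",
                      "integer", "Range", "Ratio", "SampledData", "time",
                      "dateTime", "Period"], 0, "1"),
        ("dataAbsentReason", ["CodeableConcept"], 0, "1"),
        ("interpretation", ["CodeableConcept"], 0, "*"),
        ("note", ["Annotation"], 0, "*"),
        ("bodySite", ["CodeableConcept"], 0, "1"),
        ("method", ["CodeableConcept"], 0, "1"),
        ("specimen", ["Reference"], 0, "1"),
        ("device", ["Reference"], 0, "1"),
        ("referenceRange", ["BackboneElement"], 0, "*"),
        ("hasMember", ["Reference"], 0, "*"),
        ("derivedFrom", ["Reference"], 0, "*"),
        ("component", ["BackboneElement"], 0, "*"),
        ("component.code", ["CodeableConcept"], 1, "1"),
        ("component.value[x]", ["Quantity", "CodeableConcept", "string",
                                "boolean", "integer", "Range", "Ratio",
                                "SampledData", "time", "dateTime", "Period"],
         0, "1"),
    ],
    "Patient": [
        ("identifier", ["Identifier"], 0, "*"),
        ("active", ["boolean"], 0, "1"),
        ("name", ["HumanName"], 0, "*"),
        ("telecom", ["ContactPoint"], 0, "*"),
        ("gender", ["code"], 0, "1"),
        ("birthDate", ["date"], 0, "1"),
        ("deceased[x]", ["boolean", "dateTime"], 0, "1"),
        ("address", ["Address"], 0, "*"),
        ("maritalStatus", ["CodeableConcept"], 0, "1"),
        ("multipleBirth[x]", ["boolean", "integer"], 0, "1"),
        ("photo", ["Attachment"], 0, "*"),
        ("contact", ["BackboneElement"], 0, "*"),
        ("communication", ["BackboneElement"], 0, "*"),
        ("communication.language", ["CodeableConcept"], 1, "1"),
        ("generalPractitioner", ["Reference"], 0, "*"),
        ("managingOrganization", ["Reference"], 0, "1"),
        ("link", ["BackboneElement"], 0, "*"),
    ],
    "Practitioner": [
        ("identifier", ["Identifier"], 0, "*"),
        ("active", ["boolean"], 0, "1"),
        ("name", ["HumanName"], 0, "*"),
        ("telecom", ["ContactPoint"], 0, "*"),
        ("address", ["Address"], 0, "*"),
        ("gender", ["code"], 0, "1"),
        ("birthDate", ["date"], 0, "1"),
        ("photo", ["Attachment"], 0, "*"),
        ("qualification", ["BackboneElement"], 0, "*"),
        ("qualification.code", ["CodeableConcept"], 1, "1"),
        ("communication", ["CodeableConcept"], 0, "*"),
    ],
    "Procedure": [
        ("identifier", ["Identifier"], 0, "*"),
        ("instantiatesCanonical", ["canonical"], 0, "*"),
        ("instantiatesUri", ["uri"], 0, "*"),
        ("basedOn", ["Reference"], 0, "*"),
        ("partOf", ["Reference"], 0, "*"),
        ("status", ["code"], 1, "1"),
        ("statusReason", ["CodeableConcept"], 0, "1"),
        ("category", ["CodeableConcept"], 0, "1"),
        ("code", ["CodeableConcept"], 0, "1"),
        ("subject", ["Reference"], 1, "1"),
        ("encounter", ["Reference"], 0, "1"),
        ("performed[x]", ["dateTime", "Period", "string", "Age", "Range"], 0, "1"),
        ("recorder", ["Reference"], 0, "1"),
        ("asserter", ["Reference"], 0, "1"),
        ("performer", ["BackboneElement"], 0, "*"),
        ("location", ["Reference"], 0, "1"),
        ("reasonCode", ["CodeableConcept"], 0, "*"),
        ("reasonReference", ["Reference"], 0, "*"),
        ("bodySite", ["CodeableConcept"], 0, "*"),
        ("outcome", ["CodeableConcept"], 0, "1"),
        ("report", ["Reference"], 0, "*"),
        ("complication", ["CodeableConcept"], 0, "*"),
        ("complicationDetail", ["Reference"], 0, "*"),
        ("followUp", ["CodeableConcept"], 0, "*"),
        ("note", ["Annotation"], 0, "*"),
        ("focalDevice", ["BackboneElement"], 0, "*"),
        ("usedReference", ["Reference"], 0, "*"),
        ("usedCode", ["CodeableConcept"], 0, "*"),
    ],
    "ServiceRequest": [
        ("identifier", ["Identifier"], 0, "*"),
        ("instantiatesCanonical", ["canonical"], 0, "*"),
        ("instantiatesUri", ["uri"], 0, "*"),
        ("basedOn", ["Reference"], 0, "*"),
        ("replaces", ["Reference"], 0, "*"),
        ("requisition", ["Identifier"], 0, "1"),
        ("status", ["code"], 1, "1"),
        ("intent", ["code"], 1, "1"),
        ("category", ["CodeableConcept"], 0, "*"),
        ("priority", ["code"], 0, "1"),
        ("doNotPerform", ["boolean"], 0, "1"),
        ("code", ["CodeableConcept"], 0, "1"),
        ("orderDetail", ["CodeableConcept"], 0, "*"),
        ("quantity[x]", ["Quantity", "Ratio", "Range"], 0, "1"),
        ("subject", ["Reference"], 1, "1"),
        ("encounter", ["Reference"], 0, "1"),
        ("occurrence[x]", ["dateTime", "Period", "Timing"], 0, "1"),
        ("asNeeded[x]", ["boolean", "CodeableConcept"], 0, "1"),
        ("authoredOn", ["dateTime"], 0, "1"),
        ("requester", ["Reference"], 0, "1"),
        ("performerType", ["CodeableConcept"], 0, "1"),
        ("performer", ["Reference"], 0, "*"),
        ("locationCode", ["CodeableConcept"], 0, "*"),
        ("locationReference", ["Reference"], 0, "*"),
        ("reasonCode", ["CodeableConcept"], 0, "*"),
        ("reasonReference", ["Reference"], 0, "*"),
        ("insurance", ["Reference"], 0, "*"),
        ("supportingInfo", ["Reference"], 0, "*"),
        ("specimen", ["Reference"], 0, "*"),
        ("bodySite", ["CodeableConcept"], 0, "*"),
        ("note", ["Annotation"], 0, "*"),
        ("patientInstruction", ["string"], 0, "1"),
        ("relevantHistory", ["Reference"], 0, "*"),
    ],
    "Specimen": [
        ("identifier", ["Identifier"], 0, "*"),
        ("accessionIdentifier", ["Identifier"], 0, "1"),
        ("status", ["code"], 0, "1"),
        ("type", ["CodeableConcept"], 0, "1"),
        ("subject", ["Reference"], 0, "1"),
        ("receivedTime", ["dateTime"], 0, "1"),
        ("parent", ["Reference"], 0, "*"),
        ("request", ["Reference"], 0, "*"),
        ("collection", ["BackboneElement"], 0, "1"),
        ("collection.method", ["CodeableConcept"], 0, "1"),
        ("collection.bodySite", ["CodeableConcept"], 0, "1"),
        ("processing", ["BackboneElement"], 0, "*"),
        ("container", ["BackboneElement"], 0, "*"),
        ("condition", ["CodeableConcept"], 0, "*"),
        ("note", ["Annotation"], 0, "*"),
    ],
}

# Elements every DomainResource inherits.
DOMAIN_RESOURCE = [
    ("id", ["id"], 0, "1"),
    ("meta", ["Meta"], 0, "1"),
    ("implicitRules", ["uri"], 0, "1"),
    ("language", ["code"], 0, "1"),
    ("text", ["Narrative"], 0, "1"),
    ("contained", ["Resource"], 0, "*"),
    ("extension", ["Extension"], 0, "*"),
    ("modifierExtension", ["Extension"], 0, "*"),
]


def main() -> None:
    out = {"fhirVersion": "4.0.1", "resources": {}}
    for rtype in sorted(R4):
        elements = {}
        for path, types, mn, mx in DOMAIN_RESOURCE + R4[rtype]:
            elements[path] = {"types": types, "min": mn, "max": mx}
        out["resources"][rtype] = {
            "canonical": f"http://hl7.org/fhir/StructureDefinition/{rtype}",
            "elements": elements,
        }
    dest = Path(__file__).resolve().parent.parent / "src" / "dak2fhir" / "data" / "fhir_r4_base.json"
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_text(json.dumps(out, indent=1) + "\n")
    print(f"wrote {dest} ({dest.stat().st_size} bytes, {len(out['resources'])} resources)")


if __name__ == "__main__":
    main()
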