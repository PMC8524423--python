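"""Offline FHIR R4 base-resource metadata and conformance-resource validation.

The package vendors a compact element table (path, types, cardinality) for
the 19 R4 resource types this pipeline supports, covering all top-level
elements plus the nested paths profiles commonly constrain.  That table backs
two things: path checking during profile construction, and a self-contained
structural validator for emitted StructureDefinitions.  Nothing here touches
the network; ``scripts/gen_base_metadata.py`` regenerates the table for
maintainers.

This is deliberately not a general FHIR validator: no snapshots, no slicing,
no terminology expansion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources as importlib_resources

#: Datatypes a value-set binding may legally attach to.
BINDABLE_TYPES = {"code", "Coding", "CodeableConcept", "Quantity", "string", "uri"}

#: StructureDefinition fields the validator requires.
MANDATORY_SD_FIELDS = ("resourceType", "url", "name", "status", "kind",
                       "abstract", "type", "baseDefinition", "derivation")


@dataclass(frozen=True)
class ElementMeta:
    """Base-definition facts about one element path."""

    path: str
    types: tuple[str, ...]
    min: int
    max: str  # "1" or "*"

    @property
    def max_int(self) -> float:
        return float("inf") if self.max == "*" else int(self.max)

    @property
    def bindable(self) -> bool:
        return any(t in BINDABLE_TYPES for t in self.types)


@dataclass(frozen=True)
class BaseResourceMeta:
    resource_type: str
    canonical_url: str
    elements: dict[str, ElementMeta]


@lru_cache(maxsize=1)
def _load() -> dict[str, BaseResourceMeta]:
    raw = json.loads(
        importlib_resources.files("dak2fhir").joinpath("data/fhir_r4_base.json").read_text())
    out: dict[str, BaseResourceMeta] = {}
    for rtype, body in raw["resources"].items():
        elements = {
            path: ElementMeta(path=path, types=tuple(e["types"]),
                              min=e["min"], max=e["max"])
            for path, e in body["elements"].items()
        }
        out[rtype] = BaseResourceMeta(resource_type=rtype,
                                      canonical_url=body["canonical"],
                                      elements=elements)
    return out


def supported_resources() -> list[str]:
    """The closed, sorted list of resource types this pipeline profiles."""
    return sorted(_load())


def base_meta(resource_type: str) -> BaseResourceMeta | None:
    return _load().get(resource_type)


def base_canonical(resource_type: str) -> str:
    return f"http://hl7.org/fhir/StructureDefinition/{resource_type}"


def element_meta(resource_type: str, element_path: str) -> ElementMeta | None:
    """Look up an element path, resolving choice-type variants.

    ``Observation.value`` and ``Observation.valueQuantity`` both resolve to
    the ``value[x]`` choice element; a typed variant only resolves when the
    named type is among the choice's types.
    """
    meta = base_meta(resource_type)
    if meta is None:
        return None
    if element_path in meta.elements:
        return meta.elements[element_path]
    # bare stem of a choice element: "value" -> "value[x]"
    if f"{element_path}[x]" in meta.elements:
        return meta.elements[f"{element_path}[x]"]
    # typed variant: "valueCodeableConcept" -> "value[x]" + type CodeableConcept
    for key, em in meta.elements.items():
        if not key.endswith("[x]"):
            continue
        stem = key[:-3]
        if element_path.startswith(stem) and len(element_path) > len(stem):
            suffix = element_path[len(stem):]
            if any(t.lower() == suffix.lower() for t in em.types):
                return em
    return None


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    location: str
    message: str


def _issue(loc: str, msg: str, severity: str = "error") -> ValidationIssue:
    return ValidationIssue(severity=severity, location=loc, message=msg)


def validate_structuredef(doc: dict) -> list[ValidationIssue]:
    """Structurally validate a StructureDefinition differential.

    Checks, against the vendored base metadata: mandatory fields, base
    resource known, every differential path present in the base (generated
    extensions excepted), cardinalities within base bounds, bindings only on
    bindable elements, and the R4 version/derivation pins.  Returns issues;
    an empty list means the document is clean.
    """
    issues: list[ValidationIssue] = []
    if not isinstance(doc, dict):
        return [_issue("", "document is not a JSON object")]
    for field in MANDATORY_SD_FIELDS:
        if field not in doc or doc.get(field) in (None, ""):
            if field != "abstract" or "abstract" not in doc:
                issues.append(_issue(field, f"missing mandatory field {field!r}"))
    if doc.get("resourceType") not in (None, "StructureDefinition"):
        issues.append(_issue("resourceType",
                             f"expected StructureDefinition, got {doc.get('resourceType')!r}"))
    if "fhirVersion" in doc and doc["fhirVersion"] != "4.0.1":
        issues.append(_issue("fhirVersion",
                             f"expected 4.0.1, got {doc['fhirVersion']!r}"))
    if "derivation" in doc and doc["derivation"] != "constraint":
        issues.append(_issue("derivation",
                             f"expected 'constraint', got {doc['derivation']!r}"))
    rtype = doc.get("type")
    meta = base_meta(rtype) if rtype else None
    if rtype and meta is None:
        issues.append(_issue("type", f"unknown base resource type {rtype!r}"))
    if rtype and doc.get("baseDefinition") not in (None, base_canonical(rtype)):
        issues.append(_issue("baseDefinition",
                             f"baseDefinition does not match the {rtype} base canonical"))

    declared_extensions = {
        e.get("path") for e in doc.get("_generatedExtensions", [])
    } if isinstance(doc.get("_generatedExtensions"), list) else set()

    elements = (doc.get("differential") or {}).get("element") or []
    if not elements:
        issues.append(_issue("differential", "differential has no elements"))
    for i, el in enumerate(elements):
        loc = f"differential.element[{i}]"
        path = el.get("path")
        if not path:
            issues.append(_issue(loc, "element has no path"))
            continue
        if meta is None:
            continue
        head, _, rest = path.partition(".")
        if head != rtype:
            issues.append(_issue(loc, f"path {path!r} does not start with {rtype!r}"))
            continue
        if not rest:  # root element
            continue
        if rest.startswith("extension"):
            continue
        em = element_meta(rtype, rest)
        if em is None:
            if path in declared_extensions:
                continue
            issues.append(_issue(loc, f"path {path!r} not found in the {rtype} base definition"))
            continue
        if "min" in el and int(el["min"]) < em.min:
            issues.append(_issue(loc, f"min {el['min']} below base minimum {em.min} for {path!r}"))
        if "max" in el:
            mx = el["max"]
            mx_val = float("inf") if mx == "*" else int(mx)
            if mx_val > em.max_int:
                issues.append(_issue(loc, f"max {mx!r} above base maximum {em.max!r} for {path!r}"))
            if "min" in el and mx != "*" and int(el["min"]) > int(mx):
                issues.append(_issue(loc, f"min {el['min']} exceeds max {mx!r} for {path!r}"))
        if "binding" in el:
            if not em.bindable:
                issues.append(_issue(loc, f"binding on non-bindable element {path!r} "
                                          f"(types: {', '.join(em.types)})"))
            elif not (el["binding"] or {}).get("valueSet"):
                issues.append(_issue(loc, f"binding on {path!r} has no valueSet"))
            if any(k.startswith("pattern") or k.startswith("fixed") for k in el):
                issues.append(_issue(loc, f"fixed value and binding both set on {path!r}"))
    return issues


def error_issues(issues: list[ValidationIssue]) -> list[ValidationIssue]:
    return [i for i in issues if i.severity == "error"]
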