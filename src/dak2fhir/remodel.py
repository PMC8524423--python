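"""Remodeling form-oriented dictionary entries into FHIR-ready entries.

Source dictionaries describe a user interface: questions with expected
answer formats ("Hypertension? yes/no").  A FHIR information model wants the
same fact expressed semantically — e.g. a Condition whose ``code`` is drawn
from a value set of hypertension codes, where *presence of the resource*
replaces the yes/no answer.  Each entry is classified to a remodeling
pattern from a config-driven rule table and transformed accordingly; the
original UI fields are snapshotted onto the entry so the transform is
exactly reversible for display.

Ambiguity is never guessed: entries no rule matches pass through unchanged
with a logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

from .dictionary import DictionaryEntry
from .errors import RemodelError, RevertError
from .naming import slugify
from .terminology import (SNOMED_URI, CodeSystemRegistry, Coding,
                          format_segment, parse_code_text)

logger = logging.getLogger(__name__)

Pattern = Literal["condition_presence", "coded_observation",
                  "quantity_observation", "date_observation",
                  "medication_statement", "procedure", "passthrough"]

#: Standard SNOMED CT yes/no concepts used when a boolean answer must become
#: a coded value.
YES_CODING = Coding(system=SNOMED_URI, code="373066001", display="Yes")
NO_CODING = Coding(system=SNOMED_URI, code="373067005", display="No")


@dataclass(frozen=True)
class UIElement:
    """The user-interface projection of an entry: a form question."""

    question_label: str
    answer_type: str
    answer_options: tuple[str, ...] = ()


@dataclass(frozen=True)
class RemodelRule:
    pattern: Pattern
    target_resource_path: str = ""
    value_set_strategy: Literal["per_question", "shared", "boolean_codes"] = "per_question"


@dataclass
class RemodelConfig:
    """Rule table driving classification.

    ``overrides`` maps element_id → pattern name and wins over the
    resource-type defaults, so alternative modelings (a boolean Observation
    versus a Condition for the same question) are both expressible.
    """

    overrides: dict[str, Pattern] = field(default_factory=dict)
    boolean_codes: tuple[Coding, Coding] = (YES_CODING, NO_CODING)
    registry: CodeSystemRegistry = field(default_factory=CodeSystemRegistry)


def _resource_type(entry: DictionaryEntry) -> str:
    first = entry.fhir_resource_path.replace(";", ",").split(",")[0].strip()
    return first.partition(".")[0]


def classify_entry(entry: DictionaryEntry,
                   config: RemodelConfig | None = None) -> RemodelRule:
    """Select the remodeling pattern for one entry (total and deterministic).

    Explicit per-entry overrides win; otherwise the resource type of the
    FHIR path picks the pattern; anything unresolvable is passthrough.
    """
    config = config or RemodelConfig()
    if entry.element_id in config.overrides:
        return RemodelRule(pattern=config.overrides[entry.element_id],
                           target_resource_path=entry.fhir_resource_path)
    rtype = _resource_type(entry)
    if not rtype:
        logger.debug("entry %s has no FHIR path; passthrough", entry.element_id)
        return RemodelRule(pattern="passthrough")
    if rtype == "Condition":
        return RemodelRule(pattern="condition_presence",
                           target_resource_path=f"{rtype}.code")
    if rtype == "Observation":
        if entry.answer_type == "quantity":
            return RemodelRule(pattern="quantity_observation",
                               target_resource_path=f"{rtype}.valueQuantity")
        if entry.answer_type in ("date", "datetime"):
            return RemodelRule(pattern="date_observation",
                               target_resource_path=f"{rtype}.valueDateTime")
        if entry.answer_type in ("boolean", "choice", "multi-choice"):
            strategy = "boolean_codes" if entry.answer_type == "boolean" else "per_question"
            return RemodelRule(pattern="coded_observation",
                               target_resource_path=f"{rtype}.valueCodeableConcept",
                               value_set_strategy=strategy)
    if rtype == "MedicationStatement":
        return RemodelRule(pattern="medication_statement",
                           target_resource_path=f"{rtype}.medicationCodeableConcept")
    if rtype == "Procedure":
        return RemodelRule(pattern="procedure",
                           target_resource_path=f"{rtype}.code")
    logger.debug("no rule for resource type %s (entry %s); passthrough",
                 rtype, entry.element_id)
    return RemodelRule(pattern="passthrough")


def _snapshot(entry: DictionaryEntry, rule: RemodelRule) -> dict:
    return {
        "pattern": rule.pattern,
        "question_label": entry.label,
        "answer_type": entry.answer_type,
        "answer_options": list(entry.answer_options),
        "fhir_resource_path": entry.fhir_resource_path,
        "value_set_binding": entry.value_set_binding,
    }


def remodel(entry: DictionaryEntry,
            rule: RemodelRule | None = None,
            config: RemodelConfig | None = None) -> DictionaryEntry:
    """Transform one UI-oriented entry per its remodeling rule.

    * ``condition_presence`` — a yes/no question becomes a Condition entry
      whose ``code`` is bound to a value set of the concept's terminology
      codes; presence of the resource replaces the boolean answer.
    * ``coded_observation`` — answer options become a value set bound to the
      value element; boolean answers use the standard yes/no codes.
    * ``quantity_observation`` / ``date_observation`` — the value element is
      typed accordingly; no answer value set.
    * ``medication_statement`` / ``procedure`` — the concept's codes bind the
      medication / procedure code element.
    * ``passthrough`` — the entry is returned unchanged.

    Every non-passthrough output carries a snapshot of the original UI
    fields, so :func:`revert` can reconstruct the question exactly.
    """
    config = config or RemodelConfig()
    rule = rule or classify_entry(entry, config)
    if rule.pattern == "passthrough":
        return entry

    codings, _ = parse_code_text(entry.semantic_code_text, config.registry)
    out = entry.model_copy(deep=True)
    out.ui_metadata = _snapshot(entry, rule)

    if rule.pattern == "condition_presence":
        if not codings and not entry.fhir_code:
            raise RemodelError(entry.element_id,
                               "condition presence needs at least one terminology code")
        out.fhir_resource_path = rule.target_resource_path or "Condition.code"
        if not out.value_set_binding:
            out.value_set_binding = f"{slugify(entry.label)}-codes"
        out.answer_type = "choice"
        out.answer_options = []
    elif rule.pattern == "coded_observation":
        out.fhir_resource_path = rule.target_resource_path or "Observation.valueCodeableConcept"
        if entry.answer_type == "boolean":
            out.answer_type = "choice"
            out.answer_options = [c.display or c.code for c in config.boolean_codes]
            if not out.value_set_binding:
                out.value_set_binding = "yes-no"
            # make the yes/no concepts resolvable by the value-set builder
            segments = [s for c in config.boolean_codes
                        if (s := format_segment(c, config.registry)) is not None]
            out.semantic_code_text = "\n".join(
                x for x in [entry.semantic_code_text, *segments] if x)
        # question concept codes discriminate the observation: fix them on code
        if entry.fhir_code or codings:
            fix = f"Observation.code = {entry.fhir_code}" if entry.fhir_code \
                else f"Observation.code = {codings[0].system}|{codings[0].code}"
            if fix not in out.additional_fhir_attributes:
                out.additional_fhir_attributes = [*out.additional_fhir_attributes, fix]
    elif rule.pattern == "quantity_observation":
        out.fhir_resource_path = rule.target_resource_path or "Observation.valueQuantity"
        out.value_set_binding = ""
        if codings:
            fix = f"Observation.code = {codings[0].system}|{codings[0].code}"
            if fix not in out.additional_fhir_attributes:
                out.additional_fhir_attributes = [*out.additional_fhir_attributes, fix]
    elif rule.pattern == "date_observation":
        out.fhir_resource_path = rule.target_resource_path or "Observation.valueDateTime"
        out.value_set_binding = ""
    elif rule.pattern == "medication_statement":
        out.fhir_resource_path = (rule.target_resource_path
                                  or "MedicationStatement.medicationCodeableConcept")
        if codings and not out.value_set_binding:
            out.value_set_binding = f"{slugify(entry.label)}-medication"
    elif rule.pattern == "procedure":
        out.fhir_resource_path = rule.target_resource_path or "Procedure.code"
        if codings and not out.value_set_binding:
            out.value_set_binding = f"{slugify(entry.label)}-procedure"
    logger.debug("remodeled %s with pattern %s", entry.element_id, rule.pattern)
    return out


def revert(entry: DictionaryEntry) -> UIElement:
    """Reconstruct the pre-remodel form question for display.

    Entries produced by :func:`remodel` carry a snapshot of their UI fields;
    passthrough entries (no snapshot) project their stored fields directly.
    """
    meta = entry.ui_metadata
    if meta is None:
        return UIElement(question_label=entry.label,
                         answer_type=entry.answer_type,
                         answer_options=tuple(entry.answer_options))
    try:
        return UIElement(question_label=meta["question_label"],
                         answer_type=meta["answer_type"],
                         answer_options=tuple(meta["answer_options"]))
    except (KeyError, TypeError) as exc:
        raise RevertError(entry.element_id, f"malformed remodel metadata: {exc}")
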