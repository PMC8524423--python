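"""Structured error types raised by the compiler.

Every error carries enough context (column, label, element id, path …) for a
dictionary maintainer to locate the offending row without a stack trace.  The
CLI maps these onto its exit-code contract: input/load problems exit 2,
validation failures exit 1.
"""

from __future__ import annotations


class Dak2FhirError(Exception):
    """Base class for all structured compiler errors."""


class LoadError(Dak2FhirError):
    """The input table could not be loaded as a data dictionary."""


class MissingColumnError(LoadError):
    def __init__(self, column: str, path: str = ""):
        self.column = column
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"mandatory column {column!r} missing{where}")


class DuplicateIdError(LoadError):
    def __init__(self, element_ids: list[str]):
        self.element_ids = list(element_ids)
        super().__init__(f"duplicate element_id(s): {', '.join(self.element_ids)}")


class UnresolvedSystemError(Dak2FhirError):
    """A terminology label is not in the code-system registry."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"unknown code-system label {label!r}")


class NormalizationError(Dak2FhirError):
    def __init__(self, raw: str):
        self.raw = raw
        super().__init__(f"code normalization of {raw!r} produced an empty token")


class PathError(Dak2FhirError):
    """A FHIR resource path names an unsupported resource type."""

    def __init__(self, resource_type: str, text: str = ""):
        self.resource_type = resource_type
        self.text = text
        super().__init__(f"unsupported FHIR resource type {resource_type!r}"
                         + (f" in path {text!r}" if text else ""))


class AttributeParseError(Dak2FhirError):
    """A fixed-attribute string is not of the form 'path = value'."""

    def __init__(self, text: str, reason: str):
        self.text = text
        self.reason = reason
        super().__init__(f"cannot parse fixed attribute {text!r}: {reason}")


class GroupingError(Dak2FhirError):
    """Entries sharing a target profile name different resource types."""

    def __init__(self, profile_name: str, element_ids: list[str], types: list[str]):
        self.profile_name = profile_name
        self.element_ids = list(element_ids)
        self.types = sorted(set(types))
        super().__init__(
            f"profile {profile_name!r} mixes resource types {self.types} "
            f"(entries: {', '.join(self.element_ids)})")


class RemodelError(Dak2FhirError):
    def __init__(self, element_id: str, reason: str):
        self.element_id = element_id
        self.reason = reason
        super().__init__(f"cannot remodel entry {element_id!r}: {reason}")


class RevertError(Dak2FhirError):
    def __init__(self, element_id: str, reason: str):
        self.element_id = element_id
        self.reason = reason
        super().__init__(f"cannot revert entry {element_id!r}: {reason}")


class EmptyValueSetError(Dak2FhirError):
    def __init__(self, name: str):
        self.name = name
        super().__init__(f"value set {name!r} has zero resolvable options")


class AssignmentError(Dak2FhirError):
    """A profile could not be assigned to an implementation guide."""

    def __init__(self, profile_id: str, reason: str):
        self.profile_id = profile_id
        self.reason = reason
        super().__init__(f"cannot assign profile {profile_id!r} to a guide: {reason}")


class EmitError(Dak2FhirError):
    """Writing the IG tree would clobber differing existing files."""

    def __init__(self, path: str):
        self.path = path
        super().__init__(f"refusing to overwrite differing file {path} "
                         f"(pass overwrite=True to replace)")


class FixtureSpecError(Dak2FhirError):
    def __init__(self, reason: str):
        super().__init__(f"invalid fixture spec: {reason}")
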