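"""Building FHIR R4 conformance resources from remodeled dictionary entries.

Entries sharing a Target Profile ID are grouped into one
:class:`ProfileDefinition` — a differential against the base resource: one
element constraint per mapped path, fixed-value constraints from the
"Additional FHIR Attributes" column, and value-set bindings with the entry's
strength (default ``required``).  Answer value sets are deduplicated by
content hash so a set of codes is specified once and referenced by every
entry that uses it; options without terminology codes get locally assigned
codes in a generated CodeSystem.

Emission is deterministic: equal inputs produce byte-identical JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Literal

from .dictionary import DictionaryEntry
from .errors import (AttributeParseError, EmptyValueSetError, GroupingError,
                     PathError)
from .fhir_base import base_canonical, element_meta, supported_resources
from .naming import slugify
from .terminology import CodeSystemRegistry, Coding, parse_code_text

Strength = Literal["required", "extensible", "preferred", "example"]


# ---------------------------------------------------------------------------
# parsing the mapping columns

def parse_fhir_path(text: str) -> list[tuple[str, str]]:
    """Split a "FHIR Resource" cell into (resource_type, element_path) pairs.

    Multiple comma/semicolon-separated paths are supported; a bare resource
    type yields an empty element path (profile-level mapping).  Unsupported
    resource types raise :class:`PathError`.
    """
    known = set(supported_resources())
    pairs: list[tuple[str, str]] = []
    for part in text.replace(";", ",").split(","):
        part = part.strip()
        if not part:
            continue
        rtype, _, epath = part.partition(".")
        if rtype not in known:
            raise PathError(rtype, part)
        pairs.append((rtype, epath))
    return pairs


@dataclass
class ElementConstraint:
    """One differential row: a constrained element within the profile's
    resource type.  ``path`` is relative to the resource ("" = root).
    Fixed values and bindings are mutually exclusive."""

    path: str
    min: int | None = None
    max: str = ""
    type: str = ""
    fixed_value: str = ""
    fixed_system: str = ""
    binding_url: str = ""
    binding_strength: Strength = "required"
    must_support: bool = True
    is_extension: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if self.fixed_value and self.binding_url:
            raise ValueError(
                f"constraint on {self.path!r}: fixed value and binding both set")

    def sort_key(self) -> tuple:
        return (self.path, self.binding_url, self.fixed_system,
                self.fixed_value, self.type)


def parse_fixed_attribute(text: str) -> ElementConstraint:
    """Parse an "Additional FHIR Attributes" fixation like
    ``"AllergyIntolerance.category = medication"``.

    The left side is a FHIR path (the resource head is validated and
    stripped); the right side is a primitive token or a ``system|code``
    coding.  Anything without exactly one ``=`` is rejected.
    """
    if text.count("=") != 1:
        raise AttributeParseError(
            text, f"expected exactly one '=', found {text.count('=')}")
    left, _, right = text.partition("=")
    left, right = left.strip(), right.strip()
    if not left or not right:
        raise AttributeParseError(text, "empty path or value")
    pairs = parse_fhir_path(left)
    if len(pairs) != 1 or not pairs[0][1]:
        raise AttributeParseError(text, "left side must be one resource.element path")
    _, epath = pairs[0]
    if "|" in right:
        system, _, code = right.partition("|")
        return ElementConstraint(path=epath, fixed_value=code.strip(),
                                 fixed_system=system.strip())
    return ElementConstraint(path=epath, fixed_value=right)


# ---------------------------------------------------------------------------
# value sets

@dataclass
class LocalCode:
    code: str
    display: str


@dataclass
class CodeSystemDefinition:
    """A generated CodeSystem holding locally assigned answer codes."""

    name: str
    id: str
    canonical_url: str
    codes: list[LocalCode] = dc_field(default_factory=list)


@dataclass
class ValueSetDefinition:
    name: str
    id: str
    canonical_url: str
    codings: list[Coding] = dc_field(default_factory=list)
    content_hash: str = ""
    local_code_system: CodeSystemDefinition | None = None

    def __post_init__(self) -> None:
        if not self.codings:
            raise EmptyValueSetError(self.name)
        if len({c.key() for c in self.codings}) != len(self.codings):
            raise ValueError(f"value set {self.name!r} has duplicate codings")
        if not self.content_hash:
            self.content_hash = content_hash(self.codings)


def content_hash(codings: Iterable[Coding]) -> str:
    """Digest of the (system, code) multiset; equal hash ⇔ same code set."""
    keys = sorted(c.key() for c in codings)
    return hashlib.sha256(json.dumps(keys).encode()).hexdigest()[:16]


class ValueSetRegistry:
    """Content-addressed store of value sets; a code multiset is registered
    once and reused by every later request with the same content."""

    def __init__(self, canonical_base: str):
        self.canonical_base = canonical_base.rstrip("/")
        self._by_hash: dict[str, ValueSetDefinition] = {}
        self._ref_counts: dict[str, int] = {}
        self._taken_ids: set[str] = set()

    def register(self, name: str, codings: list[Coding],
                 local_codes: list[LocalCode] | None = None,
                 refs: int = 1) -> ValueSetDefinition:
        """Return the registered value set for this code multiset, creating
        it (and its local CodeSystem, if any options needed local codes) on
        first sight."""
        h = content_hash(codings)
        if h in self._by_hash:
            vs = self._by_hash[h]
        else:
            base_id = slugify(name)
            vs_id, n = base_id, 2
            while vs_id in self._taken_ids:  # same name, different content
                vs_id, n = f"{base_id}-{n}", n + 1
            self._taken_ids.add(vs_id)
            cs = None
            if local_codes:
                cs = CodeSystemDefinition(
                    name=f"{name} codes",
                    id=f"{vs_id}-cs",
                    canonical_url=f"{self.canonical_base}/CodeSystem/{vs_id}-cs",
                    codes=list(local_codes))
            vs = ValueSetDefinition(
                name=name, id=vs_id,
                canonical_url=f"{self.canonical_base}/ValueSet/{vs_id}",
                codings=codings, local_code_system=cs)
            self._by_hash[h] = vs
            self._ref_counts[vs.id] = 0
        self._ref_counts[vs.id] += refs
        return vs

    @property
    def value_sets(self) -> list[ValueSetDefinition]:
        return sorted(self._by_hash.values(), key=lambda v: v.id)

    def reference_count(self, vs_id: str) -> int:
        return self._ref_counts.get(vs_id, 0)

    def __len__(self) -> int:
        return len(self._by_hash)


def _local_system_uri(canonical_base: str, vs_name: str) -> str:
    return f"{canonical_base.rstrip('/')}/CodeSystem/{slugify(vs_name)}-cs"


def build_value_set(entries: list[DictionaryEntry],
                    registry: ValueSetRegistry,
                    term_registry: CodeSystemRegistry | None = None,
                    name: str | None = None) -> ValueSetDefinition:
    """Resolve one answer-concept set shared by ``entries`` into a value set.

    Resolution per option: a parsed terminology coding whose display matches
    the option label; else, when the entry declares a FHIR code system, a
    code in that system (slug of the label, as FHIR codes are lowercase
    tokens); else a locally assigned code in a generated CodeSystem.
    Entries without answer options contribute their parsed codings directly
    (the condition/medication patterns).  Identical content is returned from
    the registry, never duplicated.
    """
    term_registry = term_registry or CodeSystemRegistry()
    first = entries[0]
    vs_name = name or (first.value_set_binding
                       if first.value_set_binding and "://" not in first.value_set_binding
                       else f"{slugify(first.label)}-values")

    codings: list[Coding] = []
    local_codes: list[LocalCode] = []
    seen: set[tuple[str, str]] = set()

    def add(c: Coding) -> None:
        if c.key() not in seen:
            seen.add(c.key())
            codings.append(c)

    for entry in entries:
        parsed, _ = parse_code_text(entry.semantic_code_text, term_registry)
        by_display = {(c.display or "").casefold(): c for c in parsed}
        if entry.answer_options:
            for option in entry.answer_options:
                hit = by_display.get(option.casefold())
                if hit is not None:
                    add(hit)
                elif entry.fhir_code_system:
                    add(Coding(system=entry.fhir_code_system,
                               code=slugify(option), display=option))
                else:
                    code = slugify(option)
                    add(Coding(system=_local_system_uri(registry.canonical_base, vs_name),
                               code=code, display=option))
                    if code not in {lc.code for lc in local_codes}:
                        local_codes.append(LocalCode(code=code, display=option))
        else:
            for c in parsed:
                add(c)
            if not parsed and entry.fhir_code:
                add(Coding(system=entry.fhir_code_system, code=entry.fhir_code))
    if not codings:
        raise EmptyValueSetError(vs_name)
    return registry.register(vs_name, codings, local_codes, refs=len(entries))


# ---------------------------------------------------------------------------
# profiles

@dataclass
class ProfileDefinition:
    """A named StructureDefinition differential over one base resource."""

    name: str
    id: str
    resource_type: str
    base: str
    constraints: list[ElementConstraint] = dc_field(default_factory=list)
    program: str = "core"
    description: str = ""

    def __post_init__(self) -> None:
        if self.resource_type not in supported_resources():
            raise PathError(self.resource_type)


def build_profile(group: list[DictionaryEntry],
                  value_set_urls: dict[str, str] | None = None) -> ProfileDefinition:
    """Assemble the profile for entries sharing one Target Profile ID.

    One constraint per mapped element path; fixed attributes appended;
    bindings attached with each entry's strength.  ``value_set_urls`` maps an
    entry's local value-set name to the canonical URL the registry assigned
    (absolute URLs in the binding column are used verbatim).  Mixed resource
    types within a group are a :class:`GroupingError`.
    """
    if not group:
        raise ValueError("empty profile group")
    value_set_urls = value_set_urls or {}
    name = group[0].target_profile_id or group[0].label
    rtypes: dict[str, list[str]] = {}
    parsed_paths: list[tuple[DictionaryEntry, list[tuple[str, str]]]] = []
    for e in group:
        pairs = parse_fhir_path(e.fhir_resource_path)
        parsed_paths.append((e, pairs))
        for rtype, _ in pairs:
            rtypes.setdefault(rtype, []).append(e.element_id)
    if len(rtypes) > 1:
        raise GroupingError(name, [e.element_id for e in group], list(rtypes))
    resource_type = next(iter(rtypes))

    constraints: list[ElementConstraint] = []
    seen_keys: set[tuple] = set()

    def push(c: ElementConstraint) -> None:
        if c.sort_key() not in seen_keys:
            seen_keys.add(c.sort_key())
            constraints.append(c)

    for e, pairs in parsed_paths:
        binding_url = ""
        if e.value_set_binding:
            binding_url = (e.value_set_binding if "://" in e.value_set_binding
                           else value_set_urls.get(e.value_set_binding, ""))
        for i, (_, epath) in enumerate(pairs):
            if not epath:
                continue  # profile-level mapping: root only
            meta = element_meta(resource_type, epath)
            c = ElementConstraint(path=epath,
                                  is_extension=meta is None,
                                  description=e.label)
            if meta is None:
                c.type = "Extension"
            if i == 0 and binding_url and (meta is None or meta.bindable):
                c.binding_url = binding_url
                c.binding_strength = e.binding_strength
            elif i == 0 and e.fhir_code and not binding_url:
                c.fixed_value = e.fhir_code
                c.fixed_system = e.fhir_code_system
            push(c)
        for attr_text in e.additional_fhir_attributes:
            push(parse_fixed_attribute(attr_text))

    constraints.sort(key=lambda c: c.sort_key())
    programs = {e.program for e in group}
    return ProfileDefinition(
        name=name,
        id=slugify(name),
        resource_type=resource_type,
        base=base_canonical(resource_type),
        constraints=constraints,
        program="core" if len(programs) > 1 else next(iter(programs)),
        description=group[0].description)


# ---------------------------------------------------------------------------
# emission

@dataclass
class EmitConfig:
    """Knobs governing artifact emission."""

    canonical_base: str = "http://example.org/fhir/dak"
    version: str = "0.1.0"
    publisher: str = ""
    fhir_version: str = "4.0.1"
    #: emit min=1 on constrained elements instead of the default min=0
    mandatory_elements: bool = False
    #: pattern-style (open) fixations; False switches to exact fixed[x]
    use_pattern: bool = True


def _fhir_name(display: str) -> str:
    return "".join(p.capitalize() for p in slugify(display).split("-"))


def _fixation_key(resource_type: str, epath: str, prefix: str) -> str:
    meta = element_meta(resource_type, epath)
    primary = meta.types[0] if meta and meta.types else "string"
    if primary[0].islower():
        primary = primary[0].upper() + primary[1:]
    return prefix + primary


def emit_structure_definition(profile: ProfileDefinition,
                              config: EmitConfig | None = None) -> dict:
    """Render a profile as a FHIR R4 StructureDefinition (differential only).

    Output is byte-stable across runs for equal inputs: key order is fixed
    and elements are pre-sorted by path.
    """
    config = config or EmitConfig()
    rtype = profile.resource_type
    elements: list[dict] = [{"id": rtype, "path": rtype}]
    for c in profile.constraints:
        if c.is_extension:
            slug = slugify(c.description or c.path)
            el: dict = {
                "id": f"{rtype}.extension:{slug}",
                "path": f"{rtype}.extension",
                "sliceName": slug,
                "short": c.description or c.path.replace(".", " "),
                "min": 1 if config.mandatory_elements else 0,
                "type": [{"code": "Extension"}],
                "mustSupport": True,
            }
            elements.append(el)
            continue
        el = {"id": f"{rtype}.{c.path}", "path": f"{rtype}.{c.path}"}
        if c.description:
            el["short"] = c.description
        meta = element_meta(rtype, c.path)
        wanted_min = c.min if c.min is not None else (1 if config.mandatory_elements else 0)
        el["min"] = max(wanted_min, meta.min if meta else 0)  # never below base
        if c.max:
            el["max"] = c.max
        if c.type:
            el["type"] = [{"code": c.type}]
        if c.fixed_value:
            prefix = "pattern" if config.use_pattern else "fixed"
            key = _fixation_key(rtype, c.path, prefix)
            if key.endswith("CodeableConcept"):
                coding: dict = {"code": c.fixed_value}
                if c.fixed_system:
                    coding = {"system": c.fixed_system, "code": c.fixed_value}
                el[key] = {"coding": [coding]}
            elif key.endswith("Coding"):
                el[key] = ({"system": c.fixed_system, "code": c.fixed_value}
                           if c.fixed_system else {"code": c.fixed_value})
            else:
                el[key] = c.fixed_value
        if c.binding_url:
            el["binding"] = {"strength": c.binding_strength,
                             "valueSet": c.binding_url}
        if c.must_support:
            el["mustSupport"] = True
        elements.append(el)

    doc = {
        "resourceType": "StructureDefinition",
        "id": profile.id,
        "url": f"{config.canonical_base.rstrip('/')}/StructureDefinition/{profile.id}",
        "version": config.version,
        "name": _fhir_name(profile.name),
        "title": profile.name,
        "status": "draft",
        "fhirVersion": config.fhir_version,
        "kind": "resource",
        "abstract": False,
        "type": rtype,
        "baseDefinition": profile.base,
        "derivation": "constraint",
        "differential": {"element": elements},
    }
    if config.publisher:
        doc["publisher"] = config.publisher
    if profile.description:
        doc["description"] = profile.description
    return doc


def emit_value_set(vs: ValueSetDefinition, config: EmitConfig | None = None) -> dict:
    config = config or EmitConfig()
    by_system: dict[str, list[Coding]] = {}
    for c in vs.codings:
        by_system.setdefault(c.system, []).append(c)
    includes = []
    for system in sorted(by_system):
        concepts = []
        for c in by_system[system]:
            concept = {"code": c.code}
            if c.display:
                concept["display"] = c.display
            concepts.append(concept)
        includes.append({"system": system, "concept": concepts})
    return {
        "resourceType": "ValueSet",
        "id": vs.id,
        "url": vs.canonical_url,
        "version": config.version,
        "name": _fhir_name(vs.name),
        "title": vs.name,
        "status": "draft",
        "compose": {"include": includes},
    }


def emit_code_system(cs: CodeSystemDefinition,
                     config: EmitConfig | None = None) -> dict:
    config = config or EmitConfig()
    return {
        "resourceType": "CodeSystem",
        "id": cs.id,
        "url": cs.canonical_url,
        "version": config.version,
        "name": _fhir_name(cs.name),
        "title": cs.name,
        "status": "draft",
        "content": "complete",
        "concept": [{"code": lc.code, "display": lc.display} for lc in cs.codes],
    }


def to_json_bytes(doc: dict) -> bytes:
    """Canonical serialization used for every emitted artifact."""
    return (json.dumps(doc, indent=2, ensure_ascii=False) + "\n").encode("utf-8")
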