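"""Semantic-terminology handling: codings, the code-system registry, and the
free-text multi-code parser.

Source dictionaries carry terminology codes in a single free-text column,
one ``Label: code (maps to display)`` segment per code, segments separated by
newlines or semicolons.  Codes are printed for humans — SNOMED concept ids
with thousands separators, LOINC check-digit hyphens typeset as en-dashes —
so every code is normalized to a machine token before use.

Validation here is purely syntactic (per-system format rules); no terminology
server is consulted and code *existence* is never checked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import NormalizationError, UnresolvedSystemError

# Canonical URIs of the four mapping terminologies.
SNOMED_URI = "http://snomed.info/sct"
LOINC_URI = "http://loinc.org"
ICD10_URI = "http://hl7.org/fhir/sid/icd-10"
RXNORM_URI = "http://www.nlm.nih.gov/research/umls/rxnorm"

# Unicode dash variants occasionally produced by word processors / PDF
# extraction; all canonicalized to ASCII hyphen inside codes.
_DASHES = "‐‑‒–—―−"

# Per-system syntactic format rules.  A system absent from this table falls
# back to the generic FHIR token rule (no whitespace).
_FORMAT_RULES: dict[str, re.Pattern[str]] = {
    SNOMED_URI: re.compile(r"^\d{6,18}$"),
    RXNORM_URI: re.compile(r"^\d+$"),
    LOINC_URI: re.compile(r"^\d{1,7}-\d$"),
    ICD10_URI: re.compile(r"^[A-Z]\d{2}(\.\d{1,4})?$"),
}
_TOKEN_RULE = re.compile(r"^\S+$")


@dataclass(frozen=True)
class Coding:
    """A (system, code, display) triple from any terminology."""

    system: str
    code: str
    display: str | None = None

    def key(self) -> tuple[str, str]:
        return (self.system, self.code)


@dataclass(frozen=True)
class ParseIssue:
    """A non-fatal problem found while parsing a multi-code text cell."""

    segment: str
    reason: str


@dataclass
class CodeSystemRegistry:
    """Case-insensitive label → canonical-URI map with per-system format rules.

    The built-in registry covers SNOMED CT, LOINC, ICD-10 and RxNorm (with
    common label spellings) and passes absolute URIs through unchanged, so
    FHIR code systems such as ``http://hl7.org/fhir/administrative-gender``
    need no registration.  Extra ``label → URI`` pairs and format regexes can
    be supplied from the run config.
    """

    extra_systems: dict[str, str] = field(default_factory=dict)
    extra_formats: dict[str, str] = field(default_factory=dict)

    _BUILTIN = {
        "snomed": SNOMED_URI,
        "snomed ct": SNOMED_URI,
        "snomed-ct": SNOMED_URI,
        "snomedct": SNOMED_URI,
        "sct": SNOMED_URI,
        "loinc": LOINC_URI,
        "icd-10": ICD10_URI,
        "icd10": ICD10_URI,
        "rxnorm": RXNORM_URI,
    }

    def resolve(self, label: str) -> str:
        """Resolve a system label (or pass through an absolute URI).

        Raises :class:`UnresolvedSystemError` for unknown labels.
        """
        text = label.strip()
        if re.match(r"^https?://", text) or text.startswith("urn:"):
            return text
        key = text.lower()
        if key in self._BUILTIN:
            return self._BUILTIN[key]
        for extra_label, uri in self.extra_systems.items():
            if extra_label.lower() == key:
                return uri
        raise UnresolvedSystemError(label)

    def known_uris(self) -> set[str]:
        return set(self._BUILTIN.values()) | set(self.extra_systems.values())

    def format_rule(self, system: str) -> re.Pattern[str]:
        if system in self.extra_formats:
            return re.compile(self.extra_formats[system])
        return _FORMAT_RULES.get(system, _TOKEN_RULE)


DEFAULT_REGISTRY = CodeSystemRegistry()


def normalize_code(system: str, raw: str) -> str:
    """Normalize a printed code to a machine token.

    Strips surrounding whitespace, canonicalizes dash variants to ASCII
    hyphen, and removes thousands separators from all-digit grouped inputs
    (``"14,302,001"`` → ``"14302001"``).  Anything else is returned trimmed.
    Idempotent by construction.
    """
    token = raw.strip()
    for dash in _DASHES:
        token = token.replace(dash, "-")
    token = re.sub(r"\s+", "", token)
    if re.fullmatch(r"\d{1,3}(,\d{3})+", token):
        token = token.replace(",", "")
    if not token:
        raise NormalizationError(raw)
    return token


_CANONICAL_LABELS = {SNOMED_URI: "SNOMED", LOINC_URI: "LOINC",
                     ICD10_URI: "ICD-10", RXNORM_URI: "RxNorm"}


def label_for_uri(uri: str, registry: CodeSystemRegistry | None = None) -> str | None:
    """Preferred human label for a registered system URI (None if unknown)."""
    if uri in _CANONICAL_LABELS:
        return _CANONICAL_LABELS[uri]
    registry = registry or DEFAULT_REGISTRY
    for label, candidate in registry.extra_systems.items():
        if candidate == uri:
            return label
    return None


def format_segment(coding: Coding,
                   registry: CodeSystemRegistry | None = None) -> str | None:
    """Render a coding back into the ``Label: code (maps to display)`` text
    form, or None when its system has no registered label."""
    label = label_for_uri(coding.system, registry)
    if label is None:
        return None
    text = f"{label}: {coding.code}"
    if coding.display:
        text += f" (maps to {coding.display})"
    return text


def resolve_system(label: str, registry: CodeSystemRegistry | None = None) -> str:
    """Module-level convenience wrapper over :meth:`CodeSystemRegistry.resolve`."""
    return (registry or DEFAULT_REGISTRY).resolve(label)


def validate_coding(coding: Coding,
                    registry: CodeSystemRegistry | None = None) -> list[str]:
    """Syntactic validation of a coding against its system's format rule.

    Returns a list of human-readable issues; empty means the coding is
    well-formed.  Never performs a network lookup.
    """
    registry = registry or DEFAULT_REGISTRY
    issues: list[str] = []
    if not coding.code:
        issues.append("empty code")
        return issues
    if not (re.match(r"^https?://", coding.system) or coding.system.startswith("urn:")):
        issues.append(f"system {coding.system!r} is not an absolute URI")
    rule = registry.format_rule(coding.system)
    if not rule.match(coding.code):
        issues.append(
            f"code {coding.code!r} does not match the format rule "
            f"{rule.pattern!r} for system {coding.system}")
    return issues


# One "Label: code (maps to display)" segment; the display clause is optional
# and the code may contain printed separators (commas, dashes).
_SEGMENT_RE = re.compile(
    r"^\s*(?P<label>[^:]+?)\s*:\s*(?P<code>[^()]+?)\s*"
    r"(?:\(\s*(?:maps\s+to\s+)?(?P<display>.*?)\s*\))?\s*$")


def split_segments(text: str) -> list[str]:
    """Split a multi-code cell into non-empty segments (newline/semicolon)."""
    return [s for s in re.split(r"[\n;]+", text) if s.strip()]


def parse_code_text(text: str,
                    registry: CodeSystemRegistry | None = None,
                    ) -> tuple[list[Coding], list[ParseIssue]]:
    """Parse a free-text terminology cell into structured codings.

    Each segment yields either one :class:`Coding` (system resolved through
    the registry, code normalized) or one :class:`ParseIssue`; issues are
    collected, never fatal, and segment order is preserved, so
    ``len(codings) + len(issues) == number of non-empty segments``.
    """
    registry = registry or DEFAULT_REGISTRY
    codings: list[Coding] = []
    issues: list[ParseIssue] = []
    for segment in split_segments(text or ""):
        m = _SEGMENT_RE.match(segment)
        if not m:
            issues.append(ParseIssue(segment.strip(), "not of the form 'Label: code (maps to display)'"))
            continue
        try:
            system = registry.resolve(m.group("label"))
        except UnresolvedSystemError:
            issues.append(ParseIssue(segment.strip(),
                                     f"unknown system label {m.group('label').strip()!r}"))
            continue
        try:
            code = normalize_code(system, m.group("code"))
        except NormalizationError:
            issues.append(ParseIssue(segment.strip(), "empty code after normalization"))
            continue
        codings.append(Coding(system=system, code=code, display=m.group("display")))
    return codings, issues
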