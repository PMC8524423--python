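"""Deterministic naming helpers shared across the compiler."""

from __future__ import annotations

import re
import unicodedata

_SLUG_RE = re.compile(r"[^a-z0-9]+")


def slugify(text: str) -> str:
    """Lowercase-hyphen slug of a display name.

    Punctuation (including parentheses) is dropped, runs of
    non-alphanumerics collapse to a single hyphen:
    ``"WHO-Core Observation (HIV Status)"`` → ``"who-core-observation-hiv-status"``.
    """
    text = unicodedata.normalize("NFKD", text)
    text = text.encode("ascii", "ignore").decode("ascii")
    return _SLUG_RE.sub("-", text.lower()).strip("-")


def normalize_label(text: str) -> str:
    """Case-folded, whitespace-collapsed form of a label (duplicate key)."""
    return " ".join(text.split()).casefold()
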