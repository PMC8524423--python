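"""Run configuration: one validated object driving the whole pipeline.

Loaded from YAML (or built programmatically); every knob has a documented
default so a bare ``RunConfig()`` compiles the fixtures end to end.  The
FHIR version is pinned to R4 4.0.1 — the only version the vendored base
metadata describes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .conformance import EmitConfig
from .dictionary import ColumnDialect
from .remodel import RemodelConfig
from .terminology import CodeSystemRegistry


class RunConfig(BaseModel):
    #: canonical URL prefix for every generated conformance resource
    canonical_base: str = "http://example.org/fhir/dak"
    ig_version: str = "0.1.0"
    fhir_version: Literal["4.0.1"] = "4.0.1"
    publisher: str = ""
    dialect: ColumnDialect = Field(default_factory=ColumnDialect)
    #: element_id -> remodel pattern name, overriding the rule table
    remodel_overrides: dict[str, str] = Field(default_factory=dict)
    #: extra terminology label -> URI registrations
    extra_systems: dict[str, str] = Field(default_factory=dict)
    #: extra system URI -> code format regex
    extra_formats: dict[str, str] = Field(default_factory=dict)
    output_dir: str = "out"
    overwrite: bool = False
    allow_partial: bool = False
    #: constrained elements get min=1 instead of must-support min=0
    mandatory_elements: bool = False
    #: pattern-style (open) fixations instead of exact fixed values
    use_pattern: bool = True
    log_level: str = "INFO"
    seed: int = 0

    @field_validator("canonical_base")
    @classmethod
    def _absolute(cls, v: str) -> str:
        if not (v.startswith("http://") or v.startswith("https://")):
            raise ValueError("canonical_base must be an absolute http(s) URL")
        return v.rstrip("/")

    def term_registry(self) -> CodeSystemRegistry:
        return CodeSystemRegistry(extra_systems=dict(self.extra_systems),
                                  extra_formats=dict(self.extra_formats))

    def remodel_config(self) -> RemodelConfig:
        return RemodelConfig(overrides=dict(self.remodel_overrides),  # type: ignore[arg-type]
                             registry=self.term_registry())

    def emit_config(self) -> EmitConfig:
        return EmitConfig(canonical_base=self.canonical_base,
                          version=self.ig_version,
                          publisher=self.publisher,
                          fhir_version=self.fhir_version,
                          mandatory_elements=self.mandatory_elements,
                          use_pattern=self.use_pattern)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; ``None`` yields the documented defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)
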