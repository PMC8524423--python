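"""End-to-end compilation: dictionary → remodel → conformance → guides.

This is the programmatic equivalent of the CLI's ``generate`` command and
the single entry point tests and scripts use.  The compile path contains no
randomness: equal dictionaries produce byte-identical artifact trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .assembler import IGPackage, assign_guides, emit_ig
from .config import RunConfig
from .conformance import ValueSetRegistry, build_profile, build_value_set
from .dictionary import (CoverageReport, DataDictionary, DictionaryEntry,
                         completeness_report)
from .fhir_base import ValidationIssue, error_issues, validate_structuredef
from .conformance import emit_structure_definition
from .naming import slugify
from .remodel import classify_entry, remodel


@dataclass
class CompileResult:
    packages: list[IGPackage]
    coverage: CoverageReport
    remodeled: DataDictionary
    registry: ValueSetRegistry
    validation_issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not error_issues(self.validation_issues) and \
            self.coverage.coverage_fraction == 1.0


def _needs_local_value_set(entry: DictionaryEntry) -> bool:
    if entry.value_set_binding and "://" not in entry.value_set_binding:
        return True
    return entry.answer_type in ("choice", "multi-choice") and bool(entry.answer_options)


def compile_dictionary(dictionary: DataDictionary,
                       config: RunConfig | None = None) -> CompileResult:
    """Run the full pipeline over a consolidated master dictionary.

    Steps: classify and remodel every entry; build (and deduplicate) answer
    value sets; group entries by target profile and build differentials;
    partition profiles and value sets into the Core/FP/STI guides; validate
    every emitted StructureDefinition; and produce the completeness report.
    """
    config = config or RunConfig()
    remodel_cfg = config.remodel_config()
    term_registry = config.term_registry()

    remodeled_entries: list[DictionaryEntry] = []
    for entry in dictionary.entries:
        rule = classify_entry(entry, remodel_cfg)
        remodeled_entries.append(remodel(entry, rule, remodel_cfg))
    remodeled = DataDictionary(entries=remodeled_entries,
                               source_sheets=dictionary.source_sheets,
                               duplicate_groups=dictionary.duplicate_groups)

    # assign per-question value-set names to bindable entries that lack one
    for e in remodeled.entries:
        if not e.value_set_binding and _needs_local_value_set(e):
            e.value_set_binding = f"{slugify(e.label)}-values"

    # build value sets, grouped by local binding name (shared sets build once)
    vs_registry = ValueSetRegistry(config.canonical_base)
    by_name: dict[str, list[DictionaryEntry]] = {}
    for e in remodeled.entries:
        if e.value_set_binding and "://" not in e.value_set_binding:
            by_name.setdefault(e.value_set_binding, []).append(e)
    value_set_urls: dict[str, str] = {}
    for name, group in by_name.items():
        vs = build_value_set(group, vs_registry, term_registry, name=name)
        value_set_urls[name] = vs.canonical_url

    # profiles, grouped by target profile id
    groups: dict[str, list[DictionaryEntry]] = {}
    for e in remodeled.entries:
        if not e.fhir_resource_path.strip() or not e.target_profile_id:
            continue
        groups.setdefault(e.target_profile_id, []).append(e)
    profiles = [build_profile(group, value_set_urls)
                for group in groups.values()]

    packages = assign_guides(profiles, vs_registry.value_sets,
                             config.canonical_base)
    coverage = completeness_report(remodeled, packages)

    issues: list[ValidationIssue] = []
    emit_cfg = config.emit_config()
    for pkg in packages:
        for prof in pkg.profiles:
            issues.extend(validate_structuredef(
                emit_structure_definition(prof, emit_cfg)))

    return CompileResult(packages=packages, coverage=coverage,
                         remodeled=remodeled, registry=vs_registry,
                         validation_issues=issues)


def emit_all(result: CompileResult, outdir: str | Path,
             config: RunConfig | None = None,
             overwrite: bool = False) -> list[Path]:
    """Write every guide's source tree; returns all files written."""
    config = config or RunConfig()
    written: list[Path] = []
    for pkg in result.packages:
        written.extend(emit_ig(pkg, outdir, config.emit_config(),
                               overwrite=overwrite))
    return written
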