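"""The master data-dictionary model: one row per clinical data element,
carrying the FHIR-resource and semantic-terminology mapping attributes.

Source dictionaries arrive as workflow-oriented multi-sheet workbooks in
which the same concept can appear on several sheets (once per point in the
care continuum).  :func:`consolidate` flattens them into a single master
dictionary, merging rows that are identical under the duplicate key
(normalized label + FHIR resource path) and flagging — never merging —
near-duplicates whose mappings disagree.

I/O is plain UTF-8 CSV/TSV with a declared header row; the column-name →
field mapping is configurable through :class:`ColumnDialect`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import DuplicateIdError, MissingColumnError
from .naming import normalize_label, slugify

AnswerType = Literal["boolean", "choice", "multi-choice", "quantity",
                     "date", "datetime", "text"]
BindingStrength = Literal["required", "extensible", "preferred", "example"]
Program = Literal["core", "fp", "sti"]
ValidationStatus = Literal["unmapped", "mapped", "validated"]

#: Multi-valued CSV cells (answer options, fixed attributes) use this separator.
LIST_SEP = "|"


class DictionaryEntry(BaseModel):
    """One data element with its full set of mapping attributes."""

    element_id: str
    label: str
    description: str = ""
    answer_type: AnswerType = "text"
    answer_options: list[str] = Field(default_factory=list)
    fhir_resource_path: str = ""
    additional_fhir_attributes: list[str] = Field(default_factory=list)
    target_profile_id: str = ""
    value_set_binding: str = ""
    binding_strength: BindingStrength = "required"
    fhir_code_system: str = ""
    fhir_code: str = ""
    semantic_code_text: str = ""
    program: Program = "core"
    notes: str = ""
    validation_status: ValidationStatus = "unmapped"
    # Reversible snapshot of the pre-remodel UI view; set by remodel().
    ui_metadata: Optional[dict] = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "DictionaryEntry":
        if not self.element_id:
            raise ValueError("element_id must be non-empty")
        if self.fhir_code and not self.fhir_code_system:
            raise ValueError(
                f"entry {self.element_id!r}: fhir_code without fhir_code_system")
        if self.answer_type in ("choice", "multi-choice") and \
                not self.answer_options and not self.value_set_binding:
            raise ValueError(
                f"entry {self.element_id!r}: {self.answer_type} answer needs "
                f"answer_options or a value_set_binding")
        return self

    def ui_view_fields(self) -> tuple[str, str, tuple[str, ...]]:
        """The (label, answer_type, options) triple the UI projection compares."""
        return (self.label, self.answer_type, tuple(self.answer_options))


class DuplicateGroup(BaseModel):
    """Element ids judged to denote the same concept.

    ``exact`` groups were merged into one entry (the first id survives);
    ``near`` groups share a normalized label but disagree on mapping and are
    kept separate for human review.
    """

    kind: Literal["exact", "near"]
    element_ids: list[str]

    @model_validator(mode="after")
    def _check(self) -> "DuplicateGroup":
        if len(self.element_ids) < 2:
            raise ValueError("duplicate groups have size >= 2")
        return self


class DataDictionary(BaseModel):
    entries: list[DictionaryEntry] = Field(default_factory=list)
    source_sheets: list[str] = Field(default_factory=list)
    duplicate_groups: list[DuplicateGroup] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "DataDictionary":
        ids = [e.element_id for e in self.entries]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dupes: list[str] = []
            for i in ids:
                if i in seen:
                    dupes.append(i)
                seen.add(i)
            raise DuplicateIdError(sorted(set(dupes)))
        grouped: set[str] = set()
        for g in self.duplicate_groups:
            for eid in g.element_ids:
                if eid in grouped:
                    raise ValueError(f"element_id {eid!r} in two duplicate groups")
                grouped.add(eid)
        return self

    def by_id(self, element_id: str) -> DictionaryEntry:
        for e in self.entries:
            if e.element_id == element_id:
                return e
        raise KeyError(element_id)


class ColumnDialect(BaseModel):
    """Header-name → field mapping and delimiter for dictionary tables."""

    delimiter: str = ","
    columns: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    #: columns that must be present in the header
    mandatory: list[str] = Field(default_factory=lambda: [
        "label", "fhir_resource_path", "target_profile_id"])


DEFAULT_COLUMNS: dict[str, str] = {
    "element_id": "Element ID",
    "label": "Label",
    "description": "Description",
    "answer_type": "Answer Type",
    "answer_options": "Answer Options",
    "fhir_resource_path": "FHIR Resource",
    "additional_fhir_attributes": "Additional FHIR Attributes",
    "target_profile_id": "Target Profile ID",
    "value_set_binding": "Value Set Binding",
    "binding_strength": "Binding Strength",
    "fhir_code_system": "FHIR Code System",
    "fhir_code": "FHIR Code",
    "semantic_code_text": "Semantic Terminology Code",
    "program": "Program",
    "notes": "Notes",
    "validation_status": "Validation Status",
}

_LIST_FIELDS = {"answer_options", "additional_fhir_attributes"}


def _dialect_for(path: str | Path, dialect: ColumnDialect | None) -> ColumnDialect:
    if dialect is not None:
        return dialect
    d = ColumnDialect()
    if str(path).lower().endswith((".tsv", ".tab")):
        d.delimiter = "\t"
    return d


def derive_element_id(program: str, label: str, taken: set[str]) -> str:
    """Deterministic id: slug of program + label, numeric disambiguator."""
    base = slugify(f"{program} {label}") or "entry"
    eid, n = base, 2
    while eid in taken:
        eid = f"{base}-{n}"
        n += 1
    return eid


def entries_from_frame(frame: pd.DataFrame, dialect: ColumnDialect,
                       source: str = "") -> list[DictionaryEntry]:
    """Map a raw table to entries; unknown columns are preserved in notes."""
    col_for = {field: col for field, col in dialect.columns.items()
               if col in frame.columns}
    for field in dialect.mandatory:
        if field not in col_for:
            raise MissingColumnError(dialect.columns[field], source)
    known_cols = set(col_for.values())
    extra_cols = [c for c in frame.columns if c not in known_cols]

    entries: list[DictionaryEntry] = []
    taken: set[str] = set()
    for _, row in frame.iterrows():
        values: dict[str, object] = {}
        for field, col in col_for.items():
            cell = str(row[col]).strip() if not pd.isna(row[col]) else ""
            if field in _LIST_FIELDS:
                values[field] = [p.strip() for p in cell.split(LIST_SEP) if p.strip()]
            elif cell:
                values[field] = cell
        if not any(v for v in values.values()):
            continue  # blank row
        extra_notes = "; ".join(f"{c}: {str(row[c]).strip()}"
                                for c in extra_cols
                                if not pd.isna(row[c]) and str(row[c]).strip())
        if extra_notes:
            values["notes"] = "; ".join(x for x in [values.get("notes", ""), extra_notes] if x)
        if "ui_metadata" in frame.columns and not pd.isna(row["ui_metadata"]) \
                and str(row["ui_metadata"]).strip():
            values["ui_metadata"] = json.loads(str(row["ui_metadata"]))
        if not values.get("element_id"):
            values["element_id"] = derive_element_id(
                str(values.get("program", "core")), str(values.get("label", "")), taken)
        taken.add(str(values["element_id"]))
        entries.append(DictionaryEntry(**values))
    return entries


def read_dictionary(path: str | Path,
                    dialect: ColumnDialect | None = None) -> DataDictionary:
    """Read one delimited table into a :class:`DataDictionary`.

    Raises :class:`MissingColumnError` when a mandatory column is absent and
    :class:`DuplicateIdError` when element ids repeat.
    """
    path = Path(path)
    dialect = _dialect_for(path, dialect)
    frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str,
                        keep_default_na=False)
    frame = frame.replace("", pd.NA)
    entries = entries_from_frame(frame, dialect, source=str(path))
    return DataDictionary(entries=entries, source_sheets=[path.stem])


def read_workbook(path: str | Path,
                  dialect: ColumnDialect | None = None) -> dict[str, DataDictionary]:
    """Optional XLSX adapter: one dictionary fragment per worksheet, keyed by
    sheet name, ready for :func:`consolidate`.  Requires openpyxl."""
    dialect = dialect or ColumnDialect()
    frames = pd.read_excel(path, sheet_name=None, dtype=str)
    out: dict[str, DataDictionary] = {}
    for sheet_name, frame in frames.items():
        entries = entries_from_frame(frame, dialect,
                                     source=f"{path}#{sheet_name}")
        out[sheet_name] = DataDictionary(entries=entries,
                                         source_sheets=[sheet_name])
    return out


def write_dictionary(dictionary: DataDictionary, path: str | Path,
                     dialect: ColumnDialect | None = None) -> None:
    """Write the dictionary back out; inverse of :func:`read_dictionary`."""
    path = Path(path)
    dialect = _dialect_for(path, dialect)
    rows = []
    any_meta = any(e.ui_metadata for e in dictionary.entries)
    for e in dictionary.entries:
        row = {}
        for field, col in dialect.columns.items():
            v = getattr(e, field)
            row[col] = LIST_SEP.join(v) if field in _LIST_FIELDS else v
        if any_meta:
            row["ui_metadata"] = json.dumps(e.ui_metadata) if e.ui_metadata else ""
        rows.append(row)
    cols = list(dialect.columns.values()) + (["ui_metadata"] if any_meta else [])
    frame = pd.DataFrame(rows, columns=cols)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=dialect.delimiter, index=False)


def _merge_key(e: DictionaryEntry) -> tuple[str, str]:
    return (normalize_label(e.label), " ".join(e.fhir_resource_path.split()))


def consolidate(sheets: dict[str, DataDictionary] | Iterable[tuple[str, DataDictionary]],
                ) -> DataDictionary:
    """Flatten workflow sheets into one master dictionary.

    Rows identical under the duplicate key (normalized label + FHIR resource
    path) *and* agreeing on target profile are merged into the first
    occurrence; rows sharing only a normalized label, or sharing the key but
    disagreeing on target profile, are flagged as near-duplicates and kept.
    Duplicate groups already present on the inputs are carried forward, which
    makes the operation idempotent.
    """
    items = list(sheets.items()) if isinstance(sheets, dict) else list(sheets)

    # collect rows with provenance; re-id on collision across sheets
    taken: set[str] = set()
    rows: list[DictionaryEntry] = []
    carried: list[DuplicateGroup] = []
    source_sheets: list[str] = []
    for sheet_name, fragment in items:
        source_sheets.extend(fragment.source_sheets or [sheet_name])
        carried.extend(fragment.duplicate_groups)
        for e in fragment.entries:
            e = e.model_copy(deep=True)
            if e.element_id in taken:
                e.element_id = derive_element_id(e.program, f"{e.label} {sheet_name}", taken)
            taken.add(e.element_id)
            if sheet_name and "sheet: " not in (e.notes or ""):
                # first consolidation records origin; re-runs keep it stable
                e.notes = "; ".join(x for x in [e.notes, f"sheet: {sheet_name}"] if x)
            rows.append(e)

    # label-level grouping, then partition by full merge key + profile
    by_label: dict[str, list[DictionaryEntry]] = {}
    for e in rows:
        by_label.setdefault(normalize_label(e.label), []).append(e)

    position = {e.element_id: i for i, e in enumerate(rows)}
    kept: list[DictionaryEntry] = []
    groups: list[DuplicateGroup] = []
    already_grouped = {eid for g in carried for eid in g.element_ids}
    for group in by_label.values():
        # partition the label group by full merge key; members of one
        # partition are mechanically identical and merge into the first
        partitions: dict[tuple[str, str, str], list[DictionaryEntry]] = {}
        for m in group:
            k = (*_merge_key(m), m.target_profile_id)
            partitions.setdefault(k, []).append(m)
        member_ids: list[str] = []
        for members in partitions.values():
            kept.append(members[0])
            member_ids.extend(m.element_id for m in members)
        new_ids = [i for i in member_ids if i not in already_grouped]
        if len(member_ids) >= 2 and len(new_ids) >= 2:
            kind = "exact" if len(partitions) == 1 else "near"
            groups.append(DuplicateGroup(kind=kind, element_ids=new_ids))

    kept.sort(key=lambda e: position[e.element_id])
    return DataDictionary(entries=kept,
                          source_sheets=source_sheets,
                          duplicate_groups=carried + groups)


class CoverageItem(BaseModel):
    element_id: str
    covered: bool
    guide_id: str = ""
    profile_id: str = ""
    constraint_paths: list[str] = Field(default_factory=list)
    reason: str = ""


class CoverageReport(BaseModel):
    """Per-entry realization of the dictionary in the generated guides."""

    items: list[CoverageItem]
    coverage_fraction: float
    validation_status_counts: dict[str, int]

    @property
    def uncovered(self) -> list[CoverageItem]:
        return [i for i in self.items if not i.covered]

    def to_json_dict(self) -> dict:
        return self.model_dump()

    def to_markdown(self) -> str:
        lines = ["# Dictionary coverage report", "",
                 f"Coverage: {100.0 * self.coverage_fraction:.1f}% "
                 f"({len(self.items) - len(self.uncovered)}/{len(self.items)} entries)", "",
                 "| element id | covered | guide | profile | constraints | note |",
                 "|---|---|---|---|---|---|"]
        for it in self.items:
            lines.append(
                f"| {it.element_id} | {'yes' if it.covered else 'NO'} | {it.guide_id} "
                f"| {it.profile_id} | {', '.join(it.constraint_paths)} | {it.reason} |")
        lines += ["", "Mapping progress: " + ", ".join(
            f"{k}={v}" for k, v in sorted(self.validation_status_counts.items()))]
        return "\n".join(lines) + "\n"


def completeness_report(dictionary: DataDictionary, packages: list) -> CoverageReport:
    """Check that every dictionary concept is realized in the generated guides.

    For each entry, reports the profile and the element constraints that
    realize it, or lists it as uncovered with the reason.  ``packages`` is the
    list of generated IG packages (duck-typed to avoid a circular import).
    """
    profile_index: dict[str, tuple[str, object]] = {}
    for pkg in packages:
        for prof in pkg.profiles:
            profile_index[prof.name] = (pkg.guide_id, prof)

    items: list[CoverageItem] = []
    for e in dictionary.entries:
        if not e.fhir_resource_path.strip():
            items.append(CoverageItem(element_id=e.element_id, covered=False,
                                      reason="blank FHIR resource path"))
            continue
        hit = profile_index.get(e.target_profile_id)
        if hit is None:
            items.append(CoverageItem(element_id=e.element_id, covered=False,
                                      reason=f"no profile named {e.target_profile_id!r}"))
            continue
        guide_id, prof = hit
        wanted = {p.strip() for p in
                  e.fhir_resource_path.replace(";", ",").split(",") if p.strip()}
        element_paths = {w.partition(".")[2] for w in wanted}
        realized = [c.path for c in prof.constraints
                    if c.path in element_paths or not any(element_paths)]
        if element_paths == {""} or not any(element_paths):
            # profile-level mapping: the profile itself realizes the entry
            items.append(CoverageItem(element_id=e.element_id, covered=True,
                                      guide_id=guide_id, profile_id=prof.id,
                                      reason="profile-level mapping"))
        elif realized:
            items.append(CoverageItem(element_id=e.element_id, covered=True,
                                      guide_id=guide_id, profile_id=prof.id,
                                      constraint_paths=sorted(realized)))
        else:
            items.append(CoverageItem(element_id=e.element_id, covered=False,
                                      profile_id=prof.id,
                                      reason="no constraint realizes the mapped path"))
    n = len(items)
    covered = sum(1 for i in items if i.covered)
    counts: dict[str, int] = {}
    for e in dictionary.entries:
        counts[e.validation_status] = counts.get(e.validation_status, 0) + 1
    return CoverageReport(items=items,
                          coverage_fraction=(covered / n) if n else 1.0,
                          validation_status_counts=counts)
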