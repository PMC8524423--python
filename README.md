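# dak2fhir

Compile an annotated clinical data dictionary into FHIR R4
implementation-guide source artifacts.

## The problem

Health programs increasingly publish their clinical guidance as a
semi-structured *data dictionary*: one row per data element, written the way
the element appears on a form ("Hypertension? yes/no", "Number of
pregnancies: ___").  Making that guidance machine-readable means expressing
every element against an interoperability standard — here HL7 FHIR R4
(4.0.1) — and against semantic terminologies (SNOMED CT, LOINC, ICD-10,
RxNorm), then packaging the result as implementation guides (IGs) that
system implementers can consume.  Doing this by hand is slow and
inconsistent; `dak2fhir` does the mechanical part: given a dictionary whose
mapping columns name a FHIR resource path, a target profile, fixed
attributes, a value-set binding and terminology codes per row, it generates
the complete IG source trees — profile differentials, value sets, generated
code systems, manifests and human-readable differential tables — factored
into a shared **Core** guide plus per-program (**FP** — family planning,
**STI** — sexually transmitted infections) guides.

It is aimed at informaticists and terminologists who maintain such
dictionaries and want regenerable, validated conformance artifacts instead
of hand-edited ones.

## What the compiler does

1. **Consolidation** — workflow-oriented sheets are flattened into one
   master dictionary.  Rows identical under the duplicate key
   (case-folded whitespace-collapsed label + FHIR resource path, agreeing on
   target profile) merge; rows that share a label but disagree on mapping
   are flagged for human review, never merged.
2. **Terminology parsing** — the free-text code column
   (`SNOMED: 14,302,001 (maps to Amenorrhea)`, one segment per line or
   semicolon) is parsed into `(system, code, display)` codings; printed
   thousands separators and dash variants are normalized, and each code is
   checked against its system's syntactic format rule.  No terminology
   server is consulted.
3. **Remodeling** — form questions are rewritten into a semantically
   oriented model: a yes/no condition question becomes a `Condition`
   profile whose `code` is bound to a value set of the concept's codes
   (presence replaces the boolean); choice questions become coded
   observations whose options form a bound value set; quantities and dates
   type the value element.  The original UI fields are kept as metadata, so
   the transform is exactly reversible for display.
4. **Conformance generation** — entries grouped by Target Profile ID become
   `StructureDefinition` differentials over one of the 19 supported R4
   resource types; answer value sets are content-addressed so one code set
   is defined once and referenced everywhere it is used.
5. **Assembly and validation** — profiles and value sets are partitioned
   into the Core/FP/STI guides (anything used by both programs is promoted
   to Core), written as deterministic JSON + Markdown trees, and every
   differential is validated against vendored R4 base-resource metadata —
   entirely offline.

## Worked example

Write the built-in fixture dictionary and compile it:

```sh
$ dak2fhir fixtures -o fixtures
published fixture -> fixtures/published_fixture.csv
$ dak2fhir generate fixtures/published_fixture.csv -o ig
226 files across 3 guides -> ig; coverage 100.0%
```

The fixture has 105 entries; the compile produces 46 Core, 29 FP and 30 STI
profiles, and the coverage report confirms every dictionary concept is
realized by a profile constraint.  A single amenorrhea row — a yes/no
question mapped to `Condition.code` with ICD-10 and SNOMED codes — compiles
to a condition-presence profile with a two-code value set:

```python
from dak2fhir import compile_dictionary
from dak2fhir.fixtures import single_entry_fixture

result = compile_dictionary(single_entry_fixture("fp-amenorrhea"))
for pkg in result.packages:
    for vs in pkg.value_sets:
        print(f"{pkg.guide_id}: ValueSet {vs.id} -> "
              + ", ".join(f"{c.system}|{c.code}" for c in vs.codings))
```

```
fp: ValueSet amenorrhea-codes -> http://hl7.org/fhir/sid/icd-10|N91.2, http://snomed.info/sct|14302001
```

The printed codes are the dictionary's codes after normalization (the
SNOMED concept arrives as `14,302,001` and leaves as `14302001`).  The
emitted tree under `ig/fp/input/resources/ValueSet-amenorrhea-codes.json`
carries the same two codings grouped by system.

## Layout

```
src/dak2fhir/
  dictionary.py    # master-dictionary model, CSV/TSV I/O, consolidation, coverage
  terminology.py   # code-system registry, multi-code text parser, format rules
  remodel.py       # UI-model <-> semantic-model transform (reversible)
  conformance.py   # profiles, value sets, code systems, JSON emission
  assembler.py     # guide partitioning, IG trees, differential tables
  fhir_base.py     # vendored R4 base metadata + offline structural validator
  fixtures.py      # built-in fixture dictionary, random dictionary generator
  config.py, cli.py, pipeline.py
```
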