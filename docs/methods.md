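# Methods

This note documents the model behind `dak2fhir`, the conventions it fixes
where the input format leaves room, the numerical/determinism choices, what
the built-in fixtures do and do not emulate, and known limitations.

## The compilation model

The compiler treats a clinical data dictionary as a total function from
rows to conformance artifacts.  A row (a `DictionaryEntry`) carries two
kinds of information: the *UI view* (label, answer type, answer options) and
the *mapping view* (FHIR resource path, fixed attributes, target profile,
value-set binding with strength, FHIR code system/code, free-text semantic
terminology codes, program membership).  Compilation is a pure pipeline:

    consolidate -> parse terminology -> remodel -> build value sets
                -> build profiles -> partition into guides -> validate

No step consults the network, no step is randomized, and every emission is
canonical (fixed key order, sorted constraint lists, `\n`-terminated JSON),
so equal dictionaries yield byte-identical artifact trees.  That property is
what makes regeneration safe: the guides can be thrown away and rebuilt
whenever the dictionary changes.

## Consolidation and the duplicate key

Source workbooks repeat a concept once per point in the care workflow.  The
duplicate key is declared, not inferred: case-folded, whitespace-collapsed
label plus the FHIR resource path.  Rows identical under the key *and*
agreeing on target profile merge into the first occurrence (row order is
otherwise preserved); rows that share only a label, or share the key but
name different profiles, are recorded as *near* duplicate groups and kept —
mechanical merging is restricted to cases where no judgement is involved,
and everything else is surfaced for human review.  Duplicate groups found
in an earlier pass are carried forward, which makes consolidation
idempotent (`consolidate([consolidate(S)]) == consolidate(S)`), a property
the tests check against a brute-force union-and-group oracle.

## Terminology handling

The code column is human-typed text, one `Label: code (maps to display)`
segment per newline or semicolon.  The parser never fails: each segment
becomes either a coding or a collected parse issue, and segment order is
preserved (`codings + issues == segments`, a tested invariant).
Normalization strips whitespace, canonicalizes Unicode dash variants to
ASCII hyphen, and removes thousands separators from digit-grouped codes;
it is idempotent.  Validation is *syntactic only* — per-system regexes
(SNOMED/RxNorm all-digit, LOINC `digits-hyphen-digit`, ICD-10
`letter digit digit [.n]`) — because the artifact must build and test with
no terminology downloads.  Whether a code actually exists in a terminology
release is out of scope.  The registry resolves common label spellings
case-insensitively, passes absolute URIs through, and is extensible from
the run config.

## Remodeling patterns and reversibility

The rule table maps the resource type of the mapped path (plus the answer
type, for observations) to a pattern:

| pattern | trigger | effect |
|---|---|---|
| condition_presence | Condition.* | boolean question → profile on `Condition.code` bound to a value set of the concept's codes; an instance's presence replaces "yes" |
| coded_observation | Observation + boolean/choice | options → bound value set on `valueCodeableConcept`; the question's own code is fixed on `Observation.code` |
| quantity_observation / date_observation | Observation + quantity/date | `valueQuantity` / `valueDateTime`; no answer value set |
| medication_statement / procedure | MedicationStatement.* / Procedure.* | concept codes bind `medicationCodeableConcept` / `code` |
| passthrough | everything else | entry returned unchanged |

Per-entry overrides in the config win over the table, so both modelings of
a yes/no clinical question (boolean observation vs condition presence) are
expressible; ambiguity is never guessed — unresolvable entries pass through
with a logged notice.  Boolean answers that must become coded use the
standard SNOMED CT yes/no concepts (373066001/373067005, configurable).

Reversibility is guaranteed by construction, not by inverting the transform
analytically: every non-passthrough output carries a snapshot of the
original UI fields, and `revert` projects it back.  `revert ∘ remodel` is
the identity on the UI projection for every pattern — tested property-style
on random entries.  A condition-presence entry with zero terminology codes
is a hard error: there is nothing to bind.

## Value sets, profiles, emission

Value sets are content-addressed: the registry hashes the `(system, code)`
multiset and returns the existing definition on a hash hit, so a code set
is specified once and referenced by every element that uses it.  Options
that resolve to no terminology code get locally assigned codes (slug of the
option label) in a generated CodeSystem owned by the value set; options on
an entry that declares a FHIR code system become codes in that system and
need no local CodeSystem.  Name collisions between different code sets get
a numeric disambiguator; ids are deterministic slugs throughout (lowercase,
punctuation dropped, non-alphanumeric runs → single hyphen).

Profiles are differentials only — no snapshots, no inheritance chains
beyond the base resource.  Constrained elements default to `min=0` +
`mustSupport` (a minimum data set marks what systems must be able to
handle, not what every instance must contain); a config flag switches to
`min=1`, and emitted minima are never allowed below the base's.  Fixed
values are emitted pattern-style (open fixation) by default because fixed
attributes like a category discriminator constrain a value, not the whole
element; `use_pattern: false` switches to exact `fixed[x]`.  A mapped path
absent from the base element table becomes a simple generated extension
slice rather than an invalid path.

## Offline base metadata and validation

The package vendors a compact element table (path, types, cardinality) for
the 19 supported R4 resource types: all top-level elements plus the nested
paths the pipeline commonly constrains, transcribed from the published
4.0.1 definitions (`scripts/gen_base_metadata.py` regenerates it).  The
validator checks emitted StructureDefinitions against it: mandatory fields,
known base type, differential paths present in the base (choice-type
variants like `valueCodeableConcept` resolve to `value[x]`), cardinality
within base bounds, bindings only on bindable datatypes, and the
4.0.1/constraint pins.  Unknown paths and cardinality violations are
errors; it is deliberately not a general FHIR validator (no slicing, no
invariants, no terminology expansion).

## Guide partitioning

A profile built from entries of more than one program is tagged `core` at
build time; partitioning then sends each profile to its program's guide,
with FP and STI depending on Core.  A value set follows the lowest common
guide of its referencing profiles (one program → that guide; several, or
none → Core), and a generated CodeSystem follows its value set.  The
output layout follows the de-facto IG-publisher input convention
(`input/resources`, `input/pagecontent`, NPM-style `package.json`), but no
publisher is run and no HTML is rendered.

## Fixtures: what they emulate and what they don't

`published_fixture()` reconstructs the published FP/STI mapping exercise at
desk scale: the six worked mapping examples verbatim (amenorrhea,
number-of-pregnancies, azithromycin, drug allergies, administrative gender,
the communication-not-done-reason binding) plus one row per profile of the
published 46/29/30 Core/FP/STI inventory.  The inventory publishes profile
*names* only, so the rows behind the other 99 profiles are synthetic — one
plausible element path per resource type, answer types chosen from the
concept name (quantities for measurements, dates for visit dates, booleans
otherwise), and clearly-marked synthetic SNOMED-format codes where the
condition pattern requires one.  Passing tests therefore demonstrate that
the *machinery* reproduces the published structure — profile name sets,
guide factoring, value-set reuse, code propagation — not that the synthetic
element content matches the unpublished dictionaries' clinical content.

`random_dictionary(FixtureSpec)` generates seed-reproducible dictionaries
(default mix: 50/25/25 core/fp/sti; 25% choice, 20% quantity, 30% boolean
answers; duplicate rate 0) whose codes all satisfy the format rules; it
backs the fuzz, oracle and idempotence tests.  It does not emulate
free-text noise, inconsistent column usage, or mapping errors — the error
paths are exercised by targeted tests instead.

## Problem sizes

The test suite and the acceptance script run the fixture dictionary
(105 entries), 100 random dictionaries of 8 entries for the validity sweep,
30- and 60-entry dictionaries with 20–25% deliberate duplicates for the
consolidation oracles, and the full fixture emission (226 files) twice for
the idempotence check — desk-scale sizes chosen because every property
under test is size-independent.

## Known limitations

- Validation of codes is syntactic; no check that a code exists or that a
  display matches the terminology release.
- The element metadata covers the paths the pipeline constrains, not the
  full R4 snapshot; exotic nested paths fall back to generated extensions.
- Duplicate detection is key-based; semantically equal labels with
  different wording are not grouped.
- Cross-profile slicing, FHIRPath invariants and profile inheritance are
  out of scope, as is any publishing step beyond the source tree.
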