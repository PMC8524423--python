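"""Dictionary I/O, multi-sheet consolidation, and the completeness report."""

import pytest

from dak2fhir import (compile_dictionary, completeness_report, consolidate,
                      read_dictionary, write_dictionary)
from dak2fhir.dictionary import DataDictionary, DictionaryEntry
from dak2fhir.errors import MissingColumnError
from dak2fhir.fixtures import FixtureSpec, random_dictionary


def _entry(eid, label, path="Observation.value", profile="P", program="core", **kw):
    return DictionaryEntry(element_id=eid, label=label, fhir_resource_path=path,
                           target_profile_id=profile, program=program, **kw)


class TestReadWrite:
    def test_single_row_carries_code_text_verbatim(self, tmp_path):
        f = tmp_path / "one.csv"
        f.write_text(
            "Label,FHIR Resource,Target Profile ID,Semantic Terminology Code\n"
            'Amenorrhea,Observation.value,P1,"SNOMED: 14,302,001 (maps to Amenorrhea)"\n')
        d = read_dictionary(f)
        assert len(d.entries) == 1
        assert d.entries[0].semantic_code_text == "SNOMED: 14,302,001 (maps to Amenorrhea)"

    def test_empty_data_section(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("Label,FHIR Resource,Target Profile ID\n")
        assert read_dictionary(f).entries == []

    def test_missing_target_profile_column(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("Label,FHIR Resource\nX,Observation.value\n")
        with pytest.raises(MissingColumnError) as exc:
            read_dictionary(f)
        assert "Target Profile ID" in str(exc.value)

    def test_round_trip_field_by_field(self, tmp_path, fixture_dictionary):
        f = tmp_path / "rt.csv"
        write_dictionary(fixture_dictionary, f)
        back = read_dictionary(f)
        assert len(back.entries) == len(fixture_dictionary.entries)
        for a, b in zip(fixture_dictionary.entries, back.entries):
            assert a.model_dump() == b.model_dump()

    def test_unknown_columns_preserved_as_notes(self, tmp_path):
        f = tmp_path / "extra.csv"
        f.write_text("Label,FHIR Resource,Target Profile ID,Mystery\n"
                     "X,Observation.value,P1,kept\n")
        d = read_dictionary(f)
        assert "Mystery: kept" in d.entries[0].notes


class TestWorkbookAdapter:
    def test_multisheet_xlsx_reads_and_consolidates(self, tmp_path):
        import pandas as pd
        from dak2fhir.dictionary import read_workbook
        f = tmp_path / "wb.xlsx"
        frame = pd.DataFrame({
            "Label": ["Number of Pregnancies"],
            "FHIR Resource": ["Observation.value"],
            "Target Profile ID": ["P1"],
        })
        with pd.ExcelWriter(f) as xl:
            frame.to_excel(xl, sheet_name="visit", index=False)
            frame.to_excel(xl, sheet_name="followup", index=False)
        sheets = read_workbook(f)
        assert set(sheets) == {"visit", "followup"}
        master = consolidate(sheets)
        assert len(master.entries) == 1
        assert master.duplicate_groups[0].kind == "exact"


class TestConsolidate:
    def test_identical_rows_merge_into_one(self):
        a = DataDictionary(entries=[_entry("a1", "Number of Pregnancies")])
        b = DataDictionary(entries=[_entry("b1", "Number of Pregnancies")])
        master = consolidate({"visit1": a, "visit2": b})
        assert len(master.entries) == 1
        (group,) = master.duplicate_groups
        assert group.kind == "exact" and set(group.element_ids) == {"a1", "b1"}

    def test_single_sheet_identity(self):
        a = DataDictionary(entries=[_entry("a1", "X"), _entry("a2", "Y")])
        master = consolidate({"only": a})
        assert [e.element_id for e in master.entries] == ["a1", "a2"]
        assert master.duplicate_groups == []

    def test_conflicting_profile_flagged_never_merged(self):
        a = DataDictionary(entries=[_entry("a1", "Same", profile="P1")])
        b = DataDictionary(entries=[_entry("b1", "Same", profile="P2")])
        master = consolidate({"s1": a, "s2": b})
        assert len(master.entries) == 2
        (group,) = master.duplicate_groups
        assert group.kind == "near"

    @pytest.mark.parametrize("sizes", [(3, 4, 5), (1, 1, 1), (0, 2, 7)])
    def test_disjoint_sheets_union_matches_naive_oracle(self, sizes):
        sheets = {}
        oracle = []
        for s, n in enumerate(sizes):
            rows = [_entry(f"s{s}e{i}", f"Sheet{s} Concept {i}") for i in range(n)]
            oracle.extend(rows)
            sheets[f"sheet{s}"] = DataDictionary(entries=rows)
        master = consolidate(sheets)
        assert len(master.entries) == len(oracle) == sum(sizes)
        assert [e.element_id for e in master.entries] == [e.element_id for e in oracle]

    def test_idempotent(self):
        a = DataDictionary(entries=[_entry("a1", "Dup"), _entry("a2", "Solo")])
        b = DataDictionary(entries=[_entry("b1", "Dup")])
        once = consolidate({"s1": a, "s2": b})
        twice = consolidate({"master": once})
        assert [e.model_dump() for e in twice.entries] == \
               [e.model_dump() for e in once.entries]
        assert [g.model_dump() for g in twice.duplicate_groups] == \
               [g.model_dump() for g in once.duplicate_groups]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_entry_count_matches_bruteforce_grouping_oracle(self, seed):
        d = random_dictionary(FixtureSpec(seed=seed, n_entries=40, duplicate_rate=0.25))
        half = len(d.entries) // 2
        s1 = DataDictionary(entries=d.entries[:half])
        s2 = DataDictionary(entries=d.entries[half:])
        master = consolidate({"s1": s1, "s2": s2})
        # oracle: naive concatenation grouped by the exact merge key
        groups = {}
        for e in d.entries:
            key = (" ".join(e.label.split()).casefold(),
                   e.fhir_resource_path, e.target_profile_id)
            groups.setdefault(key, []).append(e.element_id)
        expected = len(d.entries) - sum(len(g) - 1 for g in groups.values())
        assert len(master.entries) == expected


class TestCompletenessReport:
    def test_full_compile_is_fully_covered(self, fixture_dictionary, compiled):
        report = completeness_report(compiled.remodeled, compiled.packages)
        assert report.coverage_fraction == 1.0
        assert report.uncovered == []

    def test_blank_path_listed_uncovered(self):
        d = DataDictionary(entries=[_entry("u1", "Unmapped", path="")])
        report = completeness_report(d, [])
        assert len(report.uncovered) == 1
        assert report.uncovered[0].element_id == "u1"

    def test_uncovered_count_matches_set_difference_oracle(self):
        d = random_dictionary(FixtureSpec(seed=9, n_entries=50))
        unmapped_ids = {e.element_id for e in d.entries[::10]}  # 5 entries
        for e in d.entries:
            if e.element_id in unmapped_ids:
                e.fhir_resource_path = ""
        result = compile_dictionary(d)
        report = result.coverage
        assert {i.element_id for i in report.uncovered} == unmapped_ids
        assert len(report.uncovered) == 5
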