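import textwrap

import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialnet.registry_io import (
    AliasTable,
    RegionMap,
    RegistryFormatError,
    ScopeLabel,
    StudyRecord,
    assign_region,
    classify_scope,
    deduplicate_studies,
    load_aliases,
    load_region_map,
    multinational_only,
    normalize_country,
    parse_start_year,
    read_registry,
    write_registry_tsv,
)


def write_tsv(tmp_path, body, header="study_id\tstart_date\tcountries\tconditions"):
    path = tmp_path / "registry.tsv"
    path.write_text(header + "\n" + textwrap.dedent(body), encoding="utf-8")
    return path


class TestReadRegistryTsv:
    def test_direct_field_mapping(self, tmp_path):
        path = write_tsv(tmp_path, "NCT001\t2009-03\tUnited States|Canada\tDiabetes\n")
        (rec,) = read_registry(path)
        assert rec.study_id == "NCT001"
        assert rec.start_year == 2009
        assert rec.countries == {"United States", "Canada"}
        assert rec.conditions == ("diabetes",)

    def test_duplicate_country_collapses_to_set(self, tmp_path):
        path = write_tsv(tmp_path, "NCT002\t2010\tFrance|France\t\n")
        (rec,) = read_registry(path)
        assert rec.countries == {"France"}

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = write_tsv(tmp_path, "")
        assert read_registry(path) == []

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(RegistryFormatError):
            read_registry(tmp_path / "nope.tsv")

    def test_missing_columns_fatal(self, tmp_path):
        path = write_tsv(tmp_path, "x\ty\n", header="study_id\tstart_date")
        with pytest.raises(RegistryFormatError, match="missing columns"):
            read_registry(path)

    def test_malformed_row_skipped_lenient_fatal_strict(self, tmp_path, caplog):
        body = "\t2009\tFrance\t\nNCT003\t2009\tFrance\t\n"
        path = write_tsv(tmp_path, body)
        with caplog.at_level("WARNING", logger="trialnet.registry_io"):
            records = read_registry(path)
        assert [r.study_id for r in records] == ["NCT003"]
        assert any("skipped" in m for m in caplog.messages)
        with pytest.raises(RegistryFormatError):
            read_registry(path, strict=True)

    def test_no_country_list_yields_empty_set(self, tmp_path):
        path = write_tsv(tmp_path, "NCT004\t2009\t\tasthma\n")
        (rec,) = read_registry(path)
        assert rec.countries == frozenset()

    def test_alias_applied_during_read(self, tmp_path):
        path = write_tsv(tmp_path, "NCT005\t2009\tKorea, Republic of|Viet Nam\t\n")
        (rec,) = read_registry(path)
        assert rec.countries == {"South Korea", "Vietnam"}

    def test_roundtrip_write_read(self, tmp_path):
        records = [
            StudyRecord("S1", 2001, frozenset({"France", "Germany"}), ("asthma",)),
            StudyRecord("S2", None, frozenset({"Japan"}), ()),
        ]
        path = tmp_path / "out.tsv"
        write_registry_tsv(records, path)
        back = read_registry(path)
        assert back == records


class TestReadCtgovXml:
    def test_single_study_document(self, tmp_path):
        xml = """<clinical_study>
          <id_info><nct_id>NCT010</nct_id></id_info>
          <start_date>March 2009</start_date>
          <condition>Diabetes</condition>
          <location_countries>
            <country>United States</country>
            <country>Russian Federation</country>
          </location_countries>
          <phase>Phase 3</phase>
        </clinical_study>"""
        path = tmp_path / "study.xml"
        path.write_text(xml)
        (rec,) = read_registry(path, format="ctgov_xml")
        assert rec == StudyRecord(
            "NCT010", 2009, frozenset({"United States", "Russia"}), ("diabetes",)
        )

    def test_multi_study_container(self, tmp_path):
        xml = """<studies>
          <clinical_study><id_info><nct_id>A1</nct_id></id_info>
            <start_date>2001-05-02</start_date>
            <location_countries><country>France</country></location_countries>
          </clinical_study>
          <clinical_study><id_info><nct_id>A2</nct_id></id_info>
            <location_countries><country>Spain</country></location_countries>
          </clinical_study>
        </studies>"""
        path = tmp_path / "studies.xml"
        path.write_text(xml)
        records = read_registry(path, format="ctgov_xml")
        assert [r.study_id for r in records] == ["A1", "A2"]
        assert records[0].start_year == 2001
        assert records[1].start_year is None

    def test_malformed_xml_fatal(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<clinical_study><oops>")
        with pytest.raises(RegistryFormatError):
            read_registry(path, format="ctgov_xml")


class TestParseStartYear:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("2009", 2009),
            ("2009-03", 2009),
            ("2009-03-15", 2009),
            ("March 2009", 2009),
            ("March 15, 2009", 2009),
            ("", None),
            (None, None),
            ("sometime soon", None),
            ("1776", None),  # outside default plausibility window
            ("9999-01", None),
        ],
    )
    def test_dialects(self, raw, expected):
        assert parse_start_year(raw) == expected

    def test_custom_window(self):
        assert parse_start_year("1776", year_window=(1700, 2100)) == 1776


class TestDeduplicateStudies:
    def test_union_semantics(self):
        records = [
            StudyRecord("NCT001", 2005, frozenset({"United States"}), ("hiv",)),
            StudyRecord("NCT001", 2004, frozenset({"Canada"}), ("hiv", "asthma")),
        ]
        (merged,) = deduplicate_studies(records)
        assert merged.countries == {"United States", "Canada"}
        assert merged.start_year == 2004
        assert set(merged.conditions) == {"hiv", "asthma"}

    def test_all_unique_identity(self):
        records = [
            StudyRecord(f"S{i}", 2000, frozenset({"France", "Spain"})) for i in range(5)
        ]
        assert deduplicate_studies(records) == sorted(records, key=lambda r: r.study_id)

    def test_grouping_oracle_10_records_4_ids(self):
        # Independent oracle: brute-force grouping of countries by id.
        import random

        rng = random.Random(42)
        ids = ["W", "X", "Y", "Z"]
        universe = [f"C{i}" for i in range(8)]
        records = [
            StudyRecord(rng.choice(ids), 2000, frozenset(rng.sample(universe, 2)))
            for _ in range(10)
        ]
        expected: dict[str, set] = {}
        for rec in records:
            expected.setdefault(rec.study_id, set()).update(rec.countries)
        out = deduplicate_studies(records)
        assert len(out) == len(expected)
        assert {r.study_id: set(r.countries) for r in out} == expected

    def test_idempotent(self):
        records = [
            StudyRecord("A", 2001, frozenset({"France"})),
            StudyRecord("A", None, frozenset({"Spain"})),
            StudyRecord("B", 2002, frozenset({"Japan"})),
        ]
        once = deduplicate_studies(records)
        assert deduplicate_studies(once) == once

    def test_conflicting_years_warn(self, caplog):
        records = [
            StudyRecord("A", 2003, frozenset({"France"})),
            StudyRecord("A", 2001, frozenset({"France"})),
        ]
        with caplog.at_level("WARNING", logger="trialnet.registry_io"):
            (merged,) = deduplicate_studies(records)
        assert merged.start_year == 2001
        assert any("conflicting start years" in m for m in caplog.messages)


class TestClassifyScope:
    def test_multinational(self):
        rec = StudyRecord("A", None, frozenset({"United States", "Canada", "Mexico"}))
        assert classify_scope(rec) is ScopeLabel.MULTINATIONAL

    def test_single_nation(self):
        assert (
            classify_scope(StudyRecord("A", None, frozenset({"France"})))
            is ScopeLabel.SINGLE_NATION
        )

    def test_unlocated(self):
        rec = StudyRecord("A", None, frozenset())
        assert classify_scope(rec) is ScopeLabel.UNLOCATED
        assert multinational_only([rec]) == []

    @given(st.frozensets(st.sampled_from([f"C{i}" for i in range(10)])))
    def test_depends_only_on_cardinality(self, countries):
        label = classify_scope(StudyRecord("A", None, countries))
        expected = (
            ScopeLabel.UNLOCATED
            if not countries
            else ScopeLabel.SINGLE_NATION
            if len(countries) == 1
            else ScopeLabel.MULTINATIONAL
        )
        assert label is expected

    @given(
        st.lists(
            st.frozensets(st.sampled_from([f"C{i}" for i in range(6)]), max_size=4),
            max_size=20,
        )
    )
    def test_scope_counts_partition_studies(self, country_sets):
        records = [
            StudyRecord(f"S{i}", None, cs) for i, cs in enumerate(country_sets)
        ]
        unique = deduplicate_studies(records)
        labels = [classify_scope(r) for r in unique]
        assert (
            labels.count(ScopeLabel.SINGLE_NATION)
            + labels.count(ScopeLabel.MULTINATIONAL)
            + labels.count(ScopeLabel.UNLOCATED)
            == len(unique)
        )


class TestNormalizeCountry:
    def test_alias_lookup(self):
        aliases = load_aliases()
        assert normalize_country("Korea, Republic of", aliases) == "South Korea"

    def test_identity(self):
        aliases = load_aliases()
        assert normalize_country("United States", aliases) == "United States"

    def test_case_insensitive(self):
        aliases = load_aliases()
        assert normalize_country("  united states ", aliases) == "United States"

    def test_unknown_passes_through_with_warning(self, caplog):
        aliases = load_aliases()
        with caplog.at_level("WARNING", logger="trialnet.registry_io"):
            assert normalize_country("Untied States", aliases) == "Untied States"
        assert any("unknown country" in m for m in caplog.messages)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            normalize_country("   ", AliasTable())

    def test_user_overrides(self, tmp_path):
        override = tmp_path / "aliases.yaml"
        override.write_text('"Untied States": United States\n')
        aliases = load_aliases(override)
        assert normalize_country("Untied States", aliases) == "United States"


class TestAssignRegion:
    def test_brazil_south_america(self):
        assert assign_region("Brazil", load_region_map()) == "South America"

    def test_solomon_islands_oceania(self):
        assert assign_region("Solomon Islands", load_region_map()) == "Oceania"

    def test_unmapped_strict_error(self):
        with pytest.raises(KeyError):
            assign_region("Atlantis", load_region_map(), strict=True)

    def test_unmapped_lenient_bucket(self, caplog):
        with caplog.at_level("WARNING", logger="trialnet.registry_io"):
            assert assign_region("Atlantis", load_region_map()) == "Unassigned"
        assert any("Atlantis" in m for m in caplog.messages)

    def test_transcontinental_defaults(self):
        region_map = load_region_map()
        assert region_map["Russia"] == "Europe"
        assert region_map["Turkey"] == "Asia"
        assert region_map["Georgia"] == "Asia"
        assert region_map["Egypt"] == "Africa"
        assert region_map["Mexico"] == "North America"

    def test_exactly_six_region_labels(self):
        assert load_region_map().regions_present() == {
            "North America",
            "South America",
            "Africa",
            "Europe",
            "Asia",
            "Oceania",
        }

    def test_bad_region_label_rejected(self):
        with pytest.raises(ValueError):
            RegionMap({"Narnia": "Middle Earth"})

    def test_custom_region_map_file(self, tmp_path):
        path = tmp_path / "regions.yaml"
        path.write_text("Russia: Asia\n")
        assert assign_region("Russia", load_region_map(path)) == "Asia"
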