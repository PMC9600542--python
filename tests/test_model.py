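"""ICSR domain types, CSV dialects and the hierarchy dictionary."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from pvsignal.model import (
    AGE_GROUPS,
    CONTINENTS,
    Dataset,
    EmptyDatasetError,
    ICSRReport,
    IntegrityError,
    MedDRADictionary,
    SchemaError,
    SOCRecord,
    read_icsr_table,
    read_meddra_dictionary,
    toy_dictionary,
    write_icsr_table,
)

LONG_HEADER = "report_id,drug,event_pt,continent,age_group,sex,serious,notifier\n"


def _long_csv(rows):
    return io.StringIO(LONG_HEADER + "\n".join(rows) + "\n")


class TestReadLong:
    def test_rows_of_one_report_merge_with_set_deduplication(self):
        src = _long_csv(
            [
                "R1,omalizumab,Ear pain,Americas,45–65 years,Female,Yes,Physician",
                "R1,omalizumab,Otorrhoea,Americas,45–65 years,Female,Yes,Physician",
                "R1,omalizumab,Ear pain,Americas,45–65 years,Female,Yes,Physician",
            ]
        )
        ds = read_icsr_table(src)
        assert len(ds) == 1
        (r,) = ds.reports
        assert r.drugs == frozenset({"omalizumab"})
        assert r.events == frozenset({"Ear pain", "Otorrhoea"})

    def test_conflicting_demographics_within_report_rejected(self):
        src = _long_csv(
            [
                "R2,omalizumab,Ear pain,Americas,Unknown,Male,Yes,Physician",
                "R2,omalizumab,Rash,Americas,Unknown,Female,Yes,Physician",
            ]
        )
        with pytest.raises(IntegrityError, match="R2"):
            read_icsr_table(src)

    def test_missing_column_named_in_error(self):
        src = io.StringIO("report_id,drug,continent,age_group,sex,serious,notifier\nR1,d,Americas,Unknown,Male,Yes,Physician\n")
        with pytest.raises(SchemaError, match="event_pt"):
            read_icsr_table(src)

    def test_empty_file_rejected(self):
        with pytest.raises(EmptyDatasetError):
            read_icsr_table(io.StringIO(LONG_HEADER))

    def test_unknown_category_strict_vs_lenient(self):
        rows = ["R1,omalizumab,Ear pain,Atlantis,Unknown,Male,Yes,Physician"]
        with pytest.raises(SchemaError, match="Atlantis"):
            read_icsr_table(_long_csv(rows))
        ds = read_icsr_table(_long_csv(rows), lenient=True)
        assert ds.reports[0].continent == "Unknown"


class TestRoundTrip:
    def test_fixture_round_trips_byte_identically(self, fixture_csv):
        ds = read_icsr_table(fixture_csv)
        assert len(ds) == 10
        buf = io.StringIO()
        write_icsr_table(ds, buf)
        assert buf.getvalue() == fixture_csv.read_text(encoding="utf-8")

    def test_paired_dialect_round_trip(self, fixture_csv, toy_dict):
        ds = read_icsr_table(fixture_csv, dictionary=toy_dict)
        demo, links = io.StringIO(), io.StringIO()
        write_icsr_table(ds, demo, dialect="paired", links_sink=links)
        demo.seek(0), links.seek(0)
        back = read_icsr_table(demo, dialect="paired", links=links, dictionary=toy_dict)
        assert back.equals(ds)

    def test_comma_in_pt_is_quoted(self):
        r = ICSRReport("R1", frozenset({"d"}), frozenset({"Respiratory, thoracic pain"}))
        buf = io.StringIO()
        write_icsr_table(Dataset([r]), buf)
        assert '"Respiratory, thoracic pain"' in buf.getvalue()
        buf.seek(0)
        assert read_icsr_table(buf).reports[0].events == r.events

    def test_empty_dataset_writes_header_only(self):
        buf = io.StringIO()
        write_icsr_table(Dataset([]), buf)
        assert buf.getvalue() == LONG_HEADER

    @settings(max_examples=40, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.sets(st.sampled_from(["drugA", "drugB", "drugC"]), min_size=1),
                st.sets(st.sampled_from(["Ear pain", "Rash", "Cough", "Nausea"]), min_size=1),
                st.sampled_from(CONTINENTS),
                st.sampled_from(AGE_GROUPS),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_round_trip_identity_property(self, data):
        reports = [
            ICSRReport(f"R{i}", frozenset(drugs), frozenset(events), continent=c, age_group=a)
            for i, (drugs, events, c, a) in enumerate(data)
        ]
        ds = Dataset(reports)
        buf = io.StringIO()
        write_icsr_table(ds, buf)
        buf.seek(0)
        assert read_icsr_table(buf).equals(ds)


class TestReportInvariants:
    def test_empty_drug_or_event_set_rejected(self):
        with pytest.raises(ValueError):
            ICSRReport("R1", frozenset(), frozenset({"Ear pain"}))
        with pytest.raises(ValueError):
            ICSRReport("R1", frozenset({"d"}), frozenset())

    def test_enum_closure(self):
        with pytest.raises(SchemaError):
            ICSRReport("R1", frozenset({"d"}), frozenset({"e"}), sex="Intersex")

    def test_terms_nfc_normalized_and_stripped(self):
        r = ICSRReport("R1", frozenset({" omalizumab "}), frozenset({"Ear paiń".replace("́", "")}))
        assert r.drugs == frozenset({"omalizumab"})

    def test_duplicate_report_ids_rejected(self):
        r = ICSRReport("R1", frozenset({"d"}), frozenset({"e"}))
        with pytest.raises(IntegrityError):
            Dataset([r, r])


class TestDictionary:
    def test_lookup_primary_soc(self):
        d = read_meddra_dictionary(
            io.StringIO("pt,primary_soc\nEar pain,Ear and labyrinth disorders\n")
        )
        assert d.primary_soc("Ear pain") == "Ear and labyrinth disorders"

    def test_duplicate_identical_rows_collapse(self):
        d = read_meddra_dictionary(
            io.StringIO("pt,primary_soc\nEar pain,Ear and labyrinth disorders\n"
                        "Ear pain,Ear and labyrinth disorders\n")
        )
        assert len(d) == 1

    def test_conflicting_soc_rejected(self):
        src = io.StringIO("pt,primary_soc\nEar pain,Ear and labyrinth disorders\nEar pain,Nervous system disorders\n")
        with pytest.raises(IntegrityError, match="Ear pain"):
            read_meddra_dictionary(src)

    def test_case_insensitive_fallback(self, toy_dict):
        assert toy_dict.primary_soc("ear PAIN") == "Ear and labyrinth disorders"
        assert "otorrhoea" in toy_dict

    def test_empty_soc_rejected(self):
        with pytest.raises(IntegrityError):
            MedDRADictionary({"Ear pain": SOCRecord(primary_soc="")})

    def test_unmapped_events_surface_in_diagnostics(self, toy_dict):
        ds = Dataset(
            [ICSRReport("R1", frozenset({"d"}), frozenset({"Totally novel PT"}))],
            toy_dict,
        )
        assert ds.unmapped_events == frozenset({"Totally novel PT"})

    def test_toy_fixture_covers_ear_and_eosinophil_terms(self, toy_dict):
        ear = [pt for pt in toy_dict.preferred_terms
               if toy_dict.primary_soc(pt) == "Ear and labyrinth disorders"]
        assert len(ear) == 17
        socs = {toy_dict.primary_soc(pt) for pt in toy_dict.preferred_terms}
        assert len(socs) >= 5
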