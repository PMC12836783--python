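import datetime as dt
import warnings

import pandas as pd
import pytest

from clinotext.corpus_io import (ClinicalNote, ConfigurationError, NoteCorpus,
                                 TreatmentRecord, filter_pre_treatment,
                                 parse_date, read_note_table,
                                 read_structured_observations,
                                 read_treatment_table, write_note_table)

from conftest import D, write_csv

NOTE_COLS = ["patient_id", "date", "source", "text"]


class TestParseDate:
    @pytest.mark.parametrize(
        "literal,dialect,expected,ambiguous",
        [
            ("2020-03-04", "auto", D(2020, 3, 4), False),
            ("31-01-2020", "auto", D(2020, 1, 31), False),  # day>12: unambiguous dmy
            ("01-31-2020", "auto", D(2020, 1, 31), False),  # month>12 impossible: mdy
            ("03-04-2020", "auto", D(2020, 4, 3), True),  # resolved day-first, flagged
            ("03-04-2020", "dmy", D(2020, 4, 3), False),
            ("03-04-2020", "mdy", D(2020, 3, 4), False),
            ("31-02-2020", "auto", None, False),  # invalid calendar date
            ("not a date", "auto", None, False),
            ("2020-13-01", "iso", None, False),
            ("01-02-1850", "dmy", None, False),  # outside plausible range
        ],
    )
    def test_literals(self, literal, dialect, expected, ambiguous):
        date, flag = parse_date(literal, dialect=dialect)
        assert date == expected
        assert flag == ambiguous

    def test_dayfirst_false_resolves_ambiguous_as_mdy(self):
        date, flag = parse_date("03-04-2020", dialect="auto", dayfirst=False)
        assert date == D(2020, 3, 4) and flag


class TestReadNoteTable:
    def test_three_valid_rows_date_sorted(self, tmp_path):
        path = write_csv(
            tmp_path / "notes.csv",
            [
                ("A", "2020-02-01", "outpatient", "later"),
                ("A", "2020-01-01", "outpatient", "earlier"),
                ("B", "2020-01-15", "note", "x"),
            ],
            NOTE_COLS,
        )
        corpus = read_note_table(path)
        assert len(corpus) == 3
        assert [n.text for n in corpus.notes_for("A")] == ["earlier", "later"]
        assert len(corpus.rejects) == 0

    def test_invalid_calendar_date_goes_to_rejects(self, tmp_path):
        path = write_csv(
            tmp_path / "notes.csv",
            [("A", "31-02-2020", "note", "bad"), ("A", "2020-01-01", "note", "ok")],
            NOTE_COLS,
        )
        corpus = read_note_table(path)
        assert len(corpus) == 1
        assert list(corpus.rejects["reason"]) == ["unparseable date"]

    def test_mixed_dialects_parse_and_ambiguous_flagged(self, tmp_path):
        path = write_csv(
            tmp_path / "notes.csv",
            [("A", "2020-04-03", "note", "iso"),
             ("A", "31-01-2020", "note", "dutch"),
             ("A", "03-04-2020", "note", "ambiguous")],
            NOTE_COLS,
        )
        corpus = read_note_table(path, dialect="auto")
        assert len(corpus) == 3  # ambiguous rows are retained
        assert list(corpus.rejects["reason"]) == ["ambiguous-date"]
        assert {n.date for n in corpus.notes_for("A")} == {D(2020, 4, 3), D(2020, 1, 31)}

    def test_missing_column_names_the_column(self, tmp_path):
        path = write_csv(tmp_path / "notes.csv", [("A", "2020-01-01", "x")],
                         ["patient_id", "date", "text"])
        with pytest.raises(ConfigurationError, match="source"):
            read_note_table(path)

    def test_empty_file_warns_and_returns_empty_corpus(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            corpus = read_note_table(path)
        assert len(corpus) == 0

    def test_column_map_renames(self, tmp_path):
        path = write_csv(tmp_path / "notes.csv", [("A", "2020-01-01", "note", "x")],
                         ["pid", "datum", "bron", "tekst"])
        corpus = read_note_table(
            path, column_map={"patient_id": "pid", "date": "datum", "source": "bron", "text": "tekst"}
        )
        assert len(corpus) == 1

    def test_round_trip_preserves_fields(self, tmp_path, small_corpus):
        out = tmp_path / "roundtrip.csv"
        write_note_table(small_corpus, out)
        back = read_note_table(out, dialect="iso")
        orig = small_corpus.to_frame()
        pd.testing.assert_frame_equal(back.to_frame(), orig)


class TestTreatmentTable:
    def test_two_patients(self, tmp_path):
        path = write_csv(tmp_path / "t.csv",
                         [("A", "osimertinib", "2020-01-01"), ("B", "osimertinib", "2020-02-01")],
                         ["patient_id", "drug", "init_date"])
        records = read_treatment_table(path)
        assert len(records) == 2

    def test_duplicate_keeps_earliest_with_warning(self, tmp_path):
        path = write_csv(tmp_path / "t.csv",
                         [("A", "osimertinib", "2020-03-01"), ("A", "osimertinib", "2020-01-01")],
                         ["patient_id", "drug", "init_date"])
        with pytest.warns(UserWarning, match="duplicate"):
            records = read_treatment_table(path)
        assert len(records) == 1
        assert records[0].init_date == D(2020, 1, 1)

    def test_empty_table_yields_empty_collection(self, tmp_path):
        path = write_csv(tmp_path / "t.csv", [], ["patient_id", "drug", "init_date"])
        assert read_treatment_table(path) == []


class TestFilterPreTreatment:
    def test_boundary_inclusive_at_init(self, treatments):
        init = D(2020, 3, 1)
        corpus = NoteCorpus([
            ClinicalNote("A", init - dt.timedelta(days=10), text="before"),
            ClinicalNote("A", init, text="on init"),
            ClinicalNote("A", init + dt.timedelta(days=5), text="after"),
        ])
        out, no_fu = filter_pre_treatment(corpus, treatments)
        assert [n.text for n in out.notes_for("A")] == ["on init", "after"]
        assert no_fu == []

    def test_all_notes_before_init_flags_no_follow_up(self, treatments):
        corpus = NoteCorpus([ClinicalNote("A", D(2020, 1, 1), text="early")])
        out, no_fu = filter_pre_treatment(corpus, treatments)
        assert len(out) == 0
        assert no_fu == ["A"]

    def test_empty_corpus(self, treatments):
        out, no_fu = filter_pre_treatment(NoteCorpus(), treatments)
        assert len(out) == 0 and no_fu == []

    def test_idempotent(self, small_corpus, treatments):
        once, _ = filter_pre_treatment(small_corpus, treatments)
        twice, _ = filter_pre_treatment(once, treatments)
        pd.testing.assert_frame_equal(once.to_frame(), twice.to_frame())

    def test_patient_without_treatment_record_excluded(self):
        corpus = NoteCorpus([ClinicalNote("Z", D(2020, 1, 1), text="orphan")])
        out, _ = filter_pre_treatment(corpus, [TreatmentRecord("A", "osimertinib", D(2020, 1, 1))])
        assert out.patients() == []


class TestStructuredObservations:
    def test_ps_rows(self, tmp_path):
        path = write_csv(tmp_path / "s.csv",
                         [("A", "2020-01-01", "2"), ("A", "2020-01-02", "7")],
                         ["patient_id", "date", "value"])
        obs, rejects = read_structured_observations(path, kind="ps")
        assert len(obs) == 1
        assert obs[0].score == 2 and obs[0].source == "structured"
        assert list(rejects["reason"]) == ["PS outside 0-5"]

    def test_progression_closed_question_maps_to_phase(self, tmp_path):
        path = write_csv(tmp_path / "s.csv",
                         [("A", "2020-01-01", "progressie"), ("A", "2020-02-01", "remissie")],
                         ["patient_id", "date", "value"])
        obs, _ = read_structured_observations(path, kind="progression")
        assert [o.phase for o in obs] == ["PP", "BP"]
        assert all(o.rule_id == "structured" for o in obs)

    def test_unknown_kind_rejected(self, tmp_path):
        path = write_csv(tmp_path / "s.csv", [("A", "2020-01-01", "1")],
                         ["patient_id", "date", "value"])
        with pytest.raises(ConfigurationError):
            read_structured_observations(path, kind="weight")
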