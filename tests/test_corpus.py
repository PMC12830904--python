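"""Domain types, bundle round-trips, and subtask slicing."""

import json

import pytest

from vftk.corpus import (
    FormatError,
    Session,
    SliceResult,
    SubtaskRecording,
    TimestampIndex,
    TranscriptLevel,
    ValidationError,
    WordToken,
    normalize_text,
    read_session_bundle,
    slice_subtasks,
    select_transcript,
    write_session_bundle,
)


def _tok(text, start, end, **kw):
    return WordToken(text=text, start_s=start, end_s=end, **kw)


def _session(subject_id="s01"):
    phon = SubtaskRecording(
        task_kind="phonetic",
        reference=[_tok("lev", 1.0, 1.5), _tok("luna", 3.0, 3.6)],
        transcripts={
            TranscriptLevel.U: [_tok("lev", 1.0, 1.5), _tok("eee", 2.0, 2.2),
                                _tok("lunk", 3.0, 3.6)],
            TranscriptLevel.F: [_tok("lev", 1.0, 1.5), _tok("lunk", 3.0, 3.6)],
            TranscriptLevel.A: [_tok("lev", 1.0, 1.5),
                                _tok("luna", 3.0, 3.6, was_corrected=True,
                                     original_text="lunk")],
        },
    )
    sem = SubtaskRecording(
        task_kind="semantic",
        reference=[_tok("medved", 0.5, 1.1)],
        transcripts={TranscriptLevel.U: [_tok("medved", 0.5, 1.1)],
                     TranscriptLevel.F: [_tok("medved", 0.5, 1.1)],
                     TranscriptLevel.A: [_tok("medved", 0.5, 1.1)]},
    )
    return Session(subject_id=subject_id, group="HC", age=41.0, gender="F",
                   phonetic=phon, semantic=sem, acoustic={"N1": 38.2, "N10": 400.0})


class TestWordToken:
    def test_invariants(self):
        with pytest.raises(ValidationError):
            WordToken(text="", start_s=0, end_s=1)
        with pytest.raises(ValidationError):
            WordToken(text="lev", start_s=2.0, end_s=1.0)
        with pytest.raises(ValidationError):
            WordToken(text="lev", start_s=0, end_s=1, was_corrected=True)
        with pytest.raises(ValidationError):
            WordToken(text="lev", start_s=0, end_s=1, was_corrected=True,
                      original_text="lev")

    def test_normalization(self):
        assert normalize_text("Lev,") == "lev"
        # NFC: decomposed c + caron composes to the same code point
        assert normalize_text("č") == "č"


class TestSubtaskInvariants:
    def test_level_count_monotonicity(self):
        with pytest.raises(ValidationError, match="F"):
            SubtaskRecording(
                task_kind="phonetic",
                transcripts={TranscriptLevel.U: [_tok("lev", 0, 1)],
                             TranscriptLevel.F: [_tok("lev", 0, 1),
                                                 _tok("les", 2, 3)]},
            )
        with pytest.raises(ValidationError, match="A"):
            SubtaskRecording(
                task_kind="phonetic",
                transcripts={TranscriptLevel.F: [_tok("lev", 0, 1)],
                             TranscriptLevel.A: []},
            )

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            SubtaskRecording(
                task_kind="semantic",
                reference=[_tok("lev", 0.0, 2.0), _tok("miš", 1.0, 3.0)],
            )

    def test_beyond_duration_rejected(self):
        with pytest.raises(ValidationError, match="duration"):
            SubtaskRecording(task_kind="semantic", duration_s=10.0,
                             reference=[_tok("lev", 9.0, 11.0)])


class TestBundleIO:
    def test_round_trip_identity(self, tmp_path):
        session = _session()
        paths = write_session_bundle(session, tmp_path)
        back = read_session_bundle(paths["transcript"], paths["timestamps"])
        assert back == session

    def test_writes_are_deterministic(self, tmp_path):
        a = write_session_bundle(_session(), tmp_path / "a")
        b = write_session_bundle(_session(), tmp_path / "b")
        assert a["transcript"].read_bytes() == b["transcript"].read_bytes()
        assert a["timestamps"].read_bytes() == b["timestamps"].read_bytes()

    def test_handwritten_fixture_exact_floats(self, tmp_path):
        doc = {
            "subject": {"subject_id": "x", "group": "SH", "age": 33, "gender": "M"},
            "phonetic": {"task_kind": "phonetic", "duration_s": 60.0,
                         "reference": None,
                         "transcripts": {"U": [
                             {"text": "lev", "start_s": 1.25, "end_s": 1.75},
                             {"text": "led", "start_s": 4.5, "end_s": 5.0}]}},
            "semantic": {"task_kind": "semantic", "duration_s": 60.0,
                         "reference": None, "transcripts": {}},
            "acoustic": {},
        }
        tp = tmp_path / "x.json"
        tp.write_text(json.dumps(doc))
        ts = tmp_path / "x_timestamps.csv"
        ts.write_text("subject_id,task,start_s,end_s\n"
                      "x,phonetic,0.0,60.0\nx,semantic,65.0,125.0\n")
        session = read_session_bundle(tp, ts)
        toks = session.phonetic.transcripts[TranscriptLevel.U]
        assert [(t.text, t.start_s, t.end_s) for t in toks] == [
            ("lev", 1.25, 1.75), ("led", 4.5, 5.0)]

    def test_empty_filtered_level_round_trips(self, tmp_path):
        session = _session()
        session.phonetic.transcripts[TranscriptLevel.F] = []
        session.phonetic.transcripts[TranscriptLevel.A] = []
        paths = write_session_bundle(session, tmp_path)
        back = read_session_bundle(paths["transcript"], paths["timestamps"])
        assert back.phonetic.transcripts[TranscriptLevel.F] == []

    def test_bad_timestamp_row_rejected(self, tmp_path):
        session = _session()
        paths = write_session_bundle(session, tmp_path)
        paths["timestamps"].write_text(
            "subject_id,task,start_s,end_s\ns01,phonetic,10.0,5.0\n"
            "s01,semantic,65.0,125.0\n")
        with pytest.raises(ValidationError, match="exceed"):
            read_session_bundle(paths["transcript"], paths["timestamps"])

    def test_malformed_csv_names_row(self, tmp_path):
        session = _session()
        paths = write_session_bundle(session, tmp_path)
        paths["timestamps"].write_text(
            "subject_id,task,start_s,end_s\ns01,phonetic,abc,60.0\n")
        with pytest.raises(FormatError, match="row 2"):
            read_session_bundle(paths["transcript"], paths["timestamps"])


class TestSliceSubtasks:
    INDEX = TimestampIndex(phonetic=(0.0, 60.0), semantic=(61.0, 121.0))

    def test_rezeroes_to_subtask_onset(self):
        res = slice_subtasks([_tok("miš", 65.2, 65.8)], self.INDEX)
        assert res.semantic[0].start_s == pytest.approx(4.2)
        assert res.semantic[0].end_s == pytest.approx(4.8)

    def test_empty_stream(self):
        assert slice_subtasks([], self.INDEX) == SliceResult([], [], 0)

    def test_gap_token_dropped_and_counted(self):
        toks = [_tok("lev", 1, 2), _tok("les", 10, 11), _tok("hm", 60.5, 60.8),
                _tok("miš", 62, 63), _tok("pes", 70, 71)]
        res = slice_subtasks(toks, self.INDEX)
        assert len(res.phonetic) == 2 and len(res.semantic) == 2
        assert res.dropped == 1
        # conservation: assigned + dropped = input count
        assert len(res.phonetic) + len(res.semantic) + res.dropped == len(toks)

    def test_unsorted_rejected(self):
        with pytest.raises(ValidationError):
            slice_subtasks([_tok("b", 5, 6), _tok("a", 1, 2)], self.INDEX)

    def test_interval_order_enforced(self):
        with pytest.raises(ValidationError):
            TimestampIndex(phonetic=(10.0, 70.0), semantic=(5.0, 65.0))


class TestSelectTranscript:
    def test_returns_stored_sequence(self):
        session = _session()
        toks = select_transcript(session.phonetic, "U")
        assert toks is session.phonetic.transcripts[TranscriptLevel.U]

    def test_missing_level_named_in_error(self):
        sub = SubtaskRecording(task_kind="phonetic",
                               transcripts={TranscriptLevel.U: []})
        with pytest.raises(KeyError, match="A"):
            select_transcript(sub, TranscriptLevel.A)

    def test_refined_levels_equal_length(self, small_cohort):
        for session in small_cohort.sessions[:5]:
            for sub in (session.phonetic, session.semantic):
                assert len(select_transcript(sub, "A")) == len(select_transcript(sub, "F"))
                assert len(select_transcript(sub, "F")) <= len(select_transcript(sub, "U"))
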