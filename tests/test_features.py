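"""Feature engineering: worked values, invariants, purity."""

import numpy as np
import pytest

from vftk.corpus import Session, SubtaskRecording, TranscriptLevel, WordToken
from vftk.features import (
    FEATURE_IDS,
    FEATURE_SPEC,
    NONVERBAL_IDS,
    VERBAL_IDS,
    annotation_features,
    assemble_features,
    extract_features,
    inter_word_gaps,
    phonetic_coherence_features,
    semantic_similarity_features,
    temporal_features,
    transcript_adjustment_features,
)
from vftk.textsim import levenshtein_similarity


def _toks(texts, times=None, **kw):
    if times is None:
        times = [(i * 2.0, i * 2.0 + 0.5) for i in range(len(texts))]
    return [WordToken(t, s, e, **kw) for t, (s, e) in zip(texts, times)]


def _session(sem_tokens, phon_tokens, acoustic=None, age=40.0, gender="F"):
    def sub(kind, toks):
        return SubtaskRecording(task_kind=kind, transcripts={
            TranscriptLevel.U: toks, TranscriptLevel.F: toks,
            TranscriptLevel.A: toks})

    return Session("s1", "HC", age, gender, sub("phonetic", phon_tokens),
                   sub("semantic", sem_tokens),
                   acoustic=acoustic or {})


class TestFeatureRoster:
    def test_counts_per_family(self):
        families = [f.family for f in FEATURE_SPEC if f.id.startswith("V")]
        assert families.count("temporal") == 20
        assert families.count("semantic") == 17
        assert families.count("phonetic") == 2
        assert len(FEATURE_IDS) == 58

    def test_anchor_slots(self):
        by_id = {f.id: f.description for f in FEATURE_SPEC}
        assert "rate" in by_id["V1"] and "semantic" in by_id["V1"]
        assert "maximum" in by_id["V3"]
        assert "minimum" in by_id["V4"]
        assert "rate" in by_id["V16"] and "phonetic" in by_id["V16"]
        assert "max" in by_id["V23"]
        assert "kurtosis" in by_id["V26"]
        assert "mean" in by_id["V27"]
        assert "min" in by_id["V30"]
        assert "filtered" in by_id["V39"]


class TestInterWordGaps:
    def test_worked_example(self):
        toks = _toks(["a", "b"], [(1.0, 2.0), (4.0, 5.0)])
        assert inter_word_gaps(toks, 10.0).tolist() == [1.0, 2.0, 5.0]

    def test_empty_token_list(self):
        assert inter_word_gaps([], 60.0).tolist() == [60.0]

    def test_abutting_tokens_zero_interior_gaps(self):
        toks = _toks(["a", "b", "c"], [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)])
        assert inter_word_gaps(toks, 3.0).tolist() == [0.0, 0.0, 0.0, 0.0]


class TestTemporalFeatures:
    def test_semantic_rate(self):
        sem = _toks([f"w{i}" for i in range(12)],
                    [(i * 4.0, i * 4.0 + 0.5) for i in range(12)])
        s = _session(sem, _toks(["lev"]))
        feats = temporal_features(s, "A")
        assert feats["V1"] == pytest.approx(12 / 60)

    def test_max_gap_fraction_hits_designed_value(self):
        # one token leaves a 26.4 s trailing silence in a 60 s task
        sem = _toks(["lev", "pes"], [(0.0, 30.0), (33.0, 33.6)])
        s = _session(sem, _toks(["lev"]))
        assert temporal_features(s, "A")["V3"] == pytest.approx(26.4 / 60)
        assert temporal_features(s, "A")["V3"] == pytest.approx(0.44)

    def test_single_token_gap_stats_from_boundaries(self):
        sem = _toks(["lev"], [(10.0, 10.5)])
        s = _session(sem, _toks(["lev"]))
        feats = temporal_features(s, "A")
        assert feats["V4"] == pytest.approx(10.0 / 60)  # leading silence
        assert feats["V3"] == pytest.approx(49.5 / 60)


class TestSimilarityFeatures:
    def test_levenshtein_similarity_worked_values(self):
        assert levenshtein_similarity("kit", "kita") == pytest.approx(0.75)
        assert levenshtein_similarity("", "x") == 0.0
        assert levenshtein_similarity("lev", "lev") == 1.0

    def test_phonetic_series_worked_example(self):
        vals, imputed = phonetic_coherence_features(_toks(["lev", "lep", "luna"]))
        assert not imputed
        assert vals["V27"] == pytest.approx((2 / 3 + 0.25) / 2)
        assert vals["V30"] == pytest.approx(0.25)

    def test_identical_tokens_similarity_one(self):
        vals, _ = phonetic_coherence_features(_toks(["lev", "lev", "lev"]))
        assert vals["V27"] == vals["V30"] == 1.0

    def test_repeated_word_max_semantic_similarity(self):
        vals, _ = semantic_similarity_features(_toks(["pes", "pes"]))
        assert vals["V23"] == pytest.approx(1.0)

    def test_alternating_series_kurtosis(self):
        """A symmetric two-point similarity distribution has excess
        kurtosis -2 (closed form)."""
        series_vals, _ = semantic_similarity_features(
            _toks([str(i) for i in range(21)]),
            provider=lambda a, b: 0.9 if (int(b) % 2 == 0) else 0.1,
        )
        assert series_vals["V26"] == pytest.approx(-2.0, abs=1e-9)

    def test_constant_series_zero_kurtosis_convention(self):
        vals, _ = semantic_similarity_features(_toks(["pes"] * 5))
        assert vals["V26"] == 0.0

    def test_single_token_imputed(self):
        vals, imputed = phonetic_coherence_features(_toks(["lev"]))
        assert imputed and all(v == 0.0 for v in vals.values())


class TestAdjustmentFeatures:
    def test_identity_maximal_similarity(self):
        f = _toks(["lev", "les"])
        assert transcript_adjustment_features(f, f) == {"V38": 0.0, "V39": 1.0}

    def test_single_character_change(self):
        f = _toks([f"word{i}" for i in range(10)])
        a = list(f)
        a[3] = WordToken("wordx", f[3].start_s, f[3].end_s)
        vals = transcript_adjustment_features(f, a)
        joined_len = len(" ".join(t.text for t in f))
        assert vals["V38"] == pytest.approx(0.1)
        assert vals["V39"] == pytest.approx(1 - 1 / joined_len)

    def test_every_token_replaced(self):
        f = _toks(["lev", "les"])
        a = _toks(["kit", "pes"])
        assert transcript_adjustment_features(f, a)["V38"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            transcript_adjustment_features(_toks(["a"]), _toks(["a", "b"]))


class TestAnnotationFeatures:
    def test_proportions(self):
        sem = _toks(["pes"] * 18) + _toks(["miza", "okno"],
                                          [(40.0, 40.5), (42.0, 42.5)],
                                          is_intrusion=True)
        s = _session(sem, _toks(["lev"]))
        vals = annotation_features(s)
        assert vals["V33"] == pytest.approx(2 / 20)
        assert vals["V32"] == 0.0

    def test_saturation(self):
        sem = _toks(["miza"] * 4, is_intrusion=True)
        s = _session(sem, _toks(["lev"]))
        assert annotation_features(s)["V33"] == 1.0


class TestAssembly:
    def _full_session(self):
        acoustic = {f"N{i}": float(i) for i in range(1, 18)}
        return _session(_toks(["pes", "kit", "lev"]), _toks(["lev", "les"]),
                        acoustic=acoustic)

    def test_full_vector_58(self):
        fv = assemble_features(self._full_session())
        assert len(fv.values) == 58
        assert fv.ids == FEATURE_IDS

    def test_verbal_only_39(self):
        fv = assemble_features(self._full_session(), feature_set="verbal")
        assert len(fv.values) == 39
        assert fv.ids == VERBAL_IDS

    def test_nonverbal_only_17(self):
        fv = assemble_features(self._full_session(), feature_set="nonverbal")
        assert len(fv.values) == 17
        assert fv.ids == NONVERBAL_IDS

    def test_unknown_acoustic_id_rejected(self):
        s = self._full_session()
        s.acoustic["Q9"] = 1.0
        with pytest.raises(ValueError, match="Q9"):
            assemble_features(s)

    def test_missing_acoustic_imputed(self):
        s = self._full_session()
        del s.acoustic["N5"]
        fv = assemble_features(s)
        assert "N5" in fv.imputed
        assert fv.values[fv.ids.index("N5")] == 0.0

    def test_extraction_is_pure(self, small_cohort):
        df1 = extract_features(small_cohort.sessions[:6])
        df2 = extract_features(small_cohort.sessions[:6])
        assert df1.equals(df2)

    def test_fraction_features_in_unit_interval(self, small_cohort):
        df = extract_features(small_cohort.sessions)
        frac_ids = [f"V{i}" for i in list(range(1, 8)) + [10, 11, 12, 13, 14, 15, 17, 20]
                    if f"V{i}" != "V1"]
        frac_ids += [f"V{i}" for i in range(21, 26)] + [f"V{i}" for i in range(27, 31)]
        frac_ids += [f"V{i}" for i in range(32, 39)] + ["V39"]
        for fid in frac_ids:
            assert df[fid].between(0, 1).all(), fid

    def test_directional_pattern_matches_anchors(self, default_cohort):
        """Group means reproduce the anchored directional pattern:
        HC > SH for V1, V16, V27, V30, V39; SH > HC for V3."""
        df = extract_features(default_cohort.sessions)
        means = df.groupby("group")[["V1", "V3", "V16", "V27", "V30", "V39"]].mean()
        for fid in ("V1", "V16", "V27", "V30", "V39"):
            assert means.loc["HC", fid] > means.loc["SH", fid], fid
        assert means.loc["SH", "V3"] > means.loc["HC", "V3"]
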