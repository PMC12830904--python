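"""Cohort generator: determinism, rate recovery, level structure."""

import numpy as np
import pytest

from vftk.corpus import TranscriptLevel
from vftk.synthesis import (
    CohortConfig,
    corrupt_to_asr,
    default_config,
    derive_levels,
    generate_cohort,
    generate_subtask,
    write_cohort,
)


class TestDefaultConfig:
    def test_published_group_sizes(self):
        cfg = default_config()
        assert (cfg.n_hc, cfg.n_sh) == (68, 58)

    def test_calibrated_rates_and_means(self):
        cfg = default_config()
        assert cfg.hc.intrusion_rate["semantic"] == pytest.approx(0.0278)
        assert cfg.sh.intrusion_rate["semantic"] == pytest.approx(0.0853)
        assert cfg.hc.word_rate["semantic"][0] == pytest.approx(0.36)
        assert cfg.sh.max_gap_frac["semantic"][0] == pytest.approx(0.44)
        assert cfg.hc.acoustic["N10"][0] == pytest.approx(405.84)

    def test_invalid_rates_rejected(self):
        cfg = default_config()
        cfg.hc.intrusion_rate["semantic"] = 1.2
        with pytest.raises(ValueError):
            cfg.hc.__post_init__()

    def test_minimal_cohort(self):
        cohort = generate_cohort(default_config(seed=3, n_hc=1, n_sh=1))
        assert len(cohort.sessions) == 2
        assert {s.group for s in cohort.sessions} == {"HC", "SH"}

    def test_group_size_invariant(self):
        with pytest.raises(ValueError):
            CohortConfig(n_hc=0, n_sh=5, seed=0,
                         hc=default_config().hc, sh=default_config().sh)


class TestDeterminism:
    def test_identical_configs_identical_cohorts(self, tmp_path):
        a = generate_cohort(default_config(seed=42, n_hc=3, n_sh=3))
        b = generate_cohort(default_config(seed=42, n_hc=3, n_sh=3))
        assert a.sessions == b.sessions
        assert a.truth.equals(b.truth)
        da = write_cohort(a, tmp_path / "a")
        db = write_cohort(b, tmp_path / "b")
        for pa in sorted(da.glob("*")):
            assert pa.read_bytes() == (db / pa.name).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(default_config(seed=1, n_hc=2, n_sh=2))
        b = generate_cohort(default_config(seed=2, n_hc=2, n_sh=2))
        assert a.sessions != b.sessions


class TestGenerateSubtask:
    def test_intrusion_rate_recovery(self, lexicons, rng):
        """Injected semantic intrusion share recovers the configured
        rate within 3 binomial SEs over many subtasks."""
        params = default_config().sh
        rate = params.intrusion_rate["semantic"]
        hits = total = 0
        for _ in range(400):
            sub, truth = generate_subtask(params, "semantic", rng, lexicons)
            hits += truth["n_intrusions"]
            total += truth["n_tokens"]
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(hits / total - rate) < 3 * se

    def test_saturated_intrusions_all_off_lexicon(self, lexicons, rng):
        params = default_config().sh
        params.intrusion_rate = {"phonetic": 1.0, "semantic": 1.0}
        params.neologism_rate = {"phonetic": 0.0, "semantic": 0.0}
        params.stilted_rate = {"phonetic": 0.0, "semantic": 0.0}
        sub, _ = generate_subtask(params, "semantic", rng, lexicons)
        assert all(t.text not in lexicons.animals for t in sub.reference)
        assert all(t.is_intrusion for t in sub.reference)

    def test_no_long_pause_component(self, lexicons, rng):
        """With the long-pause component disabled and a tiny body scale,
        the maximum gap stays near the body distribution's maximum."""
        params = default_config().hc
        params.long_pause_prob = 0.0
        params.gap_sigma = 0.05
        fracs = [generate_subtask(params, "semantic", rng, lexicons)[1]["max_gap_frac"]
                 for _ in range(40)]
        with_pause = default_config().sh
        ref = [generate_subtask(with_pause, "semantic", rng, lexicons)[1]["max_gap_frac"]
               for _ in range(40)]
        assert np.mean(fracs) < np.mean(ref)

    def test_rate_means_recover_configured(self, lexicons, rng):
        """Empirical mean semantic phrase rate is within 3 SEs of the
        configured group mean (CLT bound)."""
        for group in ("hc", "sh"):
            params = getattr(default_config(), group)
            mean, sd = params.word_rate["semantic"]
            n = 200
            rates = [generate_subtask(params, "semantic", rng, lexicons)[1]["rate"]
                     for _ in range(n)]
            assert abs(np.mean(rates) - mean) < 3 * sd / np.sqrt(n) + 1 / 60


class TestCorruptToAsr:
    def test_zero_rates_identity(self, lexicons, rng):
        params = default_config().hc
        for k in ("asr_substitution_rate", "asr_deletion_rate",
                  "asr_filler_insertion_rate"):
            setattr(params, k, {"phonetic": 0.0, "semantic": 0.0})
        sub, _ = generate_subtask(params, "phonetic", rng, lexicons)
        u, counts = corrupt_to_asr(sub.reference, params, "phonetic", rng, lexicons)
        assert [t.text for t in u] == [t.text for t in sub.reference]
        assert counts == {"substitutions": 0, "deletions": 0, "insertions": 0}

    def test_total_deletion_empties_transcript(self, lexicons, rng):
        params = default_config().hc
        params.asr_deletion_rate = {"phonetic": 1.0, "semantic": 1.0}
        params.asr_substitution_rate = {"phonetic": 0.0, "semantic": 0.0}
        sub, _ = generate_subtask(params, "phonetic", rng, lexicons)
        params.asr_filler_insertion_rate = {"phonetic": 0.0, "semantic": 0.0}
        u, _ = corrupt_to_asr(sub.reference, params, "phonetic", rng, lexicons)
        assert u == []

    def test_expected_edit_ops_per_token(self, lexicons, rng):
        """Mean achieved ops per reference token matches s + d + i."""
        params = default_config().hc
        params.asr_substitution_rate = {"semantic": 0.1, "phonetic": 0.1}
        params.asr_deletion_rate = {"semantic": 0.1, "phonetic": 0.1}
        params.asr_filler_insertion_rate = {"semantic": 0.05, "phonetic": 0.05}
        ops = total = 0
        while total < 5000:
            sub, _ = generate_subtask(params, "semantic", rng, lexicons)
            _, counts = corrupt_to_asr(sub.reference, params, "semantic", rng, lexicons)
            ops += sum(counts.values())
            total += len(sub.reference)
        expected = 0.25
        se = np.sqrt(expected / total)  # Poisson-style bound
        assert abs(ops / total - expected) < 3 * se

    def test_rates_exceeding_one_rejected(self):
        cfg = default_config()
        cfg.hc.asr_substitution_rate["semantic"] = 0.7
        cfg.hc.asr_deletion_rate["semantic"] = 0.6
        with pytest.raises(ValueError, match="exceed 1"):
            cfg.hc.__post_init__()


class TestDeriveLevels:
    def test_no_fillers_full_retention(self, lexicons, rng):
        params = default_config().hc
        params.asr_filler_insertion_rate = {"phonetic": 0.0, "semantic": 0.0}
        params.asr_substitution_rate = {"phonetic": 0.0, "semantic": 0.0}
        params.asr_deletion_rate = {"phonetic": 0.0, "semantic": 0.0}
        params.intrusion_rate = {"phonetic": 0.0, "semantic": 0.0}
        params.neologism_rate = {"phonetic": 0.0, "semantic": 0.0}
        sub, _ = generate_subtask(params, "phonetic", rng, lexicons)
        u, _ = corrupt_to_asr(sub.reference, params, "phonetic", rng, lexicons)
        f, a = derive_levels(u, "phonetic", lexicons)
        assert len(f) == len(u)
        assert [t.text for t in a] == [t.text for t in f]

    def test_wacc_ordering_over_sessions(self, small_cohort):
        from vftk.asr_metrics import session_wacc

        u, f, a = (
            np.mean([session_wacc(s, lvl) for s in small_cohort.sessions])
            for lvl in (TranscriptLevel.U, TranscriptLevel.F, TranscriptLevel.A)
        )
        assert u < f <= a


class TestGroupStructure:
    def test_semantic_rate_separation(self, small_cohort):
        t = small_cohort.truth.groupby("group")["sem_rate"].mean()
        assert t["HC"] > t["SH"]

    def test_max_gap_direction(self, small_cohort):
        t = small_cohort.truth.groupby("group")["sem_max_gap_frac"].mean()
        assert t["SH"] > t["HC"]

    def test_every_session_valid_and_counted(self, small_cohort):
        assert len(small_cohort.sessions) == 40
        for s in small_cohort.sessions:
            s.phonetic.validate()
            s.semantic.validate()
            assert set(s.acoustic) == {f"N{i}" for i in range(1, 18)}

    def test_truth_and_acoustic_files(self, tmp_path, small_cohort):
        out = write_cohort(small_cohort, tmp_path)
        assert (out / "truth.csv").exists()
        header = (out / "acoustic.csv").read_text().splitlines()[0]
        assert header.split(",")[:2] == ["subject_id", "N1"]
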