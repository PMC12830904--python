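"""Two-group synthetic cohort generator.

Generates verbal-fluency sessions (manual-style reference transcripts
plus U/F/A automatic transcripts, an acoustic feature table, and
demographics) with the statistical structure the downstream analysis
assumes: group-dependent word production rates and pause structure,
injected intrusions/neologisms/stilted words at configured rates, and
ASR-style corruption that yields group-separated word accuracy.

Default parameters are calibrated to the published group summaries in
:mod:`vftk.calibration`; distributional families are artifact choices
documented in ``docs/methods.md``.  Per-subject latent draws are stored
as *truth* so parameter-recovery tests can compare what the pipeline
measures against what the generator injected.

The timing model per subtask: the subject produces ``n`` words
(``n``/60 s is lognormal with the group's configured mean and SD, so
configured means are reproduced in expectation), word durations are
truncated normal, and the n+1 silent gaps (leading, inter-word,
trailing) are a lognormal body plus one designated long pause whose
fraction of the task duration is a beta draw around the group's
maximum-gap target.  Gaps are rescaled to exactly fill the task window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from .annotate import annotate_session, refine_transcript
from .corpus import Session, SubtaskRecording, TranscriptLevel, WordToken, write_session_bundle
from .lexicons import LexiconPack, load_default_lexicons
from .textsim import bigram_cosine, levenshtein_similarity

__all__ = [
    "GroupParams",
    "CohortConfig",
    "GeneratedCohort",
    "generate_subtask",
    "corrupt_to_asr",
    "derive_levels",
    "generate_cohort",
    "write_cohort",
    "default_config",
]

TASKS = ("phonetic", "semantic")
ALPHABET = "abcdefghijklmnoprstuvzčšž"
NEOLOGISM_SUFFIXES = ("ing", "er", "asto", "ilna")


def _check_rates(d: dict[str, float], what: str) -> None:
    for task, r in d.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{what}[{task}] = {r} outside [0, 1]")


@dataclass
class GroupParams:
    """Generative parameters for one diagnostic group."""

    # (mean, sd) of words per second over the 60 s task; lognormal.
    word_rate: dict[str, tuple[float, float]]
    # (mean, sd) of the designated long pause as a fraction of duration; beta.
    max_gap_frac: dict[str, tuple[float, float]]
    # probability of choosing the most-similar candidate word next
    cluster_prob: dict[str, float]
    # probability of a derailed transition (least-similar candidate next)
    derail_prob: dict[str, float]
    # annotation injection rates per token
    intrusion_rate: dict[str, float]
    neologism_rate: dict[str, float]
    stilted_rate: dict[str, float]
    # ASR corruption rates per reference token
    asr_substitution_rate: dict[str, float]
    asr_deletion_rate: dict[str, float]
    asr_filler_insertion_rate: dict[str, float]
    # acoustic feature table: name -> (mean, sd); drawn normal
    acoustic: dict[str, tuple[float, float]]
    # shape of the lognormal gap body
    gap_sigma: float = 0.7
    # probability that the designated long pause is injected at all
    long_pause_prob: float = 1.0
    # probability a substituted token is mutated at edit distance 2 (else 1)
    sub_dist2_prob: float = 0.15
    token_dur: tuple[float, float] = (0.45, 0.08)
    # minimum consecutive similarity an organized speaker tolerates on a
    # uniform transition (0 disables the floor)
    coherence_floor: dict[str, float] | None = None
    age: tuple[float, float] = (46.0, 13.0)
    gender_split: float = 0.5  # fraction female

    def __post_init__(self) -> None:
        for name in ("intrusion_rate", "neologism_rate", "stilted_rate",
                     "asr_substitution_rate", "asr_deletion_rate",
                     "asr_filler_insertion_rate", "cluster_prob", "derail_prob"):
            _check_rates(getattr(self, name), name)
        for task in TASKS:
            if self.asr_substitution_rate[task] + self.asr_deletion_rate[task] > 1.0:
                raise ValueError("per-token substitution + deletion rates exceed 1")
            total = (self.intrusion_rate[task] + self.neologism_rate[task]
                     + self.stilted_rate[task])
            if total > 1.0:
                raise ValueError("per-token annotation injection rates exceed 1")
            for m, s in (self.word_rate[task], self.max_gap_frac[task]):
                if m <= 0 or s < 0:
                    raise ValueError("means must be positive and sds non-negative")


@dataclass
class CohortConfig:
    n_hc: int
    n_sh: int
    seed: int
    hc: GroupParams
    sh: GroupParams

    def __post_init__(self) -> None:
        if self.n_hc < 1 or self.n_sh < 1:
            raise ValueError("need at least one subject per group")


@dataclass
class GeneratedCohort:
    sessions: list[Session]
    truth: pd.DataFrame  # one row per subject: latent draws and injected counts
    config: CohortConfig


# ---------------------------------------------------------------------------
# token-level machinery


def _lognormal_with_moments(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One lognormal draw with the given arithmetic mean and SD."""
    if sd == 0.0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _beta_with_moments(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One beta draw with the given mean and (feasibility-capped) SD."""
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    cap = 0.8 * np.sqrt(mean * (1 - mean))
    sd = min(sd, cap) if sd > 0 else cap * 0.1
    nu = mean * (1 - mean) / sd**2 - 1.0
    return float(rng.beta(mean * nu, (1 - mean) * nu))


def _mutate(text: str, distance: int, rng: np.random.Generator) -> str:
    """Apply ``distance`` random character edits, never a no-op."""
    chars = list(text)
    for _ in range(distance):
        ops = ["sub", "ins"] + (["del"] if len(chars) > 2 else [])
        op = ops[rng.integers(len(ops))]
        if op == "sub":
            i = int(rng.integers(len(chars)))
            choices = [c for c in ALPHABET if c != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
        elif op == "ins":
            i = int(rng.integers(len(chars) + 1))
            chars.insert(i, ALPHABET[rng.integers(len(ALPHABET))])
        else:
            chars.pop(int(rng.integers(len(chars))))
    out = "".join(chars)
    return out if out and out != text else text + ALPHABET[rng.integers(len(ALPHABET))]


def _make_neologism(base: str, lexicons: LexiconPack, rng: np.random.Generator) -> str:
    for suffix in NEOLOGISM_SUFFIXES:
        cand = base + suffix
        if not lexicons.known(cand):
            return cand
    return base + "xx"  # no packaged word ends in 'xx'


def _draw_words(
    n: int,
    task_kind: str,
    cluster_prob: float,
    derail_prob: float,
    lexicons: LexiconPack,
    rng: np.random.Generator,
    coherence_floor: float = 0.0,
) -> list[str]:
    """Draw a word sequence without immediate repetition.

    With probability ``cluster_prob`` the next word is the candidate most
    similar to the previous one (phonological clustering in the phonetic
    task, semantic-neighborhood clustering in the semantic task); with
    probability ``derail_prob`` it is the least similar one (an
    incoherent transition, depressing the minimum consecutive
    similarity); otherwise it is a uniform draw.
    """
    pool = sorted(lexicons.task_lexicon(task_kind))
    sim = levenshtein_similarity if task_kind == "phonetic" else bigram_cosine
    words = [pool[rng.integers(len(pool))]]
    for _ in range(n - 1):
        candidates = [pool[i] for i in rng.integers(len(pool), size=12)]
        candidates = [w for w in candidates if w != words[-1]] or [
            pool[(pool.index(words[-1]) + 1) % len(pool)]
        ]
        u = rng.random()
        if u < cluster_prob:
            nxt = max(candidates, key=lambda w: sim(words[-1], w))
        elif u < cluster_prob + derail_prob:
            nxt = min(candidates, key=lambda w: sim(words[-1], w))
        else:
            nxt = candidates[0]
            if sim(words[-1], nxt) < coherence_floor:
                nxt = max(candidates, key=lambda w: sim(words[-1], w))
        words.append(nxt)
    return words


def generate_subtask(
    params: GroupParams,
    task_kind: str,
    rng: np.random.Generator,
    lexicons: LexiconPack | None = None,
    duration_s: float = 60.0,
) -> tuple[SubtaskRecording, dict[str, float]]:
    """Generate one subtask's reference transcript plus its latent truth."""
    lexicons = lexicons or load_default_lexicons()
    pool = lexicons.task_lexicon(task_kind)
    if not pool:
        raise ValueError(f"empty task lexicon for {task_kind}")

    rate = _lognormal_with_moments(*params.word_rate[task_kind], rng)
    n = max(1, int(round(rate * duration_s)))

    floor = (params.coherence_floor or {}).get(task_kind, 0.0)
    words = _draw_words(n, task_kind, params.cluster_prob[task_kind],
                        params.derail_prob[task_kind], lexicons, rng,
                        coherence_floor=floor)

    # annotation injection: one categorical draw per token
    p_int = params.intrusion_rate[task_kind]
    p_neo = params.neologism_rate[task_kind]
    p_sti = params.stilted_rate[task_kind]
    offtask = sorted(lexicons.offtask)
    formal_task = sorted(lexicons.formal_register & pool)
    flags: list[tuple[bool, bool, bool]] = []
    texts: list[str] = []
    n_int = n_neo = n_sti = 0
    for w in words:
        u = rng.random()
        if u < p_int:
            texts.append(offtask[rng.integers(len(offtask))])
            flags.append((True, False, False))
            n_int += 1
        elif u < p_int + p_neo:
            texts.append(_make_neologism(w, lexicons, rng))
            flags.append((False, False, True))
            n_neo += 1
        elif u < p_int + p_neo + p_sti and formal_task:
            texts.append(formal_task[rng.integers(len(formal_task))])
            flags.append((False, True, False))
            n_sti += 1
        else:
            texts.append(w)
            flags.append((False, False, False))

    # timing: durations + n+1 gaps (leading, inter-word, trailing)
    durs = np.clip(rng.normal(*params.token_dur, size=n), 0.15, 0.9)
    budget = duration_s - durs.sum()
    if budget < 0.05 * (n + 1):
        durs *= (duration_s * 0.6) / durs.sum()
        budget = duration_s - durs.sum()
    gaps = rng.lognormal(0.0, params.gap_sigma, size=n + 1)
    long_slot = -1
    if rng.random() < params.long_pause_prob:
        frac = _beta_with_moments(*params.max_gap_frac[task_kind], rng)
        long_gap = min(frac * duration_s, 0.95 * budget)
        long_slot = int(rng.integers(n + 1))
        others = np.delete(gaps, long_slot)
        others *= (budget - long_gap) / others.sum()
        gaps = np.insert(others, long_slot, long_gap)
    else:
        gaps *= budget / gaps.sum()

    tokens: list[WordToken] = []
    t = 0.0
    for i in range(n):
        t += gaps[i]
        is_int, is_sti, is_neo = flags[i]
        tokens.append(
            WordToken(
                text=texts[i],
                start_s=round(t, 4),
                end_s=round(min(t + durs[i], duration_s), 4),
                is_intrusion=is_int,
                is_stilted=is_sti,
                is_neologism=is_neo,
            )
        )
        t += durs[i]

    truth = {
        "task": task_kind,
        "rate": n / duration_s,
        "max_gap_frac": float(np.max(gaps)) / duration_s,
        "n_tokens": n,
        "n_intrusions": n_int,
        "n_neologisms": n_neo,
        "n_stilted": n_sti,
    }
    sub = SubtaskRecording(task_kind=task_kind, duration_s=duration_s, reference=tokens)
    return sub, truth


def corrupt_to_asr(
    reference: Sequence[WordToken],
    params: GroupParams,
    task_kind: str,
    rng: np.random.Generator,
    lexicons: LexiconPack | None = None,
) -> tuple[list[WordToken], dict[str, int]]:
    """Apply ASR-style corruption to a reference transcript.

    Per reference token: deletion with rate d, text substitution with
    rate s (a random character edit at distance 1, or 2 with probability
    ``sub_dist2_prob``), and filler insertion with rate i (filler placed
    in the silent gap before the token, timestamps interpolated).
    Returns the unprocessed (U) token sequence, all annotation flags
    cleared, plus achieved edit-operation counts.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    lexicons = lexicons or load_default_lexicons()
    s_rate = params.asr_substitution_rate[task_kind]
    d_rate = params.asr_deletion_rate[task_kind]
    i_rate = params.asr_filler_insertion_rate[task_kind]
    fillers = sorted(lexicons.fillers)
    out: list[WordToken] = []
    counts = {"substitutions": 0, "deletions": 0, "insertions": 0}
    prev_end = 0.0
    for tok in reference:
        if rng.random() < i_rate:
            pos = max(prev_end, tok.start_s - 0.3)
            end = max(pos, min(tok.start_s, pos + 0.25))
            out.append(WordToken(text=fillers[rng.integers(len(fillers))],
                                 start_s=round(pos, 4), end_s=round(end, 4)))
            counts["insertions"] += 1
        u = rng.random()
        if u < d_rate:
            counts["deletions"] += 1
            prev_end = tok.end_s
            continue
        text = tok.text
        if u < d_rate + s_rate:
            dist = 2 if rng.random() < params.sub_dist2_prob else 1
            text = _mutate(text, dist, rng)
            counts["substitutions"] += 1
        out.append(WordToken(text=text, start_s=tok.start_s, end_s=tok.end_s))
        prev_end = tok.end_s
    return out, counts


def derive_levels(
    u_tokens: Sequence[WordToken],
    task_kind: str,
    lexicons: LexiconPack | None = None,
) -> tuple[list[WordToken], list[WordToken]]:
    """Derive the filtered (F) and adjusted (A) transcripts from U.

    Delegates to the pipeline's own mock refinement so generated levels
    obey exactly the contracts the downstream stages assume.
    """
    lexicons = lexicons or load_default_lexicons()
    res = refine_transcript(u_tokens, task_kind, lexicons)
    return list(res.filtered), list(res.adjusted)


def _generate_session(
    subject_id: str,
    group: str,
    params: GroupParams,
    rng: np.random.Generator,
    lexicons: LexiconPack,
) -> tuple[Session, dict]:
    subtasks = {}
    truth: dict = {"subject_id": subject_id, "group": group}
    for task in TASKS:
        sub, t = generate_subtask(params, task, rng, lexicons)
        u, _ = corrupt_to_asr(sub.reference, params, task, rng, lexicons)
        f, a = derive_levels(u, task, lexicons)
        sub.transcripts = {
            TranscriptLevel.U: u,
            TranscriptLevel.F: f,
            TranscriptLevel.A: a,
        }
        sub.validate()
        subtasks[task] = sub
        prefix = "phon" if task == "phonetic" else "sem"
        for k, v in t.items():
            if k != "task":
                truth[f"{prefix}_{k}"] = v
    acoustic = {
        name: float(rng.normal(mu, sd)) for name, (mu, sd) in sorted(params.acoustic.items())
    }
    age = float(np.clip(rng.normal(*params.age), 18.0, 90.0))
    gender = "F" if rng.random() < params.gender_split else "M"
    session = Session(
        subject_id=subject_id,
        group=group,
        age=round(age, 1),
        gender=gender,
        phonetic=subtasks["phonetic"],
        semantic=subtasks["semantic"],
        acoustic=acoustic,
    )
    truth.update({f"true_{k}": v for k, v in acoustic.items()})
    annotate_session(session, lexicons)  # tag the adjusted transcripts
    return session, truth


def generate_cohort(
    config: CohortConfig, lexicons: LexiconPack | None = None
) -> GeneratedCohort:
    """Generate a full two-group cohort, deterministic under the seed."""
    lexicons = lexicons or load_default_lexicons()
    n_total = config.n_hc + config.n_sh
    streams = np.random.SeedSequence(config.seed).spawn(n_total)
    sessions, rows = [], []
    specs = [("hc", "HC", config.hc, i) for i in range(config.n_hc)] + [
        ("sh", "SH", config.sh, i) for i in range(config.n_sh)
    ]
    for stream, (prefix, group, params, i) in zip(streams, specs):
        rng = np.random.default_rng(stream)
        session, truth = _generate_session(
            f"{prefix}{i + 1:03d}", group, params, rng, lexicons
        )
        sessions.append(session)
        rows.append(truth)
    return GeneratedCohort(
        sessions=sessions, truth=pd.DataFrame(rows), config=config
    )


def write_cohort(cohort: GeneratedCohort, out_dir: str | Path) -> Path:
    """Write session bundles plus ``truth.csv`` and ``acoustic.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for session in cohort.sessions:
        write_session_bundle(session, out_dir)
    cohort.truth.to_csv(out_dir / "truth.csv", index=False)
    acoustic_names = sorted(cohort.sessions[0].acoustic)
    pd.DataFrame(
        [
            {"subject_id": s.subject_id, **{k: s.acoustic[k] for k in acoustic_names}}
            for s in cohort.sessions
        ]
    ).to_csv(out_dir / "acoustic.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# default calibration


def _acoustic_defaults(group: str) -> dict[str, tuple[float, float]]:
    anchored = {
        name: cal.anchor_mean_sd(name, group) for name in ("N3", "N8", "N10")
    }
    # non-anchored descriptors: artifact choices with modest separation
    artifact = {
        "HC": {
            "N1": (38.0, 4.0), "N2": (3.2, 1.0), "N4": (0.26, 0.08),
            "N5": (-310.0, 150.0), "N6": (170.0, 30.0), "N7": (0.45, 0.12),
            "N9": (7.5, 2.5), "N11": (0.018, 0.008), "N12": (0.9, 0.3),
            "N13": (1.8, 0.5), "N14": (0.85, 0.25), "N15": (0.012, 0.006),
            "N16": (0.008, 0.004), "N17": (0.006, 0.003),
        },
        "SH": {
            "N1": (36.0, 4.0), "N2": (2.4, 1.0), "N4": (0.18, 0.08),
            "N5": (-190.0, 120.0), "N6": (160.0, 30.0), "N7": (0.35, 0.12),
            "N9": (4.8, 2.5), "N11": (0.026, 0.008), "N12": (1.1, 0.3),
            "N13": (1.3, 0.5), "N14": (0.60, 0.25), "N15": (0.019, 0.006),
            "N16": (0.012, 0.004), "N17": (0.010, 0.003),
        },
    }[group]
    return {**anchored, **artifact}


def _asr_defaults(group: str) -> dict[str, dict[str, float]]:
    """Corruption rates derived from the calibration anchors.

    Substitution rate from the corrected-token fraction (1 - overlap),
    deletion from the filtered-level word-accuracy deficit, insertion
    from the retention identity i = (1 - d)(1 - r) / r.
    """
    dist2 = 0.15
    sub, dele, ins = {}, {}, {}
    f_err = 1.0 - cal.WACC_MEANS[group]["F"]  # = s + d at the filtered level
    for task in TASKS:
        corrected = 1.0 - cal.OVERLAP_PCT[(group, task)] / 100.0
        s = corrected / (1.0 - dist2)
        d = max(f_err - s, 0.02)
        r = cal.RETENTION_PCT[(group, task)] / 100.0
        i = (1.0 - d) * (1.0 - r) / r
        sub[task], dele[task], ins[task] = round(s, 4), round(d, 4), round(i, 4)
    return {"sub": sub, "del": dele, "ins": ins, "dist2": dist2}


def _group_defaults(group: str) -> GroupParams:
    asr = _asr_defaults(group)
    # phonetic long-pause targets have no published anchor
    phon_gap = {"HC": (0.25, 0.10), "SH": (0.45, 0.18)}[group]
    cluster = {
        "HC": {"phonetic": 0.60, "semantic": 0.50},
        "SH": {"phonetic": 0.15, "semantic": 0.20},
    }[group]
    derail = {
        "HC": {"phonetic": 0.02, "semantic": 0.02},
        "SH": {"phonetic": 0.35, "semantic": 0.35},
    }[group]
    floor = {
        "HC": {"phonetic": 0.20, "semantic": 0.15},
        "SH": {"phonetic": 0.0, "semantic": 0.0},
    }[group]
    return GroupParams(
        word_rate={
            "phonetic": cal.anchor_mean_sd("V16", group),
            "semantic": cal.anchor_mean_sd("V1", group),
        },
        max_gap_frac={
            "phonetic": phon_gap,
            "semantic": cal.anchor_mean_sd("V3", group),
        },
        cluster_prob=cluster,
        derail_prob=derail,
        coherence_floor=floor,
        intrusion_rate={
            t: cal.INTRUSION_PCT[(group, t)] / 100.0 for t in TASKS
        },
        neologism_rate={
            t: cal.NEOLOGISM_PCT[(group, t)] / 100.0 for t in TASKS
        },
        stilted_rate={"phonetic": 0.005 if group == "HC" else 0.02,
                      "semantic": 0.005 if group == "HC" else 0.02},
        asr_substitution_rate=asr["sub"],
        asr_deletion_rate=asr["del"],
        asr_filler_insertion_rate=asr["ins"],
        sub_dist2_prob=asr["dist2"],
        acoustic=_acoustic_defaults(group),
        age=(46.0, 13.0) if group == "HC" else (45.0, 12.0),
        gender_split=33 / 68 if group == "HC" else 29 / 58,
    )


def default_config(seed: int = 0, n_hc: int | None = None, n_sh: int | None = None) -> CohortConfig:
    """Cohort configuration calibrated to the published group summaries."""
    return CohortConfig(
        n_hc=cal.GROUP_N["HC"] if n_hc is None else n_hc,
        n_sh=cal.GROUP_N["SH"] if n_sh is None else n_sh,
        seed=seed,
        hc=_group_defaults("HC"),
        sh=_group_defaults("SH"),
    )
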