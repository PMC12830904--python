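"""Per-participant feature engineering: the 58-entry feature vector.

39 verbal features are computed from the transcripts (by default at the
adjusted level, the pipeline's final refinement stage):

* V1-V20, temporal — per task: phrase production rate, gap-series
  summaries as fractions of the task duration (the gap series includes
  the leading and trailing silences, so a subject who falls silent late
  in the task registers a long maximum pause), total speech time, token
  duration summaries;
* V21-V37, semantic — consecutive-utterance similarity series for both
  tasks (semantic similarity via a pluggable provider, phonetic
  similarity via normalized Levenshtein) plus intrusion / neologism /
  stilted proportions per task;
* V38-V39, phonetic — the extent of post-processing corrections:
  corrected-token fraction and the Levenshtein similarity between the
  joined filtered and adjusted transcripts.

17 non-verbal features (N1-N17) are ingested from an acoustic feature
table (or computed from F0 tracks by :mod:`vftk.acoustics`); AGE and
GENDER complete the vector.

Degenerate inputs (fewer than two tokens for a similarity series, no
voiced frames) are imputed with the neutral value 0 and flagged;
downstream Z-scoring keeps imputed values uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .corpus import Session, SubtaskRecording, TranscriptLevel, WordToken
from .textsim import get_similarity_provider, levenshtein_similarity

__all__ = [
    "FeatureSpec",
    "FEATURE_SPEC",
    "FEATURE_IDS",
    "VERBAL_IDS",
    "NONVERBAL_IDS",
    "FeatureVector",
    "inter_word_gaps",
    "temporal_features",
    "phonetic_coherence_features",
    "semantic_similarity_features",
    "transcript_adjustment_features",
    "annotation_features",
    "assemble_features",
    "extract_features",
]


@dataclass(frozen=True)
class FeatureSpec:
    id: str
    description: str
    task: str  # phonetic | semantic | both
    family: str  # temporal | semantic | phonetic | prosodic | voice-quality | demographic


def _temporal_block(task: str, offset: int, order: Sequence[str]) -> list[FeatureSpec]:
    desc = {
        "rate": f"{task} phrase production rate (tokens per second)",
        "speech_frac": f"{task} total speech time fraction",
        "max_gap": f"{task} maximum silent gap as fraction of duration",
        "min_gap": f"{task} minimum silent gap as fraction of duration",
        "mean_gap": f"{task} mean silent gap as fraction of duration",
        "sd_gap": f"{task} SD of silent gaps as fraction of duration",
        "median_gap": f"{task} median silent gap as fraction of duration",
        "mean_dur": f"{task} mean token duration (s)",
        "sd_dur": f"{task} SD of token durations (s)",
        "lead_silence": f"{task} leading-silence fraction",
    }
    return [
        FeatureSpec(f"V{offset + i}", desc[key], task, "temporal")
        for i, key in enumerate(order, start=1)
    ]


# Slot layout. In-text anchors are fixed (V1, V3, V4, V16, V23, V26, V27,
# V30, V39); the remaining slots follow a documented summary-statistic
# scheme over gaps, durations, similarity series and annotation counts.
_SEM_ORDER = ("rate", "speech_frac", "max_gap", "min_gap", "mean_gap",
              "sd_gap", "median_gap", "mean_dur", "sd_dur", "lead_silence")
_PHON_ORDER = ("max_gap", "min_gap", "mean_gap", "sd_gap", "median_gap",
               "rate", "speech_frac", "mean_dur", "sd_dur", "lead_silence")

FEATURE_SPEC: list[FeatureSpec] = (
    _temporal_block("semantic", 0, _SEM_ORDER)
    + _temporal_block("phonetic", 10, _PHON_ORDER)
    + [
        FeatureSpec("V21", "mean consecutive semantic similarity", "semantic", "semantic"),
        FeatureSpec("V22", "min consecutive semantic similarity", "semantic", "semantic"),
        FeatureSpec("V23", "max consecutive semantic similarity", "semantic", "semantic"),
        FeatureSpec("V24", "SD of consecutive semantic similarity", "semantic", "semantic"),
        FeatureSpec("V25", "median consecutive semantic similarity", "semantic", "semantic"),
        FeatureSpec("V26", "excess kurtosis of semantic similarity series", "semantic", "semantic"),
        FeatureSpec("V27", "mean consecutive phonetic similarity", "phonetic", "semantic"),
        FeatureSpec("V28", "max consecutive phonetic similarity", "phonetic", "semantic"),
        FeatureSpec("V29", "SD of consecutive phonetic similarity", "phonetic", "semantic"),
        FeatureSpec("V30", "min consecutive phonetic similarity", "phonetic", "semantic"),
        FeatureSpec("V31", "excess kurtosis of phonetic similarity series", "phonetic", "semantic"),
        FeatureSpec("V32", "intrusion proportion, phonetic task", "phonetic", "semantic"),
        FeatureSpec("V33", "intrusion proportion, semantic task", "semantic", "semantic"),
        FeatureSpec("V34", "neologism proportion, phonetic task", "phonetic", "semantic"),
        FeatureSpec("V35", "neologism proportion, semantic task", "semantic", "semantic"),
        FeatureSpec("V36", "stilted proportion, phonetic task", "phonetic", "semantic"),
        FeatureSpec("V37", "stilted proportion, semantic task", "semantic", "semantic"),
        FeatureSpec("V38", "corrected-token fraction (F to A)", "both", "phonetic"),
        FeatureSpec("V39", "Levenshtein similarity of filtered vs adjusted transcript", "both", "phonetic"),
    ]
    + [
        FeatureSpec("N1", "mean F0 (semitones re 27.5 Hz)", "both", "prosodic"),
        FeatureSpec("N2", "SD of F0 (semitones)", "both", "prosodic"),
        FeatureSpec("N3", "SD of rising F0 semitone slopes", "both", "prosodic"),
        FeatureSpec("N4", "SD of mean-normalized F0", "both", "prosodic"),
        FeatureSpec("N5", "mean falling F0 semitone slope", "both", "prosodic"),
        FeatureSpec("N6", "median F0 (Hz)", "both", "prosodic"),
        FeatureSpec("N7", "voiced frame fraction", "both", "prosodic"),
        FeatureSpec("N8", "SD of falling F0 semitone slopes", "both", "prosodic"),
        FeatureSpec("N9", "F0 inter-percentile range (80th - 20th)", "both", "prosodic"),
        FeatureSpec("N10", "mean rising F0 semitone slope", "both", "prosodic"),
        FeatureSpec("N11", "jitter (local)", "both", "voice-quality"),
        FeatureSpec("N12", "mean shimmer (dB)", "both", "voice-quality"),
        FeatureSpec("N13", "voiced segments per second", "both", "prosodic"),
        FeatureSpec("N14", "SD of shimmer (dB)", "both", "voice-quality"),
        FeatureSpec("N15", "mean phonation perturbation quotient (PPQ5)", "both", "voice-quality"),
        FeatureSpec("N16", "SD of jitter series", "both", "voice-quality"),
        FeatureSpec("N17", "SD of PPQ5 series", "both", "voice-quality"),
    ]
    + [
        FeatureSpec("AGE", "age in years", "both", "demographic"),
        FeatureSpec("GENDER", "gender (1 = female, 0 = male)", "both", "demographic"),
    ]
)

FEATURE_IDS = [f.id for f in FEATURE_SPEC]
VERBAL_IDS = [f.id for f in FEATURE_SPEC if f.id.startswith("V")]
NONVERBAL_IDS = [f.id for f in FEATURE_SPEC if f.id.startswith("N")]
DEMOGRAPHIC_IDS = ["AGE", "GENDER"]

assert len(FEATURE_IDS) == 58 and len(VERBAL_IDS) == 39 and len(NONVERBAL_IDS) == 17


@dataclass
class FeatureVector:
    """Ordered per-participant feature values plus imputation log."""

    subject_id: str
    group: str
    ids: list[str]
    values: np.ndarray
    imputed: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.values):
            raise ValueError("ids and values length mismatch")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.ids, name=self.subject_id)


# ---------------------------------------------------------------------------
# elementary operations


def inter_word_gaps(tokens: Sequence[WordToken], duration_s: float) -> np.ndarray:
    """Silent-gap series including leading and trailing silences.

    [start_1 - 0] + [start_{i+1} - end_i] + [duration - end_last]; an
    empty token list yields a single gap equal to the whole duration.
    """
    if not tokens:
        return np.array([duration_s])
    gaps = [tokens[0].start_s]
    for prev, nxt in zip(tokens, tokens[1:]):
        gaps.append(nxt.start_s - prev.end_s)
    gaps.append(duration_s - tokens[-1].end_s)
    return np.maximum(np.asarray(gaps), 0.0)


def _kurtosis(series: np.ndarray) -> float:
    """Fisher excess kurtosis (population moments); 0 for zero variance."""
    series = np.asarray(series, dtype=float)
    var = series.var()
    if var == 0.0 or series.size < 2:
        return 0.0
    return float(np.mean((series - series.mean()) ** 4) / var**2 - 3.0)


def _parse_level(level):
    """Accept a TranscriptLevel, a level name, or the string "reference"."""
    if isinstance(level, str):
        if level.lower() in ("reference", "ref"):
            return "reference"
        return TranscriptLevel.parse(level)
    return level


def _tokens_at(sub: SubtaskRecording, level) -> list[WordToken]:
    if level == "reference":
        if sub.reference is None:
            raise ValueError(f"{sub.task_kind} subtask has no reference transcript")
        return list(sub.reference)
    return sub.transcripts[level]


def _subtask_temporal(sub: SubtaskRecording, tokens: Sequence[WordToken]) -> dict[str, float]:
    d = sub.duration_s
    gaps = inter_word_gaps(tokens, d) / d
    durs = np.array([t.end_s - t.start_s for t in tokens])
    return {
        "rate": len(tokens) / d,
        "speech_frac": float(durs.sum() / d) if tokens else 0.0,
        "max_gap": float(gaps.max()),
        "min_gap": float(gaps.min()),
        "mean_gap": float(gaps.mean()),
        "sd_gap": float(gaps.std()),
        "median_gap": float(np.median(gaps)),
        "mean_dur": float(durs.mean()) if tokens else 0.0,
        "sd_dur": float(durs.std()) if tokens else 0.0,
        "lead_silence": float(gaps[0]),
    }


def temporal_features(
    session: Session, level: TranscriptLevel | str = TranscriptLevel.A
) -> dict[str, float]:
    """V1-V20: timing summaries of both subtasks at one level."""
    level = _parse_level(level)
    out: dict[str, float] = {}
    for sub, order, offset in (
        (session.semantic, _SEM_ORDER, 0),
        (session.phonetic, _PHON_ORDER, 10),
    ):
        stats = _subtask_temporal(sub, _tokens_at(sub, level))
        for i, key in enumerate(order, start=1):
            out[f"V{offset + i}"] = stats[key]
    return out


def _similarity_series(
    tokens: Sequence[WordToken], sim: Callable[[str, str], float]
) -> np.ndarray:
    return np.array(
        [sim(a.text, b.text) for a, b in zip(tokens, tokens[1:])], dtype=float
    )


def _series_stats(series: np.ndarray, keys: dict[str, str]) -> tuple[dict[str, float], bool]:
    """Summary statistics of a similarity series; flags degenerate input."""
    if series.size == 0:
        return {fid: 0.0 for fid in keys.values()}, True
    stats = {
        "mean": float(series.mean()),
        "min": float(series.min()),
        "max": float(series.max()),
        "sd": float(series.std()),
        "median": float(np.median(series)),
        "kurtosis": _kurtosis(series),
    }
    return {fid: stats[stat] for stat, fid in keys.items()}, False


def semantic_similarity_features(
    session_or_tokens, provider: str | Callable[[str, str], float] = "bigram_cosine",
    level: TranscriptLevel = TranscriptLevel.A,
) -> tuple[dict[str, float], bool]:
    """V21-V26: consecutive semantic-similarity series statistics."""
    sim = get_similarity_provider(provider) if isinstance(provider, str) else provider
    tokens = (
        _tokens_at(session_or_tokens.semantic, _parse_level(level))
        if isinstance(session_or_tokens, Session)
        else session_or_tokens
    )
    keys = {"mean": "V21", "min": "V22", "max": "V23", "sd": "V24",
            "median": "V25", "kurtosis": "V26"}
    return _series_stats(_similarity_series(tokens, sim), keys)


def phonetic_coherence_features(
    session_or_tokens, level: TranscriptLevel = TranscriptLevel.A
) -> tuple[dict[str, float], bool]:
    """V27-V31: consecutive Levenshtein-similarity series statistics."""
    tokens = (
        _tokens_at(session_or_tokens.phonetic, _parse_level(level))
        if isinstance(session_or_tokens, Session)
        else session_or_tokens
    )
    keys = {"mean": "V27", "max": "V28", "sd": "V29", "min": "V30",
            "kurtosis": "V31"}
    return _series_stats(_similarity_series(tokens, levenshtein_similarity), keys)


def transcript_adjustment_features(
    f_tokens: Sequence[WordToken], a_tokens: Sequence[WordToken]
) -> dict[str, float]:
    """V38-V39: extent of post-processing corrections between F and A."""
    if len(f_tokens) != len(a_tokens):
        raise ValueError("F and A transcripts must have equal length")
    if not f_tokens:
        return {"V38": 0.0, "V39": 1.0}
    corrected = sum(fa.text != aa.text for fa, aa in zip(f_tokens, a_tokens))
    joined_f = " ".join(t.text for t in f_tokens)
    joined_a = " ".join(t.text for t in a_tokens)
    return {
        "V38": corrected / len(f_tokens),
        "V39": levenshtein_similarity(joined_f, joined_a),
    }


def annotation_features(
    session: Session, level: TranscriptLevel = TranscriptLevel.A
) -> dict[str, float]:
    """V32-V37: flagged-token proportions per flag per task."""
    out = {}
    slots = {
        ("phonetic", "is_intrusion"): "V32",
        ("semantic", "is_intrusion"): "V33",
        ("phonetic", "is_neologism"): "V34",
        ("semantic", "is_neologism"): "V35",
        ("phonetic", "is_stilted"): "V36",
        ("semantic", "is_stilted"): "V37",
    }
    for task in ("phonetic", "semantic"):
        tokens = _tokens_at(session.subtask(task), _parse_level(level))
        n = len(tokens)
        for flag in ("is_intrusion", "is_neologism", "is_stilted"):
            fid = slots[(task, flag)]
            out[fid] = (sum(getattr(t, flag) for t in tokens) / n) if n else 0.0
    return out


# ---------------------------------------------------------------------------
# assembly


def _select_ids(feature_set: str, include_demographics: bool | None) -> list[str]:
    if feature_set in ("all", "VN"):
        ids = VERBAL_IDS + NONVERBAL_IDS
        demo = True if include_demographics is None else include_demographics
    elif feature_set in ("verbal", "V"):
        ids = list(VERBAL_IDS)
        demo = False if include_demographics is None else include_demographics
    elif feature_set in ("nonverbal", "N"):
        ids = list(NONVERBAL_IDS)
        demo = False if include_demographics is None else include_demographics
    else:
        raise ValueError(f"unknown feature set {feature_set!r}")
    return ids + (DEMOGRAPHIC_IDS if demo else [])


def assemble_features(
    session: Session,
    level: TranscriptLevel | str = TranscriptLevel.A,
    feature_set: str = "all",
    include_demographics: bool | None = None,
    similarity_provider: str | Callable[[str, str], float] = "bigram_cosine",
) -> FeatureVector:
    """Assemble the ordered feature vector for one session.

    Non-verbal entries come from the session's ingested acoustic table;
    an unknown feature id there is an error, a missing one is imputed.
    The default feature set is the full 58-entry vector (verbal +
    non-verbal + demographics).
    """
    level = _parse_level(level)
    ids = _select_ids(feature_set, include_demographics)
    values: dict[str, float] = {}
    imputed: list[str] = []

    if any(fid in VERBAL_IDS for fid in ids):
        values.update(temporal_features(session, level))
        sem, sem_imp = semantic_similarity_features(
            session, similarity_provider, level
        )
        phon, phon_imp = phonetic_coherence_features(session, level)
        values.update(sem)
        values.update(phon)
        if sem_imp:
            imputed += list(sem)
        if phon_imp:
            imputed += list(phon)
        values.update(annotation_features(session, level))
        f_all = list(session.phonetic.transcripts[TranscriptLevel.F]) + list(
            session.semantic.transcripts[TranscriptLevel.F]
        )
        a_all = list(session.phonetic.transcripts[TranscriptLevel.A]) + list(
            session.semantic.transcripts[TranscriptLevel.A]
        )
        values.update(transcript_adjustment_features(f_all, a_all))

    if any(fid in NONVERBAL_IDS for fid in ids):
        unknown = set(session.acoustic) - set(NONVERBAL_IDS)
        if unknown:
            raise ValueError(f"unknown feature ids in acoustic table: {sorted(unknown)}")
        for fid in NONVERBAL_IDS:
            if fid in session.acoustic:
                values[fid] = float(session.acoustic[fid])
            else:
                values[fid] = 0.0
                imputed.append(fid)

    if "AGE" in ids:
        values["AGE"] = float(session.age) if session.age is not None else 0.0
        values["GENDER"] = 1.0 if session.gender == "F" else 0.0
        if session.age is None:
            imputed.append("AGE")

    return FeatureVector(
        subject_id=session.subject_id,
        group=session.group,
        ids=ids,
        values=np.array([values[fid] for fid in ids]),
        imputed=[fid for fid in imputed if fid in ids],
    )


def extract_features(
    sessions: Sequence[Session],
    level: TranscriptLevel | str = TranscriptLevel.A,
    feature_set: str = "all",
    include_demographics: bool | None = None,
    similarity_provider: str | Callable[[str, str], float] = "bigram_cosine",
) -> pd.DataFrame:
    """Feature matrix for a cohort: subject_id, group, then feature columns."""
    rows = []
    for s in sessions:
        fv = assemble_features(
            s, level=level, feature_set=feature_set,
            include_demographics=include_demographics,
            similarity_provider=similarity_provider,
        )
        rows.append({"subject_id": fv.subject_id, "group": fv.group,
                     **dict(zip(fv.ids, fv.values))})
    return pd.DataFrame(rows)
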