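"""Word-level alignment and transcription-quality metrics.

Word accuracy is WAcc = 1 - WER with WER = (S + D + I) / N under a
minimal-cost word alignment (unit costs, no transpositions).  WAcc is
deliberately *not* clipped at zero: insertion-heavy hypotheses can score
below zero and downstream consumers must handle that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import Session, SubtaskRecording, TranscriptLevel, WordToken

__all__ = ["WordAlignment", "align_words", "wacc", "edit_distance",
           "evaluate_levels", "session_wacc", "group_wacc_table"]

# Alignment op codes, in tie-break preference order (match wins, then
# substitution, deletion, insertion) when total costs are equal.
MATCH, SUB, DEL, INS = "M", "S", "D", "I"
_PREFERENCE = {MATCH: 0, SUB: 1, DEL: 2, INS: 3}


@dataclass(frozen=True)
class WordAlignment:
    """Minimal edit alignment between a reference and a hypothesis.

    ``ops`` holds (op, ref_index, hyp_index) triples; indices are None on
    the side an op does not consume.  Counts satisfy H + S + D = N and
    H + S + I = len(hypothesis).
    """

    ops: tuple[tuple[str, int | None, int | None], ...]
    S: int
    D: int
    I: int
    H: int
    N: int

    @property
    def distance(self) -> int:
        return self.S + self.D + self.I


def _texts(seq: Sequence[WordToken | str]) -> list[str]:
    return [t.text if isinstance(t, WordToken) else t for t in seq]


def align_words(
    reference: Sequence[WordToken | str], hypothesis: Sequence[WordToken | str]
) -> WordAlignment:
    """Minimal-cost word alignment with a deterministic tie-break.

    Dynamic program over unit substitution/deletion/insertion costs; on
    equal cost the traceback prefers match > substitution > deletion >
    insertion.  Empty sequences are allowed.
    """
    ref, hyp = _texts(reference), _texts(hypothesis)
    n, m = len(ref), len(hyp)
    cost = np.zeros((n + 1, m + 1), dtype=np.int64)
    cost[:, 0] = np.arange(n + 1)
    cost[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        prev, cur = cost[i - 1], cost[i]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (ref[i - 1] != hyp[j - 1])
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
    ops: list[tuple[str, int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        candidates = []
        if i > 0 and j > 0:
            step = cost[i, j] - cost[i - 1, j - 1]
            if ref[i - 1] == hyp[j - 1] and step == 0:
                candidates.append((MATCH, i - 1, j - 1, i - 1, j - 1))
            elif ref[i - 1] != hyp[j - 1] and step == 1:
                candidates.append((SUB, i - 1, j - 1, i - 1, j - 1))
        if i > 0 and cost[i, j] - cost[i - 1, j] == 1:
            candidates.append((DEL, i - 1, None, i - 1, j))
        if j > 0 and cost[i, j] - cost[i, j - 1] == 1:
            candidates.append((INS, None, j - 1, i, j - 1))
        # each candidate is (op, ref_index, hyp_index, next_i, next_j)
        op, ri, hj, i, j = min(candidates, key=lambda c: _PREFERENCE[c[0]])
        ops.append((op, ri, hj))
    ops.reverse()
    counts = {MATCH: 0, SUB: 0, DEL: 0, INS: 0}
    for op, _, _ in ops:
        counts[op] += 1
    return WordAlignment(
        ops=tuple(ops),
        S=counts[SUB],
        D=counts[DEL],
        I=counts[INS],
        H=counts[MATCH],
        N=n,
    )


def edit_distance(a: str, b: str) -> int:
    """Character-level Levenshtein distance (unit costs)."""
    return align_words(list(a), list(b)).distance


def wacc(alignment: WordAlignment) -> float:
    """Word accuracy 1 - (S + D + I) / N; undefined for empty references."""
    if alignment.N == 0:
        raise ValueError("WAcc is undefined for an empty reference (N = 0)")
    return 1.0 - alignment.distance / alignment.N


def evaluate_levels(subtask: SubtaskRecording) -> dict[TranscriptLevel, float]:
    """WAcc of every available transcript level against the reference."""
    if subtask.reference is None:
        raise ValueError(f"{subtask.task_kind} subtask has no reference transcript")
    return {
        level: wacc(align_words(subtask.reference, toks))
        for level, toks in sorted(subtask.transcripts.items())
    }


def session_wacc(
    session: Session,
    level: TranscriptLevel,
    per_task: bool = False,
) -> float | dict[str, float]:
    """Per-subject WAcc at one level.

    By default both subtasks' token sequences are concatenated into a
    single reference/hypothesis pair (one WAcc per subject); with
    ``per_task=True`` a per-task mapping is returned instead.
    """
    if per_task:
        return {
            kind: wacc(align_words(sub.reference, sub.transcripts[level]))
            for kind, sub in (("phonetic", session.phonetic), ("semantic", session.semantic))
        }
    ref = list(session.phonetic.reference or []) + list(session.semantic.reference or [])
    hyp = list(session.phonetic.transcripts[level]) + list(session.semantic.transcripts[level])
    return wacc(align_words(ref, hyp))


def group_wacc_table(
    sessions: Sequence[Session],
    levels: Sequence[TranscriptLevel | str] = (TranscriptLevel.U, TranscriptLevel.F, TranscriptLevel.A),
    M: int = 20_000,
    seed: int | None = 0,
):
    """Bayesian group comparison of per-subject WAcc at each level.

    Returns a DataFrame with one row per level: posterior group means,
    95% HDIs, the posterior probability that the HC mean exceeds the SH
    mean, the subject-level superiority probability with its Monte-Carlo
    SE, and the discriminative deviation.  Each group needs at least two
    subjects for the variance posterior to be proper.
    """
    import pandas as pd

    from .bayes import compare_groups

    rng = np.random.default_rng(seed)
    levels = [TranscriptLevel.parse(l) if isinstance(l, str) else l for l in levels]
    rows = []
    for level in levels:
        samples = {"HC": [], "SH": []}
        for s in sessions:
            if s.group in samples:
                samples[s.group].append(session_wacc(s, level))
        for g, vals in samples.items():
            if len(vals) < 2:
                raise ValueError(f"group {g} has fewer than 2 subjects at level {level.name}")
        comp = compare_groups(
            np.asarray(samples["HC"]), np.asarray(samples["SH"]), M=M, rng=rng
        )
        rows.append({"level": level.name, **comp.as_dict()})
    return pd.DataFrame(rows)
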