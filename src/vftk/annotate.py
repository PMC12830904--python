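"""Transcript refinement and semantic tagging behind a provider contract.

The original pipeline delegated both steps to a remote LLM.  Here the
same two-stage contract is served by a deterministic, lexicon-backed
provider so that the rest of the pipeline is reproducible offline:

* stage 1 (filter, U -> F): drop conversational fillers and asides;
* stage 2 (adjust, F -> A): snap tokens at edit distance exactly 1 from
  a known word back onto that word (lexicographic tie-break), while
  preserving tokens at distance >= 2 as potential neologisms.

Semantic tagging flags each token as intrusion (task-constraint
violation), stilted (formal-register usage) and/or neologism (absent
from every lexicon).  Remote providers must satisfy the same schema; all
provider outputs are validated against the annotation invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import pandas as pd

from .corpus import Session, TranscriptLevel, WordToken
from .lexicons import LexiconPack

__all__ = [
    "TokenAnnotation",
    "AnnotationResult",
    "AnnotationRequest",
    "RefinementResult",
    "ProviderError",
    "LexiconAnnotator",
    "get_provider",
    "register_provider",
    "refine_transcript",
    "tag_semantics",
    "annotate_session",
    "annotation_rate_table",
    "within_distance1",
]


class ProviderError(ValueError):
    """A provider produced output violating the annotation schema."""


@dataclass(frozen=True)
class TokenAnnotation:
    is_intrusion: bool
    is_stilted: bool
    is_neologism: bool
    rationale: str = ""


@dataclass(frozen=True)
class AnnotationRequest:
    tokens: tuple[str, ...]
    task_kind: str
    description: str = ""  # pass-through context text, unused by the mock


@dataclass(frozen=True)
class AnnotationResult:
    annotations: tuple[TokenAnnotation, ...]


@dataclass(frozen=True)
class RefinementResult:
    """Output of the two-stage refinement: F and A token sequences."""

    filtered: tuple[WordToken, ...]
    adjusted: tuple[WordToken, ...]
    corrections: tuple[tuple[int, str, str], ...]  # (index in F, original, corrected)

    def __post_init__(self) -> None:
        if len(self.adjusted) != len(self.filtered):
            raise ValueError("adjustment is count-preserving: |A| must equal |F|")
        for idx, _, _ in self.corrections:
            if not 0 <= idx < len(self.filtered):
                raise ValueError(f"correction index {idx} out of range")


def within_distance1(a: str, b: str) -> bool:
    """True iff Levenshtein distance(a, b) == 1 (single edit)."""
    la, lb = len(a), len(b)
    if abs(la - lb) > 1 or a == b:
        return False
    if la == lb:  # exactly one substitution
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # a is shorter by one: one insertion into a yields b
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1:]


def _distance1_candidates(word: str, lexicon: Sequence[str]) -> list[str]:
    return [w for w in lexicon if within_distance1(word, w)]


def refine_transcript(
    u_tokens: Sequence[WordToken],
    task_kind: str,
    lexicons: LexiconPack,
    policy: str = "mock",
) -> RefinementResult:
    """Two-stage mock refinement of an unprocessed transcript.

    Correction is contextual: distance-1 candidates from the task
    lexicon are preferred (the annotator knows the task), falling back
    to the general lexicon so misrecognized off-task words are restored
    too.  Ties between distance-1 candidates are broken
    lexicographically.  Token order and the timestamps of retained
    tokens are preserved.
    """
    if task_kind not in ("phonetic", "semantic"):
        raise ValueError(f"unknown task_kind {task_kind!r}")
    if policy != "mock":
        raise ValueError(f"unknown refinement policy {policy!r}")
    filtered = tuple(
        t for t in u_tokens if t.text not in lexicons.fillers and " " not in t.text
    )
    task_space = sorted(lexicons.task_lexicon(task_kind))
    general_space = sorted(lexicons.general)
    adjusted: list[WordToken] = []
    corrections: list[tuple[int, str, str]] = []
    for i, tok in enumerate(filtered):
        if tok.text in lexicons.general:
            adjusted.append(tok)
            continue
        candidates = _distance1_candidates(tok.text, task_space) or _distance1_candidates(
            tok.text, general_space
        )
        if candidates:
            best = candidates[0]  # search_space is sorted: lexicographic tie-break
            adjusted.append(
                replace(tok, text=best, was_corrected=True, original_text=tok.text)
            )
            corrections.append((i, tok.text, best))
        else:
            adjusted.append(tok)  # distance >= 2: potential neologism, preserved
    return RefinementResult(
        filtered=filtered, adjusted=tuple(adjusted), corrections=tuple(corrections)
    )


def tag_semantics(
    tokens: Sequence[WordToken | str], task_kind: str, lexicons: LexiconPack
) -> AnnotationResult:
    """Deterministic lexicon-backed semantic tagging of one token list.

    Rules: in the semantic task a known non-animal word is an intrusion;
    in the phonetic task a word not starting with the target letter is an
    intrusion (proper nouns, tracked as a lexicon list, are excluded by
    task instruction rather than flagged).  A word absent from every
    lexicon is a neologism; a formal-register word is stilted.  Tagging
    is per-token, hence idempotent and order-independent.
    """
    if task_kind not in ("phonetic", "semantic"):
        raise ValueError(f"unknown task_kind {task_kind!r}")
    annotations = []
    for tok in tokens:
        text = tok.text if isinstance(tok, WordToken) else tok
        known = lexicons.known(text)
        neologism = not known
        if task_kind == "semantic":
            intrusion = known and text not in lexicons.animals and text not in lexicons.fillers
        else:
            intrusion = known and not text.startswith(lexicons.target_letter)
        stilted = text in lexicons.formal_register
        why = []
        if intrusion:
            why.append("violates task constraint")
        if neologism:
            why.append("absent from all lexicons")
        if stilted:
            why.append("formal-register usage")
        annotations.append(
            TokenAnnotation(
                is_intrusion=intrusion,
                is_stilted=stilted,
                is_neologism=neologism,
                rationale="; ".join(why),
            )
        )
    return AnnotationResult(annotations=tuple(annotations))


class LexiconAnnotator:
    """Deterministic provider serving the annotation contract."""

    name = "mock"

    def __init__(self, lexicons: LexiconPack):
        self.lexicons = lexicons

    def annotate(self, batch: Sequence[AnnotationRequest]) -> list[AnnotationResult]:
        results = [
            tag_semantics(req.tokens, req.task_kind, self.lexicons) for req in batch
        ]
        for req, res in zip(batch, results):
            validate_result(req, res, self.lexicons)
        return results


def validate_result(
    req: AnnotationRequest, res: AnnotationResult, lexicons: LexiconPack
) -> None:
    """Check a provider's output against the annotation invariants."""
    if len(res.annotations) != len(req.tokens):
        raise ProviderError(
            f"provider returned {len(res.annotations)} annotations "
            f"for {len(req.tokens)} tokens"
        )
    for text, ann in zip(req.tokens, res.annotations):
        if ann.is_neologism and lexicons.known(text):
            raise ProviderError(
                f"token {text!r} flagged as neologism but present in a lexicon"
            )


_PROVIDERS: dict[str, Callable[[LexiconPack], object]] = {
    "mock": LexiconAnnotator,
}


def register_provider(name: str, factory: Callable[[LexiconPack], object]) -> None:
    _PROVIDERS[name] = factory


def get_provider(name: str, lexicons: LexiconPack):
    try:
        factory = _PROVIDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown provider {name!r}; registered: {sorted(_PROVIDERS)}"
        )
    return factory(lexicons)


def annotate_session(
    session: Session,
    lexicons: LexiconPack,
    provider=None,
    level: TranscriptLevel = TranscriptLevel.A,
) -> Session:
    """Return a copy of the session with flags set on the given level."""
    provider = provider or LexiconAnnotator(lexicons)
    for sub in (session.phonetic, session.semantic):
        toks = sub.transcripts.get(level)
        if toks is None:
            continue
        req = AnnotationRequest(
            tokens=tuple(t.text for t in toks), task_kind=sub.task_kind
        )
        (res,) = provider.annotate([req])
        sub.transcripts[level] = [
            replace(
                t,
                is_intrusion=a.is_intrusion,
                is_stilted=a.is_stilted,
                is_neologism=a.is_neologism,
            )
            for t, a in zip(toks, res.annotations)
        ]
    return session


def annotation_rate_table(
    sessions: Sequence[Session],
    lexicons: LexiconPack | None = None,
    per_subject: bool = False,
) -> pd.DataFrame:
    """Refinement and tagging rates per group and task, in percent.

    * retention: |F| / |U| * 100 (how much survived filtering),
    * overlap: share of F tokens whose text is unchanged in A,
    * intrusion / neologism / stilted: flagged-token share of A-level
      tokens (tagging runs after refinement, so rates are computed on
      the corrected transcripts).

    Rates are token-weighted pooled over the group by default; with
    ``per_subject=True`` they are averaged over subjects instead.
    Groups/tasks with no U tokens are reported as missing.
    """
    from .lexicons import load_default_lexicons

    lexicons = lexicons or load_default_lexicons()
    records = []
    for s in sessions:
        for sub in (s.phonetic, s.semantic):
            u = sub.transcripts.get(TranscriptLevel.U, [])
            f = sub.transcripts.get(TranscriptLevel.F, [])
            a = sub.transcripts.get(TranscriptLevel.A, [])
            tags = tag_semantics(a, sub.task_kind, lexicons).annotations
            records.append(
                {
                    "group": s.group,
                    "task": sub.task_kind,
                    "n_u": len(u),
                    "n_f": len(f),
                    "n_a": len(a),
                    "unchanged": sum(
                        fa.text == aa.text for fa, aa in zip(f, a)
                    ),
                    "intrusions": sum(t.is_intrusion for t in tags),
                    "neologisms": sum(t.is_neologism for t in tags),
                    "stilted": sum(t.is_stilted for t in tags),
                }
            )
    df = pd.DataFrame(records)

    def _rates(g: pd.DataFrame) -> pd.Series:
        def pct(num, den):
            if den == 0:
                return float("nan")
            return 100.0 * num / den

        if per_subject:
            vals = {
                "retention_pct": (100.0 * g.n_f / g.n_u.where(g.n_u > 0)).mean(),
                "overlap_pct": (100.0 * g.unchanged / g.n_f.where(g.n_f > 0)).mean(),
                "intrusion_pct": (100.0 * g.intrusions / g.n_a.where(g.n_a > 0)).mean(),
                "neologism_pct": (100.0 * g.neologisms / g.n_a.where(g.n_a > 0)).mean(),
                "stilted_pct": (100.0 * g.stilted / g.n_a.where(g.n_a > 0)).mean(),
            }
        else:
            vals = {
                "retention_pct": pct(g.n_f.sum(), g.n_u.sum()),
                "overlap_pct": pct(g.unchanged.sum(), g.n_f.sum()),
                "intrusion_pct": pct(g.intrusions.sum(), g.n_a.sum()),
                "neologism_pct": pct(g.neologisms.sum(), g.n_a.sum()),
                "stilted_pct": pct(g.stilted.sum(), g.n_a.sum()),
            }
        return pd.Series(vals)

    return (
        df.groupby(["group", "task"], sort=True)
        .apply(_rates, include_groups=False)
        .reset_index()
    )
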