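"""String similarity primitives used for coherence features.

Phonetic similarity between consecutive utterances is a normalized
Levenshtein similarity; semantic similarity is served by a pluggable
provider whose deterministic default is a character-bigram cosine (an
embedding-free stand-in chosen so the whole pipeline runs offline).
"""

from __future__ import annotations

from collections import Counter
from math import sqrt
from typing import Callable

__all__ = ["levenshtein_distance", "levenshtein_similarity", "bigram_cosine",
           "get_similarity_provider", "register_similarity_provider"]


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost character edit distance (two-row dynamic program)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_similarity(a: str, b: str) -> float:
    """1 - distance / max(len); two empty strings are fully similar."""
    denom = max(len(a), len(b))
    if denom == 0:
        return 1.0
    return 1.0 - levenshtein_distance(a, b) / denom


def _bigrams(s: str) -> Counter:
    padded = f"^{s}$"
    return Counter(padded[i : i + 2] for i in range(len(padded) - 1))


def bigram_cosine(a: str, b: str) -> float:
    """Cosine similarity of padded character-bigram counts."""
    ca, cb = _bigrams(a), _bigrams(b)
    dot = sum(ca[k] * cb[k] for k in ca)
    na = sqrt(sum(v * v for v in ca.values()))
    nb = sqrt(sum(v * v for v in cb.values()))
    if na == 0.0 or nb == 0.0:
        return 1.0 if a == b else 0.0
    return min(1.0, dot / (na * nb))


_SIM_PROVIDERS: dict[str, Callable[[str, str], float]] = {
    "bigram_cosine": bigram_cosine,
    "levenshtein": levenshtein_similarity,
}


def register_similarity_provider(name: str, fn: Callable[[str, str], float]) -> None:
    _SIM_PROVIDERS[name] = fn


def get_similarity_provider(name: str) -> Callable[[str, str], float]:
    try:
        return _SIM_PROVIDERS[name]
    except KeyError:
        raise KeyError(f"unknown similarity provider {name!r}; "
                       f"registered: {sorted(_SIM_PROVIDERS)}")
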