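"""Task lexicons backing the deterministic annotation provider.

Toy Slovene word lists ship with the package (UTF-8, one word per line):
animal names for the semantic task, words starting with 'l' for the
phonetic task, conversational fillers, common off-task nouns, and a small
formal/archaic register used to flag stilted usage.  The *general*
lexicon is the union of all lists plus extra common words; a token absent
from every list is treated as a potential neologism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus import ValidationError, normalize_text

__all__ = ["LexiconPack", "load_default_lexicons"]

TARGET_LETTER = "l"


@dataclass(frozen=True)
class LexiconPack:
    """Normalized word sets used for tagging and mock refinement."""

    animals: frozenset[str]
    letter_words: frozenset[str]
    fillers: frozenset[str]
    offtask: frozenset[str]
    formal_register: frozenset[str]
    common: frozenset[str]
    target_letter: str = TARGET_LETTER
    general: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.fillers & self.animals:
            raise ValidationError("fillers and animals must be disjoint")
        if self.fillers & self.letter_words:
            raise ValidationError("fillers and letter words must be disjoint")
        bad = [w for w in self.letter_words if not w.startswith(self.target_letter)]
        if bad:
            raise ValidationError(f"letter-lexicon entries must start with "
                                  f"{self.target_letter!r}: {bad[:5]}")
        object.__setattr__(
            self,
            "general",
            frozenset(
                self.animals
                | self.letter_words
                | self.offtask
                | self.formal_register
                | self.common
            ),
        )

    def task_lexicon(self, task_kind: str) -> frozenset[str]:
        if task_kind == "semantic":
            return self.animals
        if task_kind == "phonetic":
            return self.letter_words
        raise KeyError(f"unknown task_kind {task_kind!r}")

    def known(self, word: str) -> bool:
        """True if the word appears in any lexicon (fillers included)."""
        return word in self.general or word in self.fillers


def _read_wordlist(path) -> frozenset[str]:
    words = frozenset(
        normalize_text(line) for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip()
    )
    if not words:
        raise ValidationError(f"empty lexicon file: {path}")
    return words


def load_lexicons(directory: str | Path) -> LexiconPack:
    """Load a lexicon pack from a directory of word-list files."""
    directory = Path(directory)
    return LexiconPack(
        animals=_read_wordlist(directory / "animals.txt"),
        letter_words=_read_wordlist(directory / "letter_l.txt"),
        fillers=_read_wordlist(directory / "fillers.txt"),
        offtask=_read_wordlist(directory / "offtask.txt"),
        formal_register=_read_wordlist(directory / "formal.txt"),
        common=_read_wordlist(directory / "general.txt"),
    )


def load_default_lexicons() -> LexiconPack:
    """Load the lexicon pack bundled with the package."""
    root = resources.files("vftk").joinpath("data/lexicons")
    with resources.as_file(root) as directory:
        return load_lexicons(directory)
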