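"""Domain model for verbal-fluency sessions and their on-disk bundles.

A *session* is one participant's recording of the two one-minute
verbal-fluency subtasks (phonetic: words starting with 'l'; semantic:
animal naming).  Each subtask carries an optional manual *reference*
transcript and up to three automatic transcripts at processing levels
U (unprocessed ASR output), F (filtered: task-irrelevant tokens removed)
and A (adjusted: clear misrecognitions corrected in place).

Token times are stored in seconds relative to the subtask onset.
Bundles are serialized as one JSON file per session plus a timestamp CSV
mirroring the paired audio+metadata layout of the original corpus.
"""

from __future__ import annotations

import csv
import enum
import json
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "ValidationError",
    "FormatError",
    "WordToken",
    "TranscriptLevel",
    "SubtaskRecording",
    "Session",
    "TimestampIndex",
    "SliceResult",
    "normalize_text",
    "read_session_bundle",
    "write_session_bundle",
    "slice_subtasks",
    "select_transcript",
]


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class FormatError(ValueError):
    """A bundle file does not parse as the documented dialect."""


_PUNCT = dict.fromkeys(
    i for i in range(0x2500) if unicodedata.category(chr(i)).startswith("P")
)


def normalize_text(text: str) -> str:
    """Lowercase, strip punctuation, NFC-normalize.

    Slovene diacritics (č, š, ž) are preserved; NFC guarantees that
    composed and decomposed forms compare equal in edit distances.
    """
    return unicodedata.normalize("NFC", text).lower().translate(_PUNCT).strip()


@dataclass(frozen=True)
class WordToken:
    """One transcribed word with timing and semantic annotation flags."""

    text: str
    start_s: float
    end_s: float
    is_intrusion: bool = False
    is_stilted: bool = False
    is_neologism: bool = False
    was_corrected: bool = False
    original_text: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValidationError("token text must be non-empty after normalization")
        if not (0.0 <= self.start_s <= self.end_s):
            raise ValidationError(
                f"token {self.text!r}: need 0 <= start_s <= end_s, "
                f"got ({self.start_s}, {self.end_s})"
            )
        if self.was_corrected and (
            self.original_text is None or self.original_text == self.text
        ):
            raise ValidationError(
                f"corrected token {self.text!r} must carry a differing original_text"
            )


class TranscriptLevel(enum.IntEnum):
    """Transcript processing level; ordering U < F < A is total."""

    U = 0
    F = 1
    A = 2

    @classmethod
    def parse(cls, name: str) -> "TranscriptLevel":
        try:
            return cls[name.upper()]
        except KeyError:
            raise KeyError(f"unknown transcript level {name!r}; expected U, F or A")


def _check_token_sequence(tokens: Sequence[WordToken], duration_s: float, what: str) -> None:
    prev_end = None
    for tok in tokens:
        if tok.end_s > duration_s + 1e-9:
            raise ValidationError(
                f"{what}: token {tok.text!r} ends at {tok.end_s} s "
                f"beyond subtask duration {duration_s} s"
            )
        if prev_end is not None and tok.start_s < prev_end - 1e-9:
            raise ValidationError(
                f"{what}: token {tok.text!r} at {tok.start_s} s overlaps previous token"
            )
        prev_end = tok.end_s


@dataclass
class SubtaskRecording:
    """One verbal-fluency subtask with reference and leveled transcripts."""

    task_kind: str  # "phonetic" | "semantic"
    duration_s: float = 60.0
    reference: list[WordToken] | None = None
    transcripts: dict[TranscriptLevel, list[WordToken]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task_kind not in ("phonetic", "semantic"):
            raise ValidationError(f"unknown task_kind {self.task_kind!r}")
        self.validate()

    def validate(self) -> None:
        if self.reference is not None:
            _check_token_sequence(self.reference, self.duration_s, f"{self.task_kind} reference")
        for level, toks in self.transcripts.items():
            _check_token_sequence(toks, self.duration_s, f"{self.task_kind} {level.name}")
        u = self.transcripts.get(TranscriptLevel.U)
        f = self.transcripts.get(TranscriptLevel.F)
        a = self.transcripts.get(TranscriptLevel.A)
        if u is not None and f is not None and len(f) > len(u):
            raise ValidationError("filtering only removes tokens: |F| must be <= |U|")
        if f is not None and a is not None and len(a) != len(f):
            raise ValidationError("adjustment replaces tokens in place: |A| must equal |F|")


@dataclass
class Session:
    """One participant: both subtasks plus demographics and acoustic table."""

    subject_id: str
    group: str  # "HC" | "SH" | "unknown"
    age: float | None
    gender: str | None
    phonetic: SubtaskRecording
    semantic: SubtaskRecording
    acoustic: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("HC", "SH", "unknown"):
            raise ValidationError(f"unknown group label {self.group!r}")
        if self.age is not None and self.age <= 0:
            raise ValidationError("age must be positive when given")
        if self.phonetic.task_kind != "phonetic" or self.semantic.task_kind != "semantic":
            raise ValidationError("subtasks assigned to wrong slots")

    def subtask(self, task_kind: str) -> SubtaskRecording:
        if task_kind == "phonetic":
            return self.phonetic
        if task_kind == "semantic":
            return self.semantic
        raise KeyError(f"unknown task_kind {task_kind!r}")


@dataclass(frozen=True)
class TimestampIndex:
    """Absolute subtask intervals within the original recording.

    The phonetic task is always administered first, so its interval must
    precede the semantic one.
    """

    phonetic: tuple[float, float]
    semantic: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("phonetic", self.phonetic), ("semantic", self.semantic)):
            if hi <= lo:
                raise ValidationError(f"{name} interval end {hi} must exceed start {lo}")
        if self.semantic[0] < self.phonetic[1]:
            raise ValidationError("phonetic interval must precede the semantic interval")


class SliceResult(NamedTuple):
    phonetic: list[WordToken]
    semantic: list[WordToken]
    dropped: int


def slice_subtasks(
    tokens_absolute: Sequence[WordToken], index: TimestampIndex
) -> SliceResult:
    """Assign absolutely-timed tokens to subtasks, re-zeroing their clocks.

    Tokens whose start falls outside both intervals (e.g. speech in the
    inter-task break) are dropped and counted.
    """
    starts = [t.start_s for t in tokens_absolute]
    if starts != sorted(starts):
        raise ValidationError("tokens must be sorted by absolute start time")
    out: dict[str, list[WordToken]] = {"phonetic": [], "semantic": []}
    dropped = 0
    for tok in tokens_absolute:
        for name in ("phonetic", "semantic"):
            lo, hi = getattr(index, name)
            if lo <= tok.start_s < hi:
                out[name].append(
                    replace(tok, start_s=tok.start_s - lo, end_s=min(tok.end_s, hi) - lo)
                )
                break
        else:
            dropped += 1
    return SliceResult(out["phonetic"], out["semantic"], dropped)


def select_transcript(
    subtask: SubtaskRecording, level: TranscriptLevel | str
) -> list[WordToken]:
    """Return the stored token sequence for one processing level."""
    if isinstance(level, str):
        level = TranscriptLevel.parse(level)
    try:
        return subtask.transcripts[level]
    except KeyError:
        raise KeyError(
            f"transcript level {level.name} not present in {subtask.task_kind} subtask"
        )


# ---------------------------------------------------------------------------
# Bundle serialization


def _token_to_dict(tok: WordToken) -> dict:
    d = {
        "text": tok.text,
        "start_s": round(tok.start_s, 4),
        "end_s": round(tok.end_s, 4),
    }
    for flag in ("is_intrusion", "is_stilted", "is_neologism", "was_corrected"):
        if getattr(tok, flag):
            d[flag] = True
    if tok.original_text is not None:
        d["original_text"] = tok.original_text
    return d


def _token_from_dict(d: dict) -> WordToken:
    return WordToken(
        text=d["text"],
        start_s=float(d["start_s"]),
        end_s=float(d["end_s"]),
        is_intrusion=bool(d.get("is_intrusion", False)),
        is_stilted=bool(d.get("is_stilted", False)),
        is_neologism=bool(d.get("is_neologism", False)),
        was_corrected=bool(d.get("was_corrected", False)),
        original_text=d.get("original_text"),
    )


def _subtask_to_dict(sub: SubtaskRecording) -> dict:
    return {
        "task_kind": sub.task_kind,
        "duration_s": sub.duration_s,
        "reference": None
        if sub.reference is None
        else [_token_to_dict(t) for t in sub.reference],
        "transcripts": {
            lvl.name: [_token_to_dict(t) for t in toks]
            for lvl, toks in sorted(sub.transcripts.items())
        },
    }


def _subtask_from_dict(d: dict) -> SubtaskRecording:
    return SubtaskRecording(
        task_kind=d["task_kind"],
        duration_s=float(d["duration_s"]),
        reference=None
        if d.get("reference") is None
        else [_token_from_dict(t) for t in d["reference"]],
        transcripts={
            TranscriptLevel.parse(name): [_token_from_dict(t) for t in toks]
            for name, toks in d.get("transcripts", {}).items()
        },
    )


# Inter-task break written into synthesized timestamp rows (seconds).
_BREAK_S = 5.0

TIMESTAMP_HEADER = ["subject_id", "task", "start_s", "end_s"]


def write_session_bundle(session: Session, out_dir: str | Path) -> dict[str, Path]:
    """Write ``<subject_id>.json`` and ``<subject_id>_timestamps.csv``.

    Output is deterministic: stable key order, fixed float formatting.
    The timestamp CSV lays the two subtasks back to back with a short
    break, phonetic first, matching the testing protocol.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    doc = {
        "subject": {
            "subject_id": session.subject_id,
            "group": session.group,
            "age": session.age,
            "gender": session.gender,
        },
        "phonetic": _subtask_to_dict(session.phonetic),
        "semantic": _subtask_to_dict(session.semantic),
        "acoustic": {k: session.acoustic[k] for k in sorted(session.acoustic)},
    }
    json_path = out_dir / f"{session.subject_id}.json"
    json_path.write_text(
        json.dumps(doc, ensure_ascii=False, sort_keys=True, indent=1) + "\n",
        encoding="utf-8",
    )
    ts_path = out_dir / f"{session.subject_id}_timestamps.csv"
    p_end = session.phonetic.duration_s
    s_start = p_end + _BREAK_S
    with ts_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TIMESTAMP_HEADER)
        writer.writerow([session.subject_id, "phonetic", "0.0", f"{p_end}"])
        writer.writerow(
            [session.subject_id, "semantic", f"{s_start}", f"{s_start + session.semantic.duration_s}"]
        )
    return {"transcript": json_path, "timestamps": ts_path}


def read_timestamp_index(timestamp_path: str | Path) -> TimestampIndex:
    """Parse the timestamp CSV (``subject_id,task,start_s,end_s``)."""
    intervals: dict[str, tuple[float, float]] = {}
    with Path(timestamp_path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != TIMESTAMP_HEADER:
            raise FormatError(
                f"{timestamp_path}: expected header {','.join(TIMESTAMP_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                task = row["task"]
                lo, hi = float(row["start_s"]), float(row["end_s"])
            except (KeyError, TypeError, ValueError):
                raise FormatError(f"{timestamp_path}: malformed row {i}: {row}")
            if task not in ("phonetic", "semantic"):
                raise FormatError(f"{timestamp_path}: row {i}: unknown task {task!r}")
            if hi <= lo:
                raise ValidationError(
                    f"{timestamp_path}: row {i}: end {hi} must exceed start {lo}"
                )
            intervals[task] = (lo, hi)
    if set(intervals) != {"phonetic", "semantic"}:
        raise FormatError(f"{timestamp_path}: need exactly one phonetic and one semantic row")
    return TimestampIndex(phonetic=intervals["phonetic"], semantic=intervals["semantic"])


def read_session_bundle(
    transcript_path: str | Path, timestamp_path: str | Path
) -> Session:
    """Read a session bundle written by :func:`write_session_bundle`."""
    try:
        doc = json.loads(Path(transcript_path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{transcript_path}: invalid JSON: {exc}") from exc
    read_timestamp_index(timestamp_path)  # validated for side effects
    subj = doc["subject"]
    return Session(
        subject_id=subj["subject_id"],
        group=subj["group"],
        age=subj.get("age"),
        gender=subj.get("gender"),
        phonetic=_subtask_from_dict(doc["phonetic"]),
        semantic=_subtask_from_dict(doc["semantic"]),
        acoustic={k: float(v) for k, v in doc.get("acoustic", {}).items()},
    )


def read_cohort_dir(cohort_dir: str | Path) -> list[Session]:
    """Read every session bundle in a directory, sorted by subject id."""
    cohort_dir = Path(cohort_dir)
    sessions = []
    for json_path in sorted(cohort_dir.glob("*.json")):
        if json_path.name in ("truth.json", "config.json"):
            continue
        ts_path = cohort_dir / f"{json_path.stem}_timestamps.csv"
        sessions.append(read_session_bundle(json_path, ts_path))
    return sessions
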