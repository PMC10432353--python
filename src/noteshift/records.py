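"""Core record types shared across the audit pipeline.

A corpus is a list of :class:`Note` objects, each carrying its latent gold
truth and (optionally) triplicate annotator records.  All character offsets
are 0-based, half-open, into the note's ``raw_text`` (or into a passage when
explicitly re-based).  Corpora round-trip through JSON-Lines, one note per
line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

#: The trinary seizure-freedom alphabet.
LABELS = ("seizure_free", "having_seizures", "unclassifiable")

#: The two span-extraction tasks.
EXTRACTION_TASKS = ("frequency", "last_seizure")

DIALECTS = ("penn", "michigan")


@dataclass(frozen=True, order=True)
class Span:
    """A half-open character span ``[start, end)`` with its surface text."""

    start: int
    end: int
    text: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "text": self.text}

    @classmethod
    def from_dict(cls, d: dict) -> "Span":
        return cls(int(d["start"]), int(d["end"]), d.get("text", ""))


def _spans_from(items: Iterable[dict | Span]) -> list[Span]:
    return [s if isinstance(s, Span) else Span.from_dict(s) for s in items]


@dataclass
class AnnotationRecord:
    """One annotator's (or the merged gold's) labels and spans for a note."""

    note_id: str
    label: str
    frequency_spans: list[Span] = field(default_factory=list)
    last_seizure_spans: list[Span] = field(default_factory=list)
    outcome_spans: list[Span] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        self.frequency_spans = _spans_from(self.frequency_spans)
        self.last_seizure_spans = _spans_from(self.last_seizure_spans)
        self.outcome_spans = _spans_from(self.outcome_spans)

    def spans_for(self, task: str) -> list[Span]:
        if task == "frequency":
            return self.frequency_spans
        if task == "last_seizure":
            return self.last_seizure_spans
        if task == "outcome":
            return self.outcome_spans
        raise KeyError(task)

    def all_spans(self) -> list[Span]:
        return self.frequency_spans + self.last_seizure_spans + self.outcome_spans

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "label": self.label,
            "frequency_spans": [s.to_dict() for s in self.frequency_spans],
            "last_seizure_spans": [s.to_dict() for s in self.last_seizure_spans],
            "outcome_spans": [s.to_dict() for s in self.outcome_spans],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationRecord":
        return cls(
            note_id=d["note_id"],
            label=d["label"],
            frequency_spans=_spans_from(d.get("frequency_spans", ())),
            last_seizure_spans=_spans_from(d.get("last_seizure_spans", ())),
            outcome_spans=_spans_from(d.get("outcome_spans", ())),
        )


@dataclass
class GoldRecord(AnnotationRecord):
    """Merged ground truth for a note, with any adjudication flags raised
    during majority-vote merging."""

    adjudication_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["adjudication_flags"] = list(self.adjudication_flags)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GoldRecord":
        rec = super().from_dict(d)
        return cls(**{**rec.__dict__, "adjudication_flags": list(d.get("adjudication_flags", ()))})


@dataclass
class Note:
    """One clinical document with specialty/dialect metadata, latent truth,
    and optional triplicate annotations."""

    note_id: str
    specialty: str
    dialect: str
    raw_text: str
    truth: GoldRecord
    annotations: list[AnnotationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.raw_text:
            raise ValueError("raw_text must be non-empty")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        for s in self.truth.all_spans():
            if self.raw_text[s.start:s.end] != s.text:
                raise ValueError(
                    f"{self.note_id}: truth span text mismatch at [{s.start},{s.end})"
                )

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "specialty": self.specialty,
            "dialect": self.dialect,
            "raw_text": self.raw_text,
            "truth": self.truth.to_dict(),
            "annotations": [a.to_dict() for a in self.annotations],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Note":
        return cls(
            note_id=d["note_id"],
            specialty=d["specialty"],
            dialect=d["dialect"],
            raw_text=d["raw_text"],
            truth=GoldRecord.from_dict(d["truth"]),
            annotations=[AnnotationRecord.from_dict(a) for a in d.get("annotations", ())],
        )


@dataclass
class Prediction:
    """One system output for a note under one seed: a class label plus an
    extracted span (or explicit no-answer, ``None``) per extraction task."""

    note_id: str
    seed: int
    label: str
    frequency_span: Span | None = None
    last_seizure_span: Span | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    def span_for(self, task: str) -> Span | None:
        if task == "frequency":
            return self.frequency_span
        if task == "last_seizure":
            return self.last_seizure_span
        raise KeyError(task)

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "seed": self.seed,
            "label": self.label,
            "frequency_span": self.frequency_span.to_dict() if self.frequency_span else None,
            "last_seizure_span": (
                self.last_seizure_span.to_dict() if self.last_seizure_span else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Prediction":
        return cls(
            note_id=d["note_id"],
            seed=int(d["seed"]),
            label=d["label"],
            frequency_span=Span.from_dict(d["frequency_span"]) if d.get("frequency_span") else None,
            last_seizure_span=(
                Span.from_dict(d["last_seizure_span"]) if d.get("last_seizure_span") else None
            ),
        )


# ---------------------------------------------------------------------------
# JSON-Lines round-trips


def _iter_jsonl(path: str | Path) -> Iterator[dict]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)


def _write_jsonl(path: str | Path, dicts: Iterable[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for d in dicts:
            fh.write(json.dumps(d, sort_keys=True) + "\n")


def write_notes(path: str | Path, notes: Iterable[Note]) -> None:
    _write_jsonl(path, (n.to_dict() for n in notes))


def read_notes(path: str | Path) -> list[Note]:
    notes = [Note.from_dict(d) for d in _iter_jsonl(path)]
    ids = [n.note_id for n in notes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate note_id in {path}")
    return notes


def write_predictions(path: str | Path, preds: Iterable[Prediction]) -> None:
    _write_jsonl(path, (p.to_dict() for p in preds))


def read_predictions(path: str | Path) -> list[Prediction]:
    return [Prediction.from_dict(d) for d in _iter_jsonl(path)]


def write_gold(path: str | Path, records: Iterable[GoldRecord]) -> None:
    _write_jsonl(path, (g.to_dict() for g in records))


def read_gold(path: str | Path) -> list[GoldRecord]:
    return [GoldRecord.from_dict(d) for d in _iter_jsonl(path)]
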