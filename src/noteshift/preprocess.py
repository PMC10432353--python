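"""Passage isolation and sentence segmentation.

The extraction models only ever see the epilepsy-history passage of a note,
truncated to a fixed character budget (default 1506, the input budget of the
BERT-class models the audit targets).  How that passage is located differs by
institutional dialect:

* ``penn`` — notes carry explicit section headers; the passage starts
  immediately after the first line-anchored "History of Present Illness" or
  "Interval History" header (case-insensitive, optional trailing colon).
* ``michigan`` — notes have no reliable headers; the passage starts at the
  first character of the first sentence containing one of a small set of
  trigger phrases ("the patient was last seen", "interval history", ...).

If neither mechanism fires the first ``char_limit`` characters are used
(``fallback_head``), so every note yields a passage.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

PENN_HEADERS = ("History of Present Illness", "Interval History")

# Trigger phrases marking the start of the epilepsy history in header-less
# notes, tried in order; matching ignores case and interior whitespace runs.
MICHIGAN_KEYWORDS = (
    "the patient was last seen",
    "interval history",
    "interval events",
    "hpi",
    "history of present illness",
)

DEFAULT_CHAR_LIMIT = 1506


@dataclass
class DialectRules:
    """Institution-specific passage-location rules."""

    name: str
    header_names: tuple[str, ...] = ()
    keyword_phrases: tuple[str, ...] = ()
    char_limit: int = DEFAULT_CHAR_LIMIT

    def __post_init__(self) -> None:
        if self.char_limit <= 0:
            raise ValueError("char_limit must be positive")
        if self.name == "penn" and not self.header_names:
            raise ValueError("penn rules need header_names")
        if self.name == "michigan" and not self.keyword_phrases:
            raise ValueError("michigan rules need keyword_phrases")

    @classmethod
    def default(cls, dialect: str, char_limit: int = DEFAULT_CHAR_LIMIT) -> "DialectRules":
        if dialect == "penn":
            return cls("penn", header_names=PENN_HEADERS, char_limit=char_limit)
        if dialect == "michigan":
            return cls("michigan", keyword_phrases=MICHIGAN_KEYWORDS, char_limit=char_limit)
        raise ValueError(f"unknown dialect {dialect!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "DialectRules":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d["name"],
            header_names=tuple(d.get("header_names", ())),
            keyword_phrases=tuple(d.get("keyword_phrases", ())),
            char_limit=int(d.get("char_limit", DEFAULT_CHAR_LIMIT)),
        )


@dataclass
class Passage:
    """The isolated (and truncated) history passage of one note."""

    text: str
    origin: str  # header_match | keyword_match | fallback_head
    start_offset: int
    note_id: str = ""

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "text": self.text,
            "origin": self.origin,
            "start_offset": self.start_offset,
        }


@dataclass(frozen=True)
class Sentence:
    start: int
    end: int
    text: str


# Abbreviations after which a period does not end a sentence.
_ABBREVIATIONS = ("dr.", "mr.", "mrs.", "q.d.", "b.i.d.", "vs.", "approx.")

_TERMINAL = re.compile(r"[.!?]+")


def _ends_with_abbreviation(prefix: str) -> bool:
    low = prefix.lower()
    for abbr in _ABBREVIATIONS:
        if low.endswith(abbr):
            before = len(low) - len(abbr) - 1
            if before < 0 or not low[before].isalnum():
                return True
    return False


def split_sentences(text: str) -> list[Sentence]:
    """Rule-based sentence segmentation with exact character offsets.

    A sentence ends at terminal punctuation (``. ! ?``) followed by
    whitespace and an uppercase letter or digit, unless the punctuation
    terminates a known clinical abbreviation.  Newlines count as whitespace,
    so line-broken notes segment naturally.  Offsets are half-open into
    ``text``; the gaps between consecutive sentences are pure whitespace.
    """
    breaks: list[int] = []
    for m in _TERMINAL.finditer(text):
        end = m.end()
        rest = text[end:]
        if not rest.strip():
            breaks.append(end)
            break
        if not rest[0].isspace():
            continue
        nxt = rest.lstrip()[0]
        if not (nxt.isupper() or nxt.isdigit()):
            continue
        if _ends_with_abbreviation(text[:end]):
            continue
        breaks.append(end)

    sentences: list[Sentence] = []
    cursor = 0
    for b in breaks:
        seg = text[cursor:b]
        lead = len(seg) - len(seg.lstrip())
        start = cursor + lead
        if start < b:
            sentences.append(Sentence(start, b, text[start:b]))
        cursor = b
    tail = text[cursor:]
    if tail.strip():
        lead = len(tail) - len(tail.lstrip())
        start = cursor + lead
        end = cursor + len(tail.rstrip())
        sentences.append(Sentence(start, end, text[start:end]))
    return sentences


_WS_RUN = re.compile(r"\s+")


def _normalize_ws(s: str) -> str:
    return _WS_RUN.sub(" ", s.lower())


def _header_pattern(headers: tuple[str, ...]) -> re.Pattern:
    alts = "|".join(re.escape(h) for h in headers)
    # Line-anchored, case-insensitive, optional trailing colon; the passage
    # starts right after the header (and its newline, if the header owns the
    # line).
    return re.compile(rf"(?im)^[ \t]*(?:{alts})[ \t]*:?[ \t]*\r?\n?")


def isolate_passage(
    raw_text: str, rules: DialectRules, note_id: str = ""
) -> Passage:
    """Locate the history passage under the dialect's rules and truncate it.

    Returns a :class:`Passage` whose ``text`` is always a verbatim slice of
    ``raw_text`` of at most ``rules.char_limit`` characters.
    """
    if not raw_text:
        raise ValueError("raw_text must be non-empty")

    start: int | None = None
    origin = "fallback_head"

    if rules.name == "penn":
        m = _header_pattern(rules.header_names).search(raw_text)
        if m is not None:
            start = m.end()
            origin = "header_match"
    elif rules.name == "michigan":
        phrases = [_normalize_ws(p) for p in rules.keyword_phrases]
        for sent in split_sentences(raw_text):
            norm = _normalize_ws(sent.text)
            if any(p in norm for p in phrases):
                start = sent.start
                origin = "keyword_match"
                break
    else:
        raise ValueError(f"unknown dialect {rules.name!r}")

    if start is None or start >= len(raw_text):
        start = 0
        origin = "fallback_head"

    text = raw_text[start : start + rules.char_limit]
    return Passage(text=text, origin=origin, start_offset=start, note_id=note_id)
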