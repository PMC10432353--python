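"""Gold-standard construction and agreement metrics.

Triplicate annotations are merged by majority vote: labels need two of three
annotators; spans are merged at the character level (a character enters the
merged span iff at least two annotators covered it, and maximal covered runs
become merged spans).  Disagreements that majority voting cannot resolve are
flagged for manual adjudication, never auto-resolved.

Agreement is measured with Cohen's kappa for the trinary classification and
token-overlap F1 for the extraction tasks, in two flavours:

* paired F1 — mean F1 over matched (token-overlapping) span pairs only;
* overall F1 — additionally scores every unmatched span as 0.0, penalising
  spans marked by only one side.  Hence overall <= paired whenever any span
  is unmatched.

``percent_agreement`` is the single headline metric: label equality for the
classification task; for extraction, the best-matched gold span must reach a
token-F1 threshold (default 0.5), and mutual absence (no gold span, explicit
no-answer) counts as agreement.
"""

from __future__ import annotations

import math
import string
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import AnnotationRecord, EXTRACTION_TASKS, GoldRecord, Prediction, Span

__all__ = [
    "AgreementReport",
    "merge_annotations",
    "cohens_kappa",
    "span_f1",
    "set_f1",
    "percent_agreement",
    "corpus_f1",
    "best_match_f1",
    "pairwise_annotator_kappa",
]


# ---------------------------------------------------------------------------
# Majority-vote merging


def merge_annotations(records: Sequence[AnnotationRecord], text: str) -> GoldRecord:
    """Merge exactly three annotation records for one note into a gold record.

    Label: any value held by >=2 annotators; a three-way split is flagged
    (``label_disagreement``) and recorded as ``unclassifiable`` pending
    adjudication.  Spans: character-level two-of-three vote per task; if an
    annotator marked a span for a task but the merge came out empty, the task
    is flagged (``<task>_empty_merge``).
    """
    if len(records) != 3:
        raise ValueError("exactly 3 annotation records are required")
    ids = {r.note_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records reference different notes: {sorted(ids)}")
    note_id = records[0].note_id

    flags: list[str] = []
    counts = Counter(r.label for r in records)
    label, top = counts.most_common(1)[0]
    if top < 2:
        flags.append("label_disagreement")
        label = "unclassifiable"

    merged: dict[str, list[Span]] = {}
    for task in (*EXTRACTION_TASKS, "outcome"):
        votes = np.zeros(len(text), dtype=np.int8)
        any_marked = False
        for r in records:
            mask = np.zeros(len(text), dtype=bool)
            for s in r.spans_for(task):
                if s.end > len(text):
                    raise ValueError(f"{note_id}: span [{s.start},{s.end}) outside text")
                mask[s.start : s.end] = True
                any_marked = True
            votes += mask
        covered = votes >= 2
        spans = [
            Span(int(a), int(b), text[a:b]) for a, b in _runs(covered)
        ]
        if any_marked and not spans:
            flags.append(f"{task}_empty_merge")
        merged[task] = spans

    return GoldRecord(
        note_id=note_id,
        label=label,
        frequency_spans=merged["frequency"],
        last_seizure_spans=merged["last_seizure"],
        outcome_spans=merged["outcome"],
        adjudication_flags=flags,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector, as half-open intervals."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


# ---------------------------------------------------------------------------
# Cohen's kappa


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two equal-length label sequences.

    kappa = (p_o - p_e) / (1 - p_e), with p_e from the two raters' marginal
    label frequencies.  When both raters are constant and identical
    (p_e = p_o = 1) the agreement is perfect and 1.0 is returned.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("label sequences must be non-empty")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum((ca[c] / n) * (cb[c] / n) for c in set(ca) | set(cb))
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def pairwise_annotator_kappa(annotation_sets: Sequence[Sequence[AnnotationRecord]]) -> float:
    """Mean Cohen's kappa over the three annotator pairs.

    ``annotation_sets`` holds one triple of records per note, annotators in a
    consistent order.
    """
    kappas = []
    for i in range(3):
        for j in range(i + 1, 3):
            a = [recs[i].label for recs in annotation_sets]
            b = [recs[j].label for recs in annotation_sets]
            kappas.append(cohens_kappa(a, b))
    return float(np.mean(kappas))


# ---------------------------------------------------------------------------
# Token-overlap F1

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def _tokens(text: str) -> list[str]:
    return text.lower().translate(_PUNCT_TABLE).split()


def span_f1(gold_text: str, pred_text: str) -> tuple[float, float, float]:
    """Token-overlap precision, recall and F1 between two span texts.

    Texts are lowercased, punctuation-stripped and whitespace-tokenised;
    overlap is counted on token multisets.  Both empty -> (1, 1, 1); exactly
    one empty -> (0, 0, 0).
    """
    g, p = _tokens(gold_text), _tokens(pred_text)
    if not g and not p:
        return (1.0, 1.0, 1.0)
    if not g or not p:
        return (0.0, 0.0, 0.0)
    shared = sum((Counter(g) & Counter(p)).values())
    if shared == 0:
        return (0.0, 0.0, 0.0)
    precision = shared / len(p)
    recall = shared / len(g)
    f1 = 2 * precision * recall / (precision + recall)
    return (precision, recall, f1)


def _greedy_match(
    gold_spans: Sequence[Span], pred_spans: Sequence[Span]
) -> tuple[list[float], int]:
    """Greedily pair spans by descending token F1 (zero-overlap pairs are
    never matched); ties break on earliest gold start, then pred start.
    Returns the matched-pair F1 values and the count of unmatched spans."""
    candidates = []
    for gi, g in enumerate(gold_spans):
        for pi, p in enumerate(pred_spans):
            f1 = span_f1(g.text, p.text)[2]
            if f1 > 0.0:
                candidates.append((-f1, g.start, p.start, gi, pi))
    candidates.sort()
    used_g: set[int] = set()
    used_p: set[int] = set()
    matched: list[float] = []
    for neg_f1, _gs, _ps, gi, pi in candidates:
        if gi in used_g or pi in used_p:
            continue
        used_g.add(gi)
        used_p.add(pi)
        matched.append(-neg_f1)
    unmatched = (len(gold_spans) - len(used_g)) + (len(pred_spans) - len(used_p))
    return matched, unmatched


def set_f1(
    gold_spans: Sequence[Span], pred_spans: Sequence[Span], mode: str = "overall"
) -> float:
    """Span-set F1 between two sets of spans over the same passage.

    ``paired`` averages token F1 over matched pairs only and is undefined
    (NaN) when no pair can be formed while spans exist on at most one side;
    ``overall`` additionally counts a 0.0 for every unmatched span.  Two
    empty sets agree vacuously (1.0) in both modes.
    """
    if mode not in ("paired", "overall"):
        raise ValueError(f"unknown mode {mode!r}")
    if not gold_spans and not pred_spans:
        return 1.0
    matched, unmatched = _greedy_match(gold_spans, pred_spans)
    if mode == "paired":
        if not matched:
            return math.nan
        return float(np.mean(matched))
    total = len(matched) + unmatched
    return float(sum(matched) / total)


def corpus_f1(
    gold_records: Sequence[AnnotationRecord],
    other_records: Mapping[str, AnnotationRecord] | Sequence[AnnotationRecord],
    task: str,
    mode: str = "overall",
    average: str = "per_note",
) -> float:
    """Mean set-level F1 across a corpus for one extraction task.

    ``average='per_note'`` averages each note's set_f1 (NaN paired values are
    skipped); ``average='pooled'`` pools matched-pair F1s and unmatched spans
    over all notes before averaging.
    """
    if not isinstance(other_records, Mapping):
        other_records = {r.note_id: r for r in other_records}
    per_note: list[float] = []
    pooled_matched: list[float] = []
    pooled_unmatched = 0
    for g in gold_records:
        o = other_records[g.note_id]
        gs, os_ = g.spans_for(task), o.spans_for(task)
        if average == "per_note":
            v = set_f1(gs, os_, mode)
            if not math.isnan(v):
                per_note.append(v)
        else:
            if not gs and not os_:
                continue
            m, u = _greedy_match(gs, os_)
            pooled_matched.extend(m)
            pooled_unmatched += u
    if average == "per_note":
        return float(np.mean(per_note)) if per_note else math.nan
    if mode == "paired":
        return float(np.mean(pooled_matched)) if pooled_matched else math.nan
    total = len(pooled_matched) + pooled_unmatched
    return float(sum(pooled_matched) / total) if total else 1.0


# ---------------------------------------------------------------------------
# Percent agreement (prediction vs gold)


def best_match_f1(gold_spans: Sequence[Span], pred_span: Span | None) -> float:
    """Token F1 of the prediction against its best-matched gold span.

    Mutual absence scores 1.0; one-sided absence scores 0.0.  Ties in F1 are
    broken by earliest gold start (the value is identical; the convention
    matters only to callers inspecting the matched span).
    """
    if not gold_spans and pred_span is None:
        return 1.0
    if not gold_spans or pred_span is None:
        return 0.0
    return max(span_f1(g.text, pred_span.text)[2] for g in gold_spans)


def percent_agreement(
    predictions: Mapping[str, Prediction] | Sequence[Prediction],
    gold_records: Sequence[GoldRecord],
    task: str,
    match_threshold: float = 0.5,
) -> float:
    """Fraction of notes where the prediction captures the gold information.

    Classification: label equality.  Extraction: mutual absence agrees;
    otherwise the best-matched gold span's token F1 must reach
    ``match_threshold`` (inclusive).
    """
    if not isinstance(predictions, Mapping):
        predictions = {p.note_id: p for p in predictions}
    if not gold_records:
        raise ValueError("no gold records")
    agree = 0
    for g in gold_records:
        if g.note_id not in predictions:
            raise KeyError(f"missing prediction for note {g.note_id}")
        p = predictions[g.note_id]
        if task == "classification":
            agree += p.label == g.label
        else:
            gs = g.spans_for(task)
            ps = p.span_for(task)
            if not gs and ps is None:
                agree += 1
            elif gs and ps is not None:
                agree += best_match_f1(gs, ps) >= match_threshold
    return agree / len(gold_records)


# ---------------------------------------------------------------------------
# Summary report


@dataclass
class AgreementReport:
    """Agreement summary for one comparison (annotator pair or model vs gold)."""

    kappa: float = math.nan
    paired_f1: dict = field(default_factory=dict)
    overall_f1: dict = field(default_factory=dict)
    percent_agreement: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "paired_f1": dict(self.paired_f1),
            "overall_f1": dict(self.overall_f1),
            "percent_agreement": dict(self.percent_agreement),
        }


def evaluate_predictions(
    gold_records: Sequence[GoldRecord],
    predictions: Sequence[Prediction] | Mapping[str, Prediction],
    match_threshold: float = 0.5,
) -> AgreementReport:
    """Full model-vs-gold agreement report: kappa + percent agreement for the
    classification task, paired/overall F1 + percent agreement per extraction
    task (a prediction contributes its span as a singleton set)."""
    if not isinstance(predictions, Mapping):
        predictions = {p.note_id: p for p in predictions}
    report = AgreementReport()
    labels_gold = [g.label for g in gold_records]
    labels_pred = [predictions[g.note_id].label for g in gold_records]
    report.kappa = cohens_kappa(labels_gold, labels_pred)
    report.percent_agreement["classification"] = percent_agreement(
        predictions, gold_records, "classification"
    )
    for task in EXTRACTION_TASKS:
        pred_sets = {
            nid: AnnotationRecord(
                note_id=nid,
                label=p.label,
                frequency_spans=[p.frequency_span] if p.frequency_span else [],
                last_seizure_spans=[p.last_seizure_span] if p.last_seizure_span else [],
            )
            for nid, p in predictions.items()
        }
        report.paired_f1[task] = corpus_f1(gold_records, pred_sets, task, "paired")
        report.overall_f1[task] = corpus_f1(gold_records, pred_sets, task, "overall")
        report.percent_agreement[task] = percent_agreement(
            predictions, gold_records, task, match_threshold
        )
    return report
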