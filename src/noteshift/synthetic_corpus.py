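"""Synthetic clinical-note corpora with gold annotations and simulated outputs.

Real epilepsy progress notes cannot be shared, so the audit pipeline ships a
generator that reproduces the *statistical* structure the analysis relies on,
with no claim to clinical language quality:

* Notes are assembled from template sentence banks per topic (epilepsy
  history, other neurology, general medicine), with slot-filled numbers,
  dates and drug names.  This makes the kernel/context decomposition exact
  by construction: the outcome-bearing sentences are known, and their spans
  are recorded as latent ground truth with precise character offsets.
* Per-specialty profiles control the trinary seizure-freedom class mix, the
  prevalence of seizure-frequency and date-of-last-seizure spans, and the
  topical mix of the surrounding context.  The shipped defaults are the
  published corpus statistics for each specialty (epileptologists
  30/62/8% class mix, 36% frequency-span and 50% last-seizure-span
  prevalence; analogous figures for neurologists, non-neurologists and the
  out-of-institution epileptologists).
* Triplicate annotators independently perturb the latent truth (label flips,
  span misses, boundary jitter), so majority-vote merging and agreement
  metrics have realistic inputs; with zero noise the merge returns the truth
  exactly.
* A simulated predictor stands in for the finetuned transformer pipeline:
  the probability of a correct output is logistic in the note's mean
  similarity to the training corpus, which is the mechanism the diagnostics
  are designed to detect.

All three simulation stages are pure functions of their seeds.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .preprocess import split_sentences
from .records import (
    LABELS,
    AnnotationRecord,
    EXTRACTION_TASKS,
    GoldRecord,
    Note,
    Prediction,
    Span,
)
from .similarity import SimilarityProfile

__all__ = [
    "SpecialtyProfile",
    "AnnotatorNoise",
    "PredictorEffect",
    "PROFILES",
    "generate_corpus",
    "simulate_annotators",
    "simulate_predictions",
]


# ---------------------------------------------------------------------------
# Parameters


@dataclass
class SpecialtyProfile:
    """Generator parameters for one author-specialty / institution stratum."""

    name: str
    p_class: tuple[float, float, float]  # over (seizure_free, having_seizures, unclassifiable)
    p_has_frequency_span: float
    p_has_last_seizure_span: float
    context_topic_mix: tuple[float, float, float]  # (epilepsy, other neuro, general medicine)
    dialect: str = "penn"
    context_sentences: tuple[int, int] = (6, 11)
    p_second_span: float = 0.15  # chance of a second span for a present task

    def __post_init__(self) -> None:
        if abs(sum(self.p_class) - 1.0) > 1e-9:
            raise ValueError("p_class must sum to 1")
        probs = (*self.p_class, self.p_has_frequency_span, self.p_has_last_seizure_span,
                 self.p_second_span)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(w < 0 for w in self.context_topic_mix) or sum(self.context_topic_mix) <= 0:
            raise ValueError("context_topic_mix weights must be nonnegative, not all zero")
        if self.dialect not in ("penn", "michigan"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        lo, hi = self.context_sentences
        if not (0 <= lo <= hi):
            raise ValueError("invalid context_sentences range")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "p_class": list(self.p_class),
            "p_has_frequency_span": self.p_has_frequency_span,
            "p_has_last_seizure_span": self.p_has_last_seizure_span,
            "context_topic_mix": list(self.context_topic_mix),
            "dialect": self.dialect,
            "context_sentences": list(self.context_sentences),
            "p_second_span": self.p_second_span,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpecialtyProfile":
        return cls(
            name=d["name"],
            p_class=tuple(d["p_class"]),
            p_has_frequency_span=d["p_has_frequency_span"],
            p_has_last_seizure_span=d["p_has_last_seizure_span"],
            context_topic_mix=tuple(d["context_topic_mix"]),
            dialect=d.get("dialect", "penn"),
            context_sentences=tuple(d.get("context_sentences", (6, 11))),
            p_second_span=d.get("p_second_span", 0.15),
        )


#: Published per-specialty corpus statistics, used as generator defaults.
PROFILES: dict[str, SpecialtyProfile] = {
    "epileptologist": SpecialtyProfile(
        name="epileptologist",
        p_class=(0.30, 0.62, 0.08),
        p_has_frequency_span=0.36,
        p_has_last_seizure_span=0.50,
        context_topic_mix=(0.80, 0.15, 0.05),
        dialect="penn",
    ),
    "neurologist": SpecialtyProfile(
        name="neurologist",
        p_class=(0.33, 0.47, 0.20),
        p_has_frequency_span=0.14,
        p_has_last_seizure_span=0.48,
        context_topic_mix=(0.45, 0.40, 0.15),
        dialect="penn",
    ),
    "non_neurologist": SpecialtyProfile(
        name="non_neurologist",
        p_class=(0.30, 0.35, 0.35),
        p_has_frequency_span=0.07,
        p_has_last_seizure_span=0.36,
        context_topic_mix=(0.15, 0.20, 0.65),
        dialect="penn",
    ),
    "michigan_epileptologist": SpecialtyProfile(
        name="michigan_epileptologist",
        p_class=(0.23, 0.63, 0.14),
        p_has_frequency_span=0.33,
        p_has_last_seizure_span=0.51,
        context_topic_mix=(0.80, 0.15, 0.05),
        dialect="michigan",
    ),
}


@dataclass
class AnnotatorNoise:
    """Independent per-annotator perturbation of the latent truth.

    Defaults are calibrated so that merged-vs-truth and pairwise annotator
    kappa land near 0.8, the scale reported for real triplicate annotation.
    """

    p_label_flip: float = 0.20
    p_span_miss: float = 0.15
    boundary_jitter_max: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_label_flip <= 1.0 and 0.0 <= self.p_span_miss <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.boundary_jitter_max < 0:
            raise ValueError("boundary_jitter_max must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "p_label_flip": self.p_label_flip,
            "p_span_miss": self.p_span_miss,
            "boundary_jitter_max": self.boundary_jitter_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotatorNoise":
        return cls(**d)


@dataclass
class PredictorEffect:
    """Logistic dependence of prediction correctness on similarity to training.

    logit(correct) = base_logit + beta_kernel * kernel_score
                                + beta_context * context_score,

    where kernel_score / context_score are the mean of the available
    (Levenshtein, cosine) measures for that side of the note's similarity
    profile; a fully missing side contributes 0.
    """

    beta_kernel: float = 0.0
    beta_context: float = 0.0
    base_logit: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.beta_kernel, self.beta_context, self.base_logit):
            if not math.isfinite(v):
                raise ValueError("effect parameters must be finite")

    def to_dict(self) -> dict:
        return {
            "beta_kernel": self.beta_kernel,
            "beta_context": self.beta_context,
            "base_logit": self.base_logit,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorEffect":
        return cls(**d)


# ---------------------------------------------------------------------------
# Template banks.  Kernel templates are (prefix, core, suffix) triples; the
# core is the annotated span.

_CONTEXT_BANKS = (
    (  # epilepsy history
        "The patient carries a diagnosis of {etype} epilepsy since {year}.",
        "Current regimen includes {drug} {dose} mg twice daily.",
        "Prior EEG in {year} showed {eeg}.",
        "There have been no adverse effects from the current regimen.",
        "MRI of the brain previously demonstrated {mri}.",
        "Events are typically preceded by a brief aura of epigastric rising.",
        "Medication adherence has been good per the patient and family.",
        "A previous trial of {drug} was stopped because of side effects.",
        "The semiology remains focal onset with impaired awareness.",
        "Seizure safety precautions were reviewed, including driving restrictions.",
    ),
    (  # other neurology
        "He also reports intermittent migraine headaches with photophobia.",
        "Gait examination was notable for mild appendicular ataxia.",
        "There is a history of essential tremor affecting the right hand.",
        "Sensory examination shows a length-dependent peripheral neuropathy.",
        "She follows in clinic for surveillance of multiple sclerosis.",
        "Cognitive screening at this visit was unremarkable for age.",
        "Nerve conduction studies in {year} were within normal limits.",
        "He describes occasional episodes of benign positional vertigo.",
    ),
    (  # general medicine
        "Blood pressure has been well controlled on {drug2}.",
        "He follows with cardiology for paroxysmal atrial fibrillation.",
        "Diabetes management was reviewed and the hemoglobin A1c was {a1c}.",
        "She was counseled on diet, exercise, and medication adherence.",
        "Immunizations were reviewed and updated at this visit.",
        "Review of systems was otherwise negative in detail.",
        "He reports no chest pain, dyspnea, or lower extremity edema.",
        "Screening colonoscopy was discussed and scheduled for {year}.",
    ),
)

_FREQUENCY_TEMPLATES = (
    ("He has had ", "{n} seizures in the last {m} months", "."),
    ("She reports approx. ", "{n} seizures per month", " on average."),
    ("Per the family he averages ", "{n} events per week", "."),
    ("Seizure burden is currently ", "about {n} seizures every {m} weeks", "."),
)

_LAST_SEIZURE_TEMPLATES = (
    ("Her last seizure was ", "in {month} {year}", "."),
    ("The last event occurred ", "on {month} {day}, {year}", "."),
    ("He states his ", "most recent seizure was {month} {year}", "."),
    ("The last convulsion was ", "around {month} of {year}", " per the patient."),
)

_OUTCOME_TEMPLATES = {
    "seizure_free": (
        ("", "She has been seizure free since the last visit", "."),
        ("", "No seizures in the past year", " per patient report."),
        ("", "He denies any seizures since {month} {year}", "."),
    ),
    "having_seizures": (
        ("", "He continues to have breakthrough seizures", " despite adjustments."),
        ("", "She is still having seizures", " at this time."),
        ("Unfortunately ", "seizures have recurred this month", "."),
    ),
}

# Unclassifiable notes carry no outcome evidence span, only an uninformative
# sentence.
_UNCLEAR_SENTENCES = (
    "Seizure control was not discussed in detail at this visit.",
    "It is unclear from the interview whether events have recurred.",
    "No reliable update on seizure activity was obtainable today.",
)

_PENN_PREAMBLE_SECTIONS = (
    "Medications:\n{drug} {dose} mg twice daily.\nAspirin 81 mg daily.",
    "Allergies:\nNo known drug allergies.",
    "Vital Signs:\nBP 122/78, HR 72, afebrile.",
)

_PENN_HEADERS = ("History of Present Illness:", "Interval History:")

_PENN_TRAILER = "\n\nAssessment and Plan:\nContinue the current regimen and follow up in clinic."

_MICHIGAN_LEADS = (
    "Seen in neurology clinic today for follow-up of epilepsy.",
    "Follow-up visit for seizure disorder management.",
)

_MICHIGAN_KEYWORD_SENTENCES = (
    "The patient was last seen in our clinic on {month} {day}, {year}.",
    "Interval events since the last visit were reviewed in detail.",
    "HPI: The patient returns for routine follow-up of epilepsy.",
)

_MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)

_SLOT_RE = re.compile(r"\{(\w+)\}")


def _fill(template: str, rng: np.random.Generator) -> str:
    values: dict[str, str] = {}
    for key in _SLOT_RE.findall(template):
        if key in values:
            continue
        if key == "n":
            values[key] = str(int(rng.integers(1, 10)))
        elif key == "m":
            values[key] = str(int(rng.integers(2, 13)))
        elif key == "day":
            values[key] = str(int(rng.integers(1, 29)))
        elif key == "year":
            values[key] = str(int(rng.integers(2015, 2019)))
        elif key == "month":
            values[key] = _MONTHS[int(rng.integers(0, 12))]
        elif key == "etype":
            values[key] = ("focal", "generalized", "temporal lobe", "frontal lobe")[
                int(rng.integers(0, 4))
            ]
        elif key == "drug":
            values[key] = (
                "levetiracetam", "lamotrigine", "carbamazepine",
                "valproate", "zonisamide", "lacosamide",
            )[int(rng.integers(0, 6))]
        elif key == "dose":
            values[key] = str((100, 200, 250, 500, 750, 1000)[int(rng.integers(0, 6))])
        elif key == "eeg":
            values[key] = (
                "left temporal sharp waves", "generalized spike-and-wave discharges",
                "no epileptiform abnormalities", "right frontal slowing",
            )[int(rng.integers(0, 4))]
        elif key == "mri":
            values[key] = (
                "mesial temporal sclerosis", "a normal study",
                "nonspecific white matter changes",
            )[int(rng.integers(0, 3))]
        elif key == "drug2":
            values[key] = ("lisinopril", "metoprolol", "amlodipine")[int(rng.integers(0, 3))]
        elif key == "a1c":
            values[key] = ("6.4", "7.1", "7.8", "8.2")[int(rng.integers(0, 4))]
        else:
            raise KeyError(f"unknown template slot {key!r}")
    return template.format(**values)


# ---------------------------------------------------------------------------
# Note assembly


class _Builder:
    """Accumulates text parts while tracking absolute character offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.spans: dict[str, list[tuple[int, int]]] = {t: [] for t in (*EXTRACTION_TASKS, "outcome")}

    def add(self, text: str) -> None:
        self.parts.append(text)
        self.length += len(text)

    def add_kernel(self, prefix: str, core: str, suffix: str, task: str) -> None:
        self.add(prefix)
        self.spans[task].append((self.length, self.length + len(core)))
        self.add(core)
        self.add(suffix)

    def text(self) -> str:
        return "".join(self.parts)


def _body_items(
    profile: SpecialtyProfile, label: str, rng: np.random.Generator
) -> list[tuple]:
    """Draw the history-body sentences: ('ctx', text) and ('kernel', prefix,
    core, suffix, task) items in final order."""
    mix = np.asarray(profile.context_topic_mix, dtype=float)
    mix = mix / mix.sum()
    lo, hi = profile.context_sentences
    n_ctx = int(rng.integers(lo, hi + 1))
    items: list[tuple] = []
    for _ in range(n_ctx):
        bank = _CONTEXT_BANKS[int(rng.choice(3, p=mix))]
        items.append(("ctx", _fill(bank[int(rng.integers(0, len(bank)))], rng)))

    kernels: list[tuple] = []
    if label in _OUTCOME_TEMPLATES:
        tpl = _OUTCOME_TEMPLATES[label][int(rng.integers(0, len(_OUTCOME_TEMPLATES[label])))]
        kernels.append(("kernel", _fill(tpl[0], rng), _fill(tpl[1], rng), tpl[2], "outcome"))
    else:
        items.append(("ctx", _UNCLEAR_SENTENCES[int(rng.integers(0, len(_UNCLEAR_SENTENCES)))]))

    for task, prob, bank in (
        ("frequency", profile.p_has_frequency_span, _FREQUENCY_TEMPLATES),
        ("last_seizure", profile.p_has_last_seizure_span, _LAST_SEIZURE_TEMPLATES),
    ):
        if rng.random() < prob:
            n_spans = 2 if rng.random() < profile.p_second_span else 1
            for _ in range(n_spans):
                tpl = bank[int(rng.integers(0, len(bank)))]
                kernels.append(("kernel", _fill(tpl[0], rng), _fill(tpl[1], rng), tpl[2], task))

    for k in kernels:
        pos = int(rng.integers(0, len(items) + 1))
        items.insert(pos, k)
    return items


def _assemble(
    profile: SpecialtyProfile, label: str, rng: np.random.Generator, note_id: str
) -> Note:
    b = _Builder()
    items = _body_items(profile, label, rng)

    if profile.dialect == "penn":
        n_pre = int(rng.integers(1, 3))
        sections = list(rng.choice(len(_PENN_PREAMBLE_SECTIONS), size=n_pre, replace=False))
        for si in sections:
            b.add(_fill(_PENN_PREAMBLE_SECTIONS[si], rng))
            b.add("\n\n")
        header = _PENN_HEADERS[0] if rng.random() < 0.7 else _PENN_HEADERS[1]
        b.add(header + "\n")
    else:
        if rng.random() < 0.6:
            b.add(_MICHIGAN_LEADS[int(rng.integers(0, len(_MICHIGAN_LEADS)))] + " ")
        if rng.random() < 0.9:
            tpl = _MICHIGAN_KEYWORD_SENTENCES[
                int(rng.integers(0, len(_MICHIGAN_KEYWORD_SENTENCES)))
            ]
            b.add(_fill(tpl, rng) + " ")

    for i, item in enumerate(items):
        if item[0] == "ctx":
            b.add(item[1])
        else:
            _, prefix, core, suffix, task = item
            b.add_kernel(prefix, core, suffix, task)
        if i < len(items) - 1:
            b.add(" ")

    if profile.dialect == "penn" and rng.random() < 0.5:
        b.add(_PENN_TRAILER)

    text = b.text()

    def spans_of(task: str) -> list[Span]:
        return [Span(a, z, text[a:z]) for a, z in b.spans[task]]

    truth = GoldRecord(
        note_id=note_id,
        label=label,
        frequency_spans=spans_of("frequency"),
        last_seizure_spans=spans_of("last_seizure"),
        outcome_spans=spans_of("outcome"),
    )
    return Note(
        note_id=note_id,
        specialty=profile.name,
        dialect=profile.dialect,
        raw_text=text,
        truth=truth,
    )


def generate_corpus(profile: SpecialtyProfile, n: int, seed: int) -> list[Note]:
    """Generate ``n`` synthetic notes under a specialty profile.

    A pure function of (profile, n, seed): each note is drawn from its own
    seeded stream, so note ``i`` is identical across calls regardless of
    ``n``.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    notes = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        label = LABELS[int(rng.choice(3, p=np.asarray(profile.p_class)))]
        note_id = f"{profile.name}-{seed}-{i:05d}"
        notes.append(_assemble(profile, label, rng, note_id))
    return notes


# ---------------------------------------------------------------------------
# Triplicate annotator simulation


def _note_stream(seed: int, note_id: str, salt: int = 0) -> np.random.Generator:
    digest = hashlib.blake2b(note_id.encode(), digest_size=4).digest()
    return np.random.default_rng([seed, salt, int.from_bytes(digest, "little")])


def _perturb_span(
    s: Span, text: str, jitter: int, rng: np.random.Generator
) -> Span:
    d1 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    d2 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    start = min(max(s.start + d1, 0), len(text) - 1)
    end = min(max(s.end + d2, start + 1), len(text))
    return Span(start, end, text[start:end])


def simulate_annotators(
    note: Note, noise: AnnotatorNoise, seed: int
) -> list[AnnotationRecord]:
    """Three independent noisy annotations of a note's latent truth.

    Each annotator flips the label to a uniformly chosen other label with
    probability ``p_label_flip``, drops each span with ``p_span_miss``, and
    jitters surviving span boundaries by a uniform integer in
    [-boundary_jitter_max, +boundary_jitter_max], clipped to text bounds.
    """
    rng = _note_stream(seed, note.note_id, salt=1)
    text = note.raw_text
    records = []
    for _ in range(3):
        label = note.truth.label
        if noise.p_label_flip > 0 and rng.random() < noise.p_label_flip:
            others = [l for l in LABELS if l != label]
            label = others[int(rng.integers(0, len(others)))]
        spans: dict[str, list[Span]] = {}
        for task in (*EXTRACTION_TASKS, "outcome"):
            kept = []
            for s in note.truth.spans_for(task):
                if noise.p_span_miss > 0 and rng.random() < noise.p_span_miss:
                    continue
                kept.append(_perturb_span(s, text, noise.boundary_jitter_max, rng))
            spans[task] = kept
        records.append(
            AnnotationRecord(
                note_id=note.note_id,
                label=label,
                frequency_spans=spans["frequency"],
                last_seizure_spans=spans["last_seizure"],
                outcome_spans=spans["outcome"],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Simulated predictor


def _side_score(profile: SimilarityProfile, side: str) -> float:
    vals = [
        v
        for v in (profile.value(f"lev_{side}"), profile.value(f"cos_{side}"))
        if not math.isnan(v)
    ]
    return float(np.mean(vals)) if vals else 0.0


def _decoy_span(note: Note, rng: np.random.Generator) -> Span:
    """A context sentence of the note, used as a wrong extraction answer."""
    truth_spans = note.truth.all_spans()
    sentences = [
        s
        for s in split_sentences(note.raw_text)
        if not any(sp.overlaps(s.start, s.end) for sp in truth_spans)
    ]
    if not sentences:
        end = min(40, len(note.raw_text))
        return Span(0, end, note.raw_text[:end])
    s = sentences[int(rng.integers(0, len(sentences)))]
    return Span(s.start, s.end, s.text)


def simulate_predictions(
    notes: Sequence[Note],
    profiles: Mapping[str, SimilarityProfile],
    effect: PredictorEffect,
) -> list[Prediction]:
    """Simulate one prediction per note under a similarity-correctness effect.

    Correctness of the classification and of each extraction task is drawn
    independently as Bernoulli with the logit of :class:`PredictorEffect`.
    Correct classifications emit the true label, incorrect ones a uniformly
    chosen other label.  Correct extractions emit the first gold span (or a
    no-answer when the truth has none); incorrect ones emit a decoy context
    sentence or a spurious no-answer.  Deterministic given ``effect.seed``.
    """
    preds = []
    for note in notes:
        if note.note_id not in profiles:
            raise KeyError(f"missing similarity profile for note {note.note_id}")
        prof = profiles[note.note_id]
        logit = (
            effect.base_logit
            + effect.beta_kernel * _side_score(prof, "kernel")
            + effect.beta_context * _side_score(prof, "context")
        )
        p_correct = float(expit(logit))
        rng = _note_stream(effect.seed, note.note_id, salt=2)

        if rng.random() < p_correct:
            label = note.truth.label
        else:
            others = [l for l in LABELS if l != note.truth.label]
            label = others[int(rng.integers(0, len(others)))]

        spans: dict[str, Span | None] = {}
        for task in EXTRACTION_TASKS:
            gold = note.truth.spans_for(task)
            if rng.random() < p_correct:
                spans[task] = replace(gold[0]) if gold else None
            elif gold:
                spans[task] = _decoy_span(note, rng) if rng.random() < 0.5 else None
            else:
                spans[task] = _decoy_span(note, rng)
        preds.append(
            Prediction(
                note_id=note.note_id,
                seed=effect.seed,
                label=label,
                frequency_span=spans["frequency"],
                last_seizure_span=spans["last_seizure"],
            )
        )
    return preds


# ---------------------------------------------------------------------------
# Config round-trip


def load_generator_config(path: str | Path) -> dict:
    """Load a generator config JSON into typed objects.

    Keys: ``profiles`` (list of SpecialtyProfile dicts), ``noise``
    (AnnotatorNoise dict), ``effect`` (PredictorEffect dict); all optional,
    defaults apply.
    """
    d = json.loads(Path(path).read_text())
    return {
        "profiles": {
            p["name"]: SpecialtyProfile.from_dict(p) for p in d.get("profiles", ())
        }
        or dict(PROFILES),
        "noise": AnnotatorNoise.from_dict(d["noise"]) if "noise" in d else AnnotatorNoise(),
        "effect": PredictorEffect.from_dict(d["effect"]) if "effect" in d else PredictorEffect(),
    }
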