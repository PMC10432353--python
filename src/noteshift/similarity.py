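"""Kernel/context decomposition and similarity profiling against a training corpus.

Each passage is split into the *kernel* — the sentences overlapping any gold
span, i.e. the sentences carrying the information the extraction tasks target
— and the *surrounding context*, everything else.  Four similarity measures
are then computed per test note against every note of the training corpus:

* ``lev_kernel`` / ``lev_context`` — normalised character-level Levenshtein
  similarity, 1 - d(a, b) / max(|a|, |b|), on case-folded text: a syntactic
  ("how differently written") measure;
* ``cos_kernel`` / ``cos_context`` — cosine similarity of text embeddings: a
  semantic measure.  The built-in provider is a deterministic hashed
  bag-of-words term-frequency embedding (dimension 512, L2-normalised), so
  the full pipeline runs offline; any object satisfying
  :class:`EmbeddingProvider` (e.g. a sentence-transformer wrapper) can be
  plugged in instead.

A test note's profile stores, per measure, the *mean* pairwise similarity to
all training notes with a non-empty corresponding side; the within-training
reference distribution stores all unordered training pairs (self-pairs
excluded) and is the baseline for Q-Q comparisons downstream.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import edlib
import numpy as np

from .preprocess import Passage, split_sentences
from .records import AnnotationRecord, GoldRecord, Span

MEASURES = ("lev_kernel", "lev_context", "cos_kernel", "cos_context")


# ---------------------------------------------------------------------------
# Kernel / context split


@dataclass
class KernelContextSplit:
    """A passage's sentences partitioned into kernel and surrounding context."""

    note_id: str
    kernel_text: str
    context_text: str


def rebase_spans(spans: Sequence[Span], passage: Passage) -> list[Span]:
    """Project note-coordinate spans into passage coordinates, clipping at the
    passage boundary and dropping spans that fall entirely outside."""
    out: list[Span] = []
    lo, hi = passage.start_offset, passage.start_offset + len(passage.text)
    for s in spans:
        a, b = max(s.start, lo), min(s.end, hi)
        if a < b:
            out.append(Span(a - lo, b - lo, passage.text[a - lo : b - lo]))
    return out


def split_kernel_context(
    passage: Passage,
    gold: GoldRecord | AnnotationRecord,
    include_outcome: bool = True,
    rebase: bool = True,
) -> KernelContextSplit:
    """Partition a passage's sentences into kernel and context.

    Kernel sentences are those overlapping any gold span (frequency,
    last-seizure, and — by default — the seizure-freedom evidence span); all
    remaining sentences form the context.  Order is preserved and each side
    is joined with single spaces.  Gold spans are in note coordinates when
    ``rebase`` is true (the usual case), else already in passage coordinates.
    """
    spans = list(gold.frequency_spans) + list(gold.last_seizure_spans)
    if include_outcome:
        spans += list(gold.outcome_spans)
    if rebase:
        spans = rebase_spans(spans, passage)
    else:
        for s in spans:
            if s.end > len(passage.text):
                raise ValueError(
                    f"{gold.note_id}: span [{s.start},{s.end}) outside passage"
                )
    kernel, context = [], []
    for sent in split_sentences(passage.text):
        if any(sp.overlaps(sent.start, sent.end) for sp in spans):
            kernel.append(sent.text)
        else:
            context.append(sent.text)
    return KernelContextSplit(
        note_id=passage.note_id,
        kernel_text=" ".join(kernel),
        context_text=" ".join(context),
    )


# ---------------------------------------------------------------------------
# Levenshtein similarity


def _edit_distance(a: str, b: str) -> int:
    try:
        return edlib.align(a, b)["editDistance"]
    except (ValueError, MemoryError):  # e.g. alphabet too large for edlib
        return _dp_edit_distance(a, b)


def _dp_edit_distance(a: str, b: str) -> int:
    """Two-row Wagner-Fischer fallback for inputs edlib cannot handle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_similarity(a: str, b: str, case_fold: bool = True) -> float:
    """Normalised character-level Levenshtein similarity in [0, 1].

    1 - d(a, b) / max(|a|, |b|); two empty strings are identical (1.0).
    """
    if case_fold:
        a, b = a.casefold(), b.casefold()
    if not a and not b:
        return 1.0
    longest = max(len(a), len(b))
    return 1.0 - _edit_distance(a, b) / longest


# ---------------------------------------------------------------------------
# Embeddings and cosine similarity


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Anything that deterministically maps text to a fixed-length vector.

    The zero vector is reserved for empty text.
    """

    dimension: int

    def embed(self, text: str) -> np.ndarray: ...


class HashedBagOfWords:
    """Deterministic hashed bag-of-words term-frequency embedding.

    Tokens (lowercased ``\\w+`` runs) are hashed with BLAKE2b under a fixed
    seed into ``dimension`` buckets; counts are L2-normalised.  Counts are
    nonnegative, so the zero vector arises only for token-free text.
    """

    def __init__(self, dimension: int = 512, hash_seed: int = 13) -> None:
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        self.dimension = dimension
        self._salt = hash_seed.to_bytes(8, "little")
        self._cache: dict[str, int] = {}

    def _bucket(self, token: str) -> int:
        idx = self._cache.get(token)
        if idx is None:
            h = hashlib.blake2b(token.encode(), digest_size=8, salt=self._salt)
            idx = int.from_bytes(h.digest(), "little") % self.dimension
            self._cache[token] = idx
        return idx

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for token in _word_tokens(text):
            vec[self._bucket(token)] += 1.0
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


_WORD = re.compile(r"\w+")


def _word_tokens(text: str) -> list[str]:
    return _WORD.findall(text.lower())


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two non-zero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for the zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


# ---------------------------------------------------------------------------
# Profiling against the training corpus


@dataclass
class SimilarityProfile:
    """Per-note mean pairwise similarity to the training corpus, per measure.

    A measure is NaN when the note's corresponding side (kernel or context)
    is empty, or when no training note has that side.
    """

    note_id: str
    lev_kernel: float
    lev_context: float
    cos_kernel: float
    cos_context: float
    n_train: int

    def value(self, measure: str) -> float:
        return getattr(self, measure)

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "lev_kernel": self.lev_kernel,
            "lev_context": self.lev_context,
            "cos_kernel": self.cos_kernel,
            "cos_context": self.cos_context,
            "n_train": self.n_train,
        }


@dataclass
class ReferenceDistribution:
    """All pairwise similarities among training notes (unordered pairs,
    self-pairs excluded), per measure."""

    values: dict[str, np.ndarray] = field(default_factory=dict)
    n_train: int = 0

    def median(self, measure: str) -> float:
        v = self.values[measure]
        return float(np.median(v)) if v.size else math.nan


def _sides(split: KernelContextSplit, measure: str) -> str:
    return split.kernel_text if measure.endswith("kernel") else split.context_text


def profile_against_training(
    test_splits: Sequence[KernelContextSplit],
    train_splits: Sequence[KernelContextSplit],
    provider: EmbeddingProvider | None = None,
) -> tuple[list[SimilarityProfile], ReferenceDistribution]:
    """Compute the four mean pairwise similarities of each test note against
    the training corpus, plus the within-training reference distribution.

    Embeddings are computed once per text.  Means are taken over training
    notes whose corresponding side is non-empty; a test note with an empty
    side gets NaN for that side's measures.
    """
    if not train_splits:
        raise ValueError("training corpus must be non-empty")
    provider = provider or HashedBagOfWords()

    n_train = len(train_splits)
    sides = {
        "kernel": ([s.kernel_text for s in test_splits], [s.kernel_text for s in train_splits]),
        "context": ([s.context_text for s in test_splits], [s.context_text for s in train_splits]),
    }

    means: dict[str, np.ndarray] = {}
    ref = ReferenceDistribution(n_train=n_train)

    for side, (test_texts, train_texts) in sides.items():
        train_ok = [bool(t) for t in train_texts]
        ok_idx = [i for i, ok in enumerate(train_ok) if ok]

        # Levenshtein
        lev = np.full(len(test_texts), math.nan)
        for ti, text in enumerate(test_texts):
            if text and ok_idx:
                lev[ti] = float(
                    np.mean([levenshtein_similarity(text, train_texts[j]) for j in ok_idx])
                )
        means[f"lev_{side}"] = lev
        ref.values[f"lev_{side}"] = np.array(
            [
                levenshtein_similarity(train_texts[i], train_texts[j])
                for ii, i in enumerate(ok_idx)
                for j in ok_idx[ii + 1 :]
            ]
        )

        # Cosine (vectorised; provider outputs are L2-normalised here again
        # so arbitrary providers need not pre-normalise)
        emb_train = np.stack([provider.embed(t) for t in train_texts]) if train_texts else None
        emb_test = (
            np.stack([provider.embed(t) for t in test_texts])
            if test_texts
            else np.zeros((0, provider.dimension))
        )
        cos = np.full(len(test_texts), math.nan)
        if ok_idx:
            tr = _l2_rows(emb_train[ok_idx])
            te_norms = np.linalg.norm(emb_test, axis=1)
            for ti in range(len(test_texts)):
                if test_texts[ti] and te_norms[ti] > 0:
                    cos[ti] = float(np.mean(tr @ (emb_test[ti] / te_norms[ti])))
            g = tr @ tr.T
            iu = np.triu_indices(len(ok_idx), k=1)
            ref.values[f"cos_{side}"] = np.clip(g[iu], -1.0, 1.0)
        else:
            ref.values[f"cos_{side}"] = np.array([])
        means[f"cos_{side}"] = cos

    profiles = [
        SimilarityProfile(
            note_id=s.note_id,
            lev_kernel=float(means["lev_kernel"][i]),
            lev_context=float(means["lev_context"][i]),
            cos_kernel=float(means["cos_kernel"][i]),
            cos_context=float(means["cos_context"][i]),
            n_train=n_train,
        )
        for i, s in enumerate(test_splits)
    ]
    return profiles, ref


def _l2_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return m / norms
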