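"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: edit
distance is a plain recurrence over the full DP table, and the Mann-Whitney
p-value is an exhaustive enumeration over group assignments.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import pytest

from noteshift.cli import annotate_and_merge, passages_and_splits
from noteshift.records import GoldRecord, Span
from noteshift.synthetic_corpus import AnnotatorNoise, PROFILES, generate_corpus


def dp_levenshtein(a: str, b: str) -> int:
    """Full-table Wagner-Fischer edit distance (reference oracle)."""
    n, m = len(a), len(b)
    table = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        table[i][0] = i
    for j in range(m + 1):
        table[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            table[i][j] = min(
                table[i - 1][j] + 1,
                table[i][j - 1] + 1,
                table[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return table[n][m]


def mw_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney (U of x, p) for tie-free samples by
    enumerating every assignment of pooled ranks to the x group."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free samples"
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    n, m = len(x), len(y)
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    total = comb(n + m, n)
    us = [
        sum(pos + 1 for pos in subset) - n * (n + 1) / 2
        for subset in combinations(range(n + m), n)
    ]
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def make_gold(note_id: str, label: str = "having_seizures", **span_kw) -> GoldRecord:
    """Convenience constructor for hand-built gold records."""
    return GoldRecord(note_id=note_id, label=label, **span_kw)


@pytest.fixture(scope="session")
def epi_corpus():
    """A small epileptologist corpus with noisy annotations and merged gold."""
    notes = generate_corpus(PROFILES["epileptologist"], 60, 42)
    gold = annotate_and_merge(notes, AnnotatorNoise(), 43)
    return notes, gold


@pytest.fixture(scope="session")
def epi_splits(epi_corpus):
    notes, gold = epi_corpus
    _, splits = passages_and_splits(notes, gold, 1506)
    return splits
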