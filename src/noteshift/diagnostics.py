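"""Correctness-stratified shift diagnostics.

Given per-note similarity profiles and model outputs, this module answers the
question "did the model do better on notes that look more like its training
data?" in two ways:

1. Stratified two-sided Mann-Whitney U tests per similarity measure, the
   strata being notes the model got right vs wrong (label equality for the
   classification task; best token-overlap F1 >= 0.50 for extraction).
2. Q-Q tables comparing a test set's similarity distribution against the
   within-training reference distribution.  No p-values are attached to
   these distribution-level comparisons: with tens of thousands of pairwise
   values they would be arbitrarily small and uninformative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import best_match_f1
from .records import EXTRACTION_TASKS, GoldRecord, Prediction
from .similarity import MEASURES, ReferenceDistribution, SimilarityProfile

__all__ = [
    "CorrectnessLabel",
    "StratifiedComparison",
    "QQTable",
    "label_correctness",
    "mann_whitney_u",
    "stratified_comparison",
    "qq_table",
    "ShiftReport",
]


@dataclass
class CorrectnessLabel:
    """Per-note correctness of one prediction set.

    ``extraction_success`` is the conjunction over extraction tasks where
    either side produced spans (best F1 >= threshold); when no task has
    spans on either side the note is a vacuous success (``vacuous=True``).
    """

    note_id: str
    classification_correct: bool
    extraction_success: bool
    vacuous: bool = False


def label_correctness(
    predictions: Mapping[str, Prediction] | Sequence[Prediction],
    gold_records: Sequence[GoldRecord],
    threshold: float = 0.50,
    task: str | None = None,
) -> list[CorrectnessLabel]:
    """Label each note's prediction as correct/incorrect per task.

    ``task`` restricts extraction success to one task ("frequency" or
    "last_seizure"); by default both tasks are combined.  Mutual absence of
    an answer counts as success (and is flagged vacuous when no task is
    informative).  The F1 threshold is inclusive.
    """
    if not isinstance(predictions, Mapping):
        predictions = {p.note_id: p for p in predictions}
    tasks = EXTRACTION_TASKS if task is None else (task,)
    out: list[CorrectnessLabel] = []
    for g in gold_records:
        if g.note_id not in predictions:
            raise KeyError(f"missing prediction for note {g.note_id}")
        p = predictions[g.note_id]
        success = True
        informative = False
        for t in tasks:
            gs, ps = g.spans_for(t), p.span_for(t)
            if not gs and ps is None:
                continue
            informative = True
            success = success and best_match_f1(gs, ps) >= threshold
        out.append(
            CorrectnessLabel(
                note_id=g.note_id,
                classification_correct=p.label == g.label,
                extraction_success=success,
                vacuous=not informative,
            )
        )
    return out


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    ``auto`` uses exact enumeration when n_x * n_y <= 400 and the pooled
    sample is tie-free, else the normal approximation with tie and
    continuity corrections.  Returns (U, p) with U the statistic of ``x``.
    Completely tied samples return (n_x * n_y / 2, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return (x.size * y.size / 2.0, 1.0)
    if method == "auto":
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (x.size * y.size <= 400 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return (float(res.statistic), float(min(res.pvalue, 1.0)))


@dataclass
class StratifiedComparison:
    """Mann-Whitney comparison of one similarity measure across strata."""

    measure: str
    n_correct: int
    n_incorrect: int
    U: float
    p: float
    median_correct: float
    median_incorrect: float
    computable: bool = True

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "U": self.U,
            "p": self.p,
            "median_correct": self.median_correct,
            "median_incorrect": self.median_incorrect,
            "computable": self.computable,
        }


def stratified_comparison(
    profiles: Sequence[SimilarityProfile],
    correctness: Sequence[CorrectnessLabel],
    task: str = "classification",
) -> list[StratifiedComparison]:
    """One Mann-Whitney comparison per similarity measure, correct vs
    incorrect.  ``task`` is "classification" or "extraction".  Notes with a
    missing (NaN) measure are excluded from that measure's comparison; an
    empty stratum yields a non-computable entry rather than an exception.
    """
    if task not in ("classification", "extraction"):
        raise ValueError(f"unknown task {task!r}")
    by_id = {c.note_id: c for c in correctness}
    out: list[StratifiedComparison] = []
    for measure in MEASURES:
        correct_vals, incorrect_vals = [], []
        for prof in profiles:
            c = by_id.get(prof.note_id)
            if c is None:
                continue
            v = prof.value(measure)
            if math.isnan(v):
                continue
            flag = (
                c.classification_correct if task == "classification" else c.extraction_success
            )
            (correct_vals if flag else incorrect_vals).append(v)
        n_c, n_i = len(correct_vals), len(incorrect_vals)
        med_c = float(np.median(correct_vals)) if n_c else math.nan
        med_i = float(np.median(incorrect_vals)) if n_i else math.nan
        if n_c == 0 or n_i == 0:
            out.append(
                StratifiedComparison(measure, n_c, n_i, math.nan, math.nan, med_c, med_i, False)
            )
        else:
            U, p = mann_whitney_u(correct_vals, incorrect_vals)
            out.append(StratifiedComparison(measure, n_c, n_i, U, p, med_c, med_i, True))
    return out


@dataclass
class QQTable:
    """Quantiles of a sample against a reference distribution, for Q-Q plots."""

    measure: str
    grid: np.ndarray
    sample_quantiles: np.ndarray
    reference_quantiles: np.ndarray
    sample_median: float
    reference_median: float

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "grid": self.grid.tolist(),
            "sample_quantiles": self.sample_quantiles.tolist(),
            "reference_quantiles": self.reference_quantiles.tolist(),
            "sample_median": self.sample_median,
            "reference_median": self.reference_median,
        }


def qq_table(
    sample: Sequence[float],
    reference: Sequence[float],
    grid: Sequence[float] | None = None,
    measure: str = "",
) -> QQTable:
    """Linear-interpolation quantiles of sample and reference on a common
    grid (default the 99 percentiles 0.01..0.99)."""
    sample = np.asarray(sample, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if sample.size == 0 or reference.size == 0:
        raise ValueError("sample and reference must be non-empty")
    if grid is None:
        grid = np.arange(1, 100) / 100.0
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid values must lie in (0, 1)")
    return QQTable(
        measure=measure,
        grid=grid,
        sample_quantiles=np.quantile(sample, grid, method="linear"),
        reference_quantiles=np.quantile(reference, grid, method="linear"),
        sample_median=float(np.median(sample)),
        reference_median=float(np.median(reference)),
    )


@dataclass
class ShiftReport:
    """Bundle of stratified comparisons and Q-Q tables for one test set."""

    comparisons: dict[str, list[StratifiedComparison]] = field(default_factory=dict)
    qq: list[QQTable] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "comparisons": {
                k: [c.to_dict() for c in v] for k, v in self.comparisons.items()
            },
            "qq": [t.to_dict() for t in self.qq],
            "notes": dict(self.notes),
        }


def build_shift_report(
    profiles: Sequence[SimilarityProfile],
    correctness: Sequence[CorrectnessLabel],
    reference: ReferenceDistribution,
) -> ShiftReport:
    """Stratified comparisons for both tasks plus per-measure Q-Q tables of
    the test profiles against the within-training reference."""
    report = ShiftReport()
    for task in ("classification", "extraction"):
        report.comparisons[task] = stratified_comparison(profiles, correctness, task)
    for measure in MEASURES:
        vals = np.array(
            [p.value(measure) for p in profiles if not math.isnan(p.value(measure))]
        )
        ref_vals = reference.values.get(measure, np.array([]))
        if vals.size and ref_vals.size:
            report.qq.append(qq_table(vals, ref_vals, measure=measure))
    n_missing = {
        measure: int(sum(math.isnan(p.value(measure)) for p in profiles))
        for measure in MEASURES
    }
    report.notes["n_missing_per_measure"] = n_missing
    return report


def plot_qq(report: ShiftReport, path: str) -> None:
    """Render the Q-Q tables as a panel figure (one per measure) with the
    identity line and per-distribution medians."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tables = report.qq
    if not tables:
        raise ValueError("report has no Q-Q tables")
    fig, axes = plt.subplots(1, len(tables), figsize=(4 * len(tables), 4))
    if len(tables) == 1:
        axes = [axes]
    for ax, t in zip(axes, tables):
        ax.plot(t.reference_quantiles, t.sample_quantiles, "o", ms=3)
        lo = min(t.reference_quantiles.min(), t.sample_quantiles.min())
        hi = max(t.reference_quantiles.max(), t.sample_quantiles.max())
        ax.plot([lo, hi], [lo, hi], "k-", lw=1)
        ax.axvline(t.reference_median, ls="--", lw=0.8, color="red")
        ax.axhline(t.sample_median, ls="--", lw=0.8, color="blue")
        ax.set_title(t.measure)
        ax.set_xlabel("training reference quantiles")
        ax.set_ylabel("test-set quantiles")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
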