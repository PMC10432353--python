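"""Majority-vote merging and agreement metrics."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noteshift.annotation import (
    cohens_kappa,
    corpus_f1,
    merge_annotations,
    percent_agreement,
    set_f1,
    span_f1,
)
from noteshift.records import AnnotationRecord, GoldRecord, Prediction, Span

TEXT = "0123456789abcdefghij klmnopqrst uvwxyz ABCDE."


def rec(label="seizure_free", freq=(), last=(), note_id="n1"):
    mk = lambda spans: [Span(a, b, TEXT[a:b]) for a, b in spans]
    return AnnotationRecord(
        note_id=note_id, label=label, frequency_spans=mk(freq), last_seizure_spans=mk(last)
    )


class TestMerge:
    def test_unanimity_returns_input_no_flags(self):
        r = rec(freq=[(0, 10)], last=[(21, 31)])
        g = merge_annotations([r, r, r], TEXT)
        assert g.label == r.label
        assert g.frequency_spans == r.frequency_spans
        assert g.last_seizure_spans == r.last_seizure_spans
        assert g.adjudication_flags == []

    def test_majority_label_wins(self):
        g = merge_annotations(
            [rec("seizure_free"), rec("seizure_free"), rec("having_seizures")], TEXT
        )
        assert g.label == "seizure_free"
        assert g.adjudication_flags == []

    def test_three_way_label_split_flagged(self):
        g = merge_annotations(
            [rec("seizure_free"), rec("having_seizures"), rec("unclassifiable")], TEXT
        )
        assert g.label == "unclassifiable"
        assert "label_disagreement" in g.adjudication_flags

    def test_character_vote_merge(self):
        # chars 0-4 get 2 votes, 5-9 get 3, 10-14 get 1 -> merged span [0,10)
        g = merge_annotations(
            [rec(freq=[(0, 10)]), rec(freq=[(0, 10)]), rec(freq=[(5, 15)])], TEXT
        )
        assert g.frequency_spans == [Span(0, 10, TEXT[0:10])]

    def test_single_annotator_span_dropped_and_flagged(self):
        g = merge_annotations([rec(freq=[(0, 10)]), rec(), rec()], TEXT)
        assert g.frequency_spans == []
        assert "frequency_empty_merge" in g.adjudication_flags

    def test_annotator_permutation_invariance(self):
        records = [
            rec("seizure_free", freq=[(0, 10)]),
            rec("having_seizures", freq=[(5, 15)]),
            rec("seizure_free", freq=[(0, 12)], last=[(21, 31)]),
        ]
        merges = [merge_annotations(list(p), TEXT) for p in permutations(records)]
        assert all(m == merges[0] for m in merges)

    def test_mismatched_notes_rejected(self):
        with pytest.raises(ValueError):
            merge_annotations([rec(), rec(), rec(note_id="other")], TEXT)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            merge_annotations([rec(), rec()], TEXT)


class TestCohensKappa:
    def test_perfect_agreement(self):
        a = ["seizure_free", "having_seizures", "seizure_free", "unclassifiable"]
        assert cohens_kappa(a, list(a)) == 1.0

    def test_balanced_complete_disagreement(self):
        a = ["F", "F", "S", "S"]
        b = ["S", "S", "F", "F"]
        assert cohens_kappa(a, b) == pytest.approx(-1.0)

    def test_constant_identical_sequences(self):
        assert cohens_kappa(["x"] * 5, ["x"] * 5) == 1.0

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.choice(list("abc"), 60).tolist()
        b = rng.choice(list("abc"), 60).tolist()
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))
        relabel = {"a": "z", "b": "y", "c": "x"}
        assert cohens_kappa([relabel[v] for v in a], [relabel[v] for v in b]) == pytest.approx(
            cohens_kappa(a, b)
        )

    def test_chance_level_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.choice(list("abc"), 10_000).tolist()
        b = rng.choice(list("abc"), 10_000).tolist()
        assert abs(cohens_kappa(a, b)) <= 0.03

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(11)
        a = rng.choice(list("abc"), 200).tolist()
        b = rng.choice(list("abc"), 200).tolist()
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cohens_kappa(["a"], ["a", "b"])
        with pytest.raises(ValueError):
            cohens_kappa([], [])


class TestSpanF1:
    def test_identity(self):
        assert span_f1("3 seizures last month", "3 seizures last month") == (1.0, 1.0, 1.0)

    def test_subset_hand_computed(self):
        p, r, f1 = span_f1("3 seizures in the last 6 months", "seizures in the last 6 months")
        assert p == pytest.approx(1.0)
        assert r == pytest.approx(6 / 7)
        assert f1 == pytest.approx(12 / 13)

    def test_disjoint(self):
        assert span_f1("alpha beta", "gamma delta")[2] == 0.0

    def test_empty_conventions(self):
        assert span_f1("", "") == (1.0, 1.0, 1.0)
        assert span_f1("words here", "") == (0.0, 0.0, 0.0)
        assert span_f1("", "words here") == (0.0, 0.0, 0.0)

    def test_normalization_case_and_punctuation(self):
        assert span_f1("Last seizure: March, 2017.", "last seizure March 2017")[2] == 1.0

    @given(st.text(alphabet="ab c.", max_size=20), st.text(alphabet="ab c.", max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_swap_symmetry(self, g, p):
        pg, rg, fg = span_f1(g, p)
        pp, rp, fp = span_f1(p, g)
        assert pg == pytest.approx(rp)
        assert rg == pytest.approx(pp)
        assert fg == pytest.approx(fp)


def sp(text, start=0):
    return Span(start, start + len(text), text)


class TestSetF1:
    def test_identity(self):
        s = sp("three seizures weekly")
        assert set_f1([s], [s], "paired") == 1.0
        assert set_f1([s], [s], "overall") == 1.0

    def test_extra_disjoint_prediction(self):
        x = sp("three seizures weekly")
        y = sp("blood pressure stable", start=100)
        assert set_f1([x], [x, y], "paired") == 1.0
        assert set_f1([x], [x, y], "overall") == pytest.approx(0.5)

    def test_both_empty_vacuous_agreement(self):
        assert set_f1([], [], "paired") == 1.0
        assert set_f1([], [], "overall") == 1.0

    def test_one_empty(self):
        s = sp("events monthly")
        assert math.isnan(set_f1([s], [], "paired"))
        assert set_f1([s], [], "overall") == 0.0

    def test_no_overlapping_pair_paired_undefined(self):
        assert math.isnan(set_f1([sp("aaa bbb")], [sp("ccc ddd", 50)], "paired"))

    def test_greedy_prefers_best_match(self):
        g = sp("seizure free since March")
        p_good = sp("free since March", 8)
        p_weak = sp("seizure", 0)
        # best pair (g, p_good) is taken; p_weak left unmatched
        paired = set_f1([g], [p_good, p_weak], "paired")
        assert paired == pytest.approx(span_f1(g.text, p_good.text)[2])


class TestPercentAgreement:
    def make(self, gold_label, pred_label, gold_spans=(), pred_span=None):
        gold = [
            GoldRecord(
                note_id="n1",
                label=gold_label,
                frequency_spans=list(gold_spans),
            )
        ]
        preds = [
            Prediction(note_id="n1", seed=0, label=pred_label, frequency_span=pred_span)
        ]
        return preds, gold

    def test_classification_exact(self):
        preds, gold = self.make("seizure_free", "seizure_free")
        assert percent_agreement(preds, gold, "classification") == 1.0
        preds, gold = self.make("seizure_free", "having_seizures")
        assert percent_agreement(preds, gold, "classification") == 0.0

    def test_extraction_mutual_absence_agrees(self):
        preds, gold = self.make("seizure_free", "seizure_free")
        assert percent_agreement(preds, gold, "frequency") == 1.0

    def test_extraction_best_match_among_gold(self):
        a = sp("two seizures in April", 0)
        b = sp("weekly convulsions lately", 60)
        pred = sp("two seizures in April", 0)
        preds, gold = self.make("seizure_free", "seizure_free", [b, a], pred)
        assert percent_agreement(preds, gold, "frequency") == 1.0
        # invariant to gold span enumeration order
        preds, gold = self.make("seizure_free", "seizure_free", [a, b], pred)
        assert percent_agreement(preds, gold, "frequency") == 1.0

    def test_one_sided_absence_disagrees(self):
        preds, gold = self.make("seizure_free", "seizure_free", [sp("four events")], None)
        assert percent_agreement(preds, gold, "frequency") == 0.0

    def test_missing_prediction_is_error(self):
        _, gold = self.make("seizure_free", "seizure_free")
        with pytest.raises(KeyError):
            percent_agreement({}, gold, "classification")


@st.composite
def span_sets(draw):
    """Random span-set pairs over a shared vocabulary, so overlaps occur."""
    vocab = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
    def one_set():
        n = draw(st.integers(0, 3))
        spans = []
        offset = 0
        for _ in range(n):
            k = draw(st.integers(1, 4))
            words = [vocab[draw(st.integers(0, 5))] for _ in range(k)]
            text = " ".join(words)
            spans.append(Span(offset, offset + len(text), text))
            offset += len(text) + 1
        return spans
    return one_set(), one_set()


class TestOverallVsPaired:
    @given(span_sets())
    @settings(max_examples=300, deadline=None)
    def test_overall_never_exceeds_paired(self, sets):
        gold, pred = sets
        paired = set_f1(gold, pred, "paired")
        overall = set_f1(gold, pred, "overall")
        if math.isnan(paired):
            return
        assert overall <= paired + 1e-12
        from noteshift.annotation import _greedy_match

        _, unmatched = _greedy_match(gold, pred)
        if unmatched and (gold or pred):
            assert overall < paired
        elif not unmatched:
            assert overall == pytest.approx(paired)


class TestCorpusF1:
    def test_per_note_and_pooled_agree_on_identical_sets(self, epi_corpus):
        notes, gold = epi_corpus
        same = {g.note_id: g for g in gold}
        for mode in ("paired", "overall"):
            v = corpus_f1(gold, same, "frequency", mode)
            assert v == pytest.approx(1.0)
            v = corpus_f1(gold, same, "frequency", mode, average="pooled")
            assert v == pytest.approx(1.0)
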