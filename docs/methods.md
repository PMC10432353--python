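# Methods

`noteshift` audits how a clinical text-extraction/classification system
degrades when it is applied outside the context it was trained in — other
author specialties, other institutions — and attributes the degradation to
measurable distance between each test note and the training corpus.  This
note documents the models, the estimators, the synthetic-data machinery, and
the numerical conventions, in that order.

## The audited system and its outputs

The audited system reads the epilepsy-history passage of an outpatient
progress note and produces three outputs per note: a trinary seizure-freedom
classification (`seizure_free`, `having_seizures`, `unclassifiable`), an
extracted seizure-frequency text span, and an extracted date-of-last-seizure
text span (either extraction may be an explicit no-answer).  The system
itself is behind a predictor interface: predictions may be ingested from a
JSONL file produced by any real pipeline, or simulated (below).  Replicated
inference is represented as `n_prediction_seeds` independent prediction sets
(default 5), and reports are emitted per seed and seed-averaged.

## Passage isolation

Models see at most `char_limit` characters (default 1506, the input budget
of BERT-class encoders after tokenisation overhead).  Two dialects of
passage location are supported:

* **penn** — the passage starts immediately after the first line-anchored
  `History of Present Illness` or `Interval History` header
  (case-insensitive, optional trailing colon).  When both headers occur the
  earlier one wins and the passage runs on through the later section up to
  the character limit, which maximises captured history under the
  "and/or" reading of the two sections.
* **michigan** — notes lack reliable headers; the passage starts at the
  first character of the first sentence containing one of the trigger
  phrases `the patient was last seen`, `interval history`,
  `interval events`, `hpi`, `history of present illness` (case-insensitive,
  interior whitespace runs collapsed, phrases tried in listed order).

If neither mechanism fires, the first `char_limit` characters are used.
Truncation is by raw character count with no word-boundary snapping, so the
bound is exact and testable.  Dialect rules are plain JSON documents, so a
new institution is configuration, not code.

Sentence segmentation (used for Michigan passage starts and the
kernel/context split) is rule-based: a sentence ends at terminal
punctuation followed by whitespace and an uppercase letter or digit, with a
fixed clinical abbreviation stoplist (`Dr.`, `Mr.`, `Mrs.`, `q.d.`,
`b.i.d.`, `vs.`, `approx.`).  The splitter is deterministic and offsets are
exact slices, which the tests rely on.

## Gold standards and agreement

Triplicate annotations are merged by majority vote.  Labels need two of
three annotators; a three-way split is flagged for manual adjudication and
recorded as `unclassifiable` in the meantime (adjudication is flagged,
never auto-resolved).  Spans are merged at the character level: a character
enters the merged set iff at least two annotators covered it, and maximal
covered runs become merged spans.  Character-level voting is one of several
defensible merge rules; it is declared here because it is order-invariant,
deterministic, and reduces to the identity when annotators agree.

Agreement metrics:

* **Cohen's κ** for labels: κ = (p_o − p_e)/(1 − p_e) with chance agreement
  from the two raters' marginal frequencies; both-raters-constant-and-equal
  returns 1.
* **Token-overlap F1** between two span texts after lowercasing,
  punctuation stripping and whitespace tokenisation (the
  reading-comprehension convention; the multiset of shared tokens defines
  precision and recall).  Two empty texts score 1, one empty text scores 0.
* **Paired vs overall set F1** between two span sets: spans are greedily
  matched by descending pairwise F1 (zero-token-overlap pairs never match;
  ties break on earliest gold start).  Paired F1 averages matched pairs
  only and is undefined (NaN, skipped with a flag) when spans exist but no
  pair can be formed.  Overall F1 additionally scores every unmatched span
  as 0.  Hence overall ≤ paired, strictly when any unmatched span exists —
  the mechanism by which one-sided annotations depress overall agreement.
  Two empty sets agree vacuously (1.0): mutual recognition of absence is
  agreement.
* **Percent agreement**, the headline cross-task metric: label equality for
  classification; for extraction, the best-matched gold span's token F1
  must reach `match_threshold` (default 0.5, inclusive), with mutual
  absence counting as agreement.  Corpus-level F1 averages per note by
  default; a pooled option exists because the two conventions differ when
  span counts vary across notes.

## Kernel / surrounding context and similarity

The *kernel* of a passage is the set of sentences overlapping any gold span
(the frequency and last-seizure spans, plus the classification evidence
span); everything else is the *surrounding context*.  Each side is the
concatenation of its sentences in order.  Per test note and side, two
similarities against every training note are computed and averaged:

* **Levenshtein similarity** 1 − d(a,b)/max(|a|,|b|) with d the
  character-level edit distance on case-folded text — a syntactic,
  "how differently written" measure.  Distances are computed with the
  bit-parallel `edlib` aligner with a plain dynamic-programming fallback.
* **Cosine similarity** of text embeddings — a semantic measure.  The
  built-in provider is a deterministic hashed bag-of-words term-frequency
  embedding (dimension 512, BLAKE2-hashed buckets under a fixed seed,
  L2-normalised), chosen so the whole pipeline is reproducible offline with
  no model download.  It captures lexical-topical similarity, not true
  sentence semantics; any deterministic text-to-vector object (e.g. a
  sentence-transformer wrapper) satisfies the same provider contract and
  can be substituted for production use.

Kernel/context similarity is computed once per note pair on the
concatenated sentence blocks, not averaged over sentence pairs.  Notes with
an empty side are excluded from that side's means and distributions and
counted in the report.  The *reference distribution* holds all pairwise
similarities among training notes — unordered pairs, self-pairs excluded
(they would inject an atom at 1.0 that no test-vs-training comparison can
attain).

## Shift diagnostics

Per prediction set, each note is labelled correct/incorrect
(classification: label equality; extraction: best token F1 ≥ 0.50,
inclusive, mutual no-answer a vacuous success).  For each similarity
measure a two-sided Mann-Whitney U test compares correct vs incorrect
strata.  The implementation uses midranks for ties and selects exact
enumeration when n_x·n_y ≤ 400 with a tie-free pooled sample, else the
normal approximation with tie-corrected variance and continuity correction;
completely tied samples return (n_x·n_y/2, p = 1).  No multiple-testing
adjustment is applied across the four measures — raw p-values are reported
per measure, with both α = .05 and a Bonferroni-style α = .0167 carried in
the config for the caller's use.

Distribution-level comparisons of a test set against the training reference
are reported as Q-Q tables (linear-interpolation quantiles at the 99
percentiles, with both medians), deliberately without p-values: with tens
of thousands of pairwise values any test rejects and the p-value carries no
information.

## The synthetic corpus generator

Notes are assembled from template sentence banks over three topics
(epilepsy history, other neurology, general medicine) with slot-filled
numbers, dates, and drug names.  Kernel sentences are generated as
(prefix, core, suffix) triples and the core's exact character span is
recorded as latent truth, so the kernel/context split is well-defined by
construction.  Per-specialty profiles set the class mix, span prevalences
and topic mix; the shipped defaults are the published corpus statistics:

| profile | seizure-free / having / unclassifiable | frequency span | last-seizure span |
|---|---|---|---|
| epileptologist | .30 / .62 / .08 | .36 | .50 |
| neurologist | .33 / .47 / .20 | .14 | .48 |
| non_neurologist | .30 / .35 / .35 | .07 | .36 |
| michigan_epileptologist | .23 / .63 / .14 | .33 | .51 |

Topic mixes (.80/.15/.05 for epileptologists down to .15/.20/.65 for
non-neurologists) and the 6–11-sentence context range are the package's own
choices for plausible note length and topical drift; both are
configurable.  Penn-dialect notes always place at least one non-history
section before the history header, so passage isolation is exercised
non-trivially; Michigan-dialect notes use the keyword-phrase style with a
10% keyword-free fraction to exercise the fallback.  Unclassifiable notes
carry no outcome-evidence span, so empty-kernel handling is exercised at
its natural prevalence.

**Annotator noise.**  Each of three annotators independently flips the
label to a uniformly chosen other label with `p_label_flip`, drops each
span with `p_span_miss`, and jitters surviving boundaries by a uniform
integer in ±`boundary_jitter_max` (clipped, spans kept non-degenerate).
Defaults (0.20 / 0.15 / 3 characters) were calibrated once so that
merged-vs-truth κ lands near 0.8, the scale reported for real triplicate
annotation of such notes; this is a plausibility target, not a claim of
equivalence to any real annotator pool.  Under this simple independent
model, pairwise inter-annotator κ is necessarily lower (≈0.45) than
merged-vs-truth κ — real annotators are both better and correlated.

**Simulated predictor.**  Correctness of each output is Bernoulli with
logit = base_logit + β_kernel·kernel_score + β_context·context_score, where
each side's score is the mean of its available (Levenshtein, cosine) mean
similarities and a fully missing side contributes 0.  Correct
classifications emit the true label, incorrect ones a uniform other label;
correct extractions emit the first gold span (or no-answer when none
exists), incorrect ones a decoy context sentence or a spurious no-answer.
This is exactly the mechanism — "the system does better on notes more
similar to its training data" — that the stratified diagnostics exist to
detect, which makes power and type-I behaviour of the whole pipeline
testable end to end.  A convenience (`centered_effect`) re-centres
base_logit so the average note hits a chosen marginal correctness rate
(default 0.75 in the audit config).

What the generator does *not* emulate: clinical language variety,
copy-forwarded text, correlated annotator errors, multi-semiology notes, or
institution-specific formatting beyond the two dialects.  Green tests
therefore certify the *estimators and their statistical behaviour under the
assumed mechanism*, not performance claims about any real note corpus.

## Problem sizes and test design

The statistical test-bench uses one fixed synthetic study of 150 training
and 100 test notes, sizes at which the similarity profiling (two alignments
and two embeddings per note pair) completes in seconds while Mann-Whitney
strata of ~50 notes are large enough for the normal-approximation regime.
Type-I error (nominal 5% under zero slopes) is estimated by redrawing only
the simulated predictions over 1000 replicates on that fixed corpus:
under the null, correctness is independent Bernoulli, so the conditional
rejection rate given the profiles equals the nominal level, and
regenerating ~40k pairwise alignments per replicate would add cost without
information.  Power is reported for a strong kernel-only effect
(β_kernel = 40 ≈ a four-log-odds swing across two standard deviations of
the observed kernel-score spread, β_context = 0, balanced base rate), where
kernel-measure comparisons reject in ≳80% of replicates while context
measures stay at chance.

## Numerical conventions and degenerate inputs

* All simulation stages are pure functions of their seeds; per-note streams
  are keyed by (seed, note-id digest), so corpora are prefix-stable in n
  and reruns are byte-identical, including the end-to-end audit manifest.
* κ with both raters constant and identical → 1.0.  Mann-Whitney with all
  values tied → (n_x·n_y/2, 1.0).  Paired F1 with no formable pair → NaN,
  skipped and counted.  Empty kernel → NaN similarity means, excluded per
  measure.  Empty span sets on both sides → 1.0.
* Quantiles are linear-interpolation order statistics (numpy default),
  declared because quantile conventions differ across packages.
* Best-match and greedy-matching ties break on earliest gold start offset,
  then prediction start, for determinism.

## Known limitations

* The built-in embedding is lexical; semantic shifts that preserve
  vocabulary are invisible to the cosine measures until a neural provider
  is plugged in.
* The annotator noise model is independent across annotators and notes; it
  cannot reproduce the correlated disagreement structure of real annotation
  campaigns, and its parameters are not estimates of any real annotators.
* Span-level agreement is textual overlap only; differing surface forms of
  the same fact ("two per week" vs "2/week") do not match, by design.
* The stratified comparisons report associations between similarity and
  correctness, not causal attributions.
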