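# Methods

## Data model and encoding

A questionnaire is a codebook of questions, each with an ordered list of
`k ≤ 9` answer labels and an answer-index base (0 for the demographic
questions, 1 for Likert items). The cap `k ≤ 9` is structural: an item is
the string `"<question>-<answer>"` and the decoder takes the single digit
after the final `-` as the answer index, so the encoding round-trips for
every valid pair. Each question contributes exactly `k` distinct items, and
a participant's report maps to at most one item per question. Missing
answers contribute no item — there is no sentinel item, so an unanswered
question simply cannot enter a rule.

## Eligibility screening

Reports are dropped for three reasons, checked in a fixed order so a
report with several flags is counted once and the log is deterministic:
(1) participant outside the US at survey time, (2) non-binary gender (the
comparison is defined for two groups; small strata cannot be mined at
fraction-based thresholds), (3) missing-answer fraction above a ceiling.
The ceiling is a judgment call in the original screening protocol
("no excessive missing answers" without a number); the package exposes it
as `max_missing_fraction` with a conservative default of **0.2** so the
choice is explicit, configurable and testable. The filter is idempotent.

## Frequent-itemset mining

FP-growth: transactions are compressed into a prefix tree over the frequent
items ordered by descending support (ties broken by ascending item code, so
the tree — and therefore all output — is deterministic), and frequent
itemsets are extracted recursively from conditional pattern bases without
candidate generation.

Numerical policy: all supports are exact integer counts; the threshold
comparison is `count ≥ ceil(minsup·|T| − 1e-9)`, making `support ≥ minsup`
inclusive at exact thresholds and immune to float edges such as
`0.3 × 10 = 2.9999…`. Reported support is the count divided by `|T|`,
evaluated once.

Itemset length is capped at **4** by default in the pipeline (antecedent
plus consequent sizes of interest are small, and the cap bounds the
combinatorial blowup on dense Likert baskets where every transaction holds
one item per question); `max_len=None` removes the cap.

A brute-force enumerator with the same contract (`brute_force_frequent`,
guarded to ≤ 20 distinct items) is part of the package as the independent
correctness oracle; the test suite checks set-equality of miner and oracle
on hundreds of randomized instances. The single-prefix-path shortcut is
not implemented: correctness is defined by the oracle, not by an
optimization.

## Rule generation and filtering

Every frequent itemset `Z` with `|Z| ≥ 2` is split into bipartitions
`X ⊎ Y`; by default only single-item consequents are enumerated
(`single_consequent=False` enables arbitrary bipartitions). A rule is kept
iff `confidence ≥ minconf` and `lift > minlift`. The lift comparison is
**strict** and the support/confidence comparisons **inclusive** — both
conventions are centralized in one place. Defaults are the study
thresholds: 0.20 / 0.70 / 1.2. Metrics are computed from the integer
counts of `Z`, `X` and `Y` (all present in a complete frequent collection
by anti-monotonicity) at the last step. Output is sorted by descending
lift, then descending confidence, then canonical rule text; canonical
item ordering prevents duplicate logical rules.

## Group comparison

The cohort is stratified by the answer to a group-defining question
(default: the gender question), which must induce exactly two non-empty
groups after screening. Rules are mined per (group, category) with baskets
restricted to that category's questions — the comparison counts are
per-category by construction and cross-category rules are out of scope for
the headline table (an exploratory whole-survey entry point exists). The
group-defining item itself is excluded from in-group baskets by default:
within a stratum its support is 1.0 and it is uninformative (a flag
restores it for whole-cohort mining).

Both groups are mined at the same absolute thresholds even under strong
size imbalance (41 vs 281 by default). At `n = 41`, `minsup = 0.2` means
9 transactions; small-group supports are coarse fractions and counts react
discretely to single participants. The package applies no per-group
adjustment — matching the comparison being reproduced — and surfaces the
imbalance in the report instead.

Per category: `diff = M − F` and `ratio = max(M, F)/min(M, F)`. When
either count is zero the ratio is reported as *undefined* (not infinity):
max/min is simply not defined there, and both raw counts remain visible.
Display output rounds ratios to 2 decimals; machine output keeps full
precision. Rows are ordered by descending ratio (undefined last). Swapping
group labels negates every diff and leaves every ratio unchanged.

## Synthetic cohorts

No generative model of the real survey is available, so the generator
defines its own, documented one and claims internal consistency only:

- **Mixture with reserved antecedents.** Per participant, each planted
  rule applicable to their group activates with probability
  `antecedent_support`; if active, the antecedent answers are forced and
  the consequent answer is set with probability `confidence`, otherwise
  redrawn from the baseline *excluding* the consequent answer. Baseline
  draws for antecedent questions exclude the planted antecedent answers
  altogether, so the antecedent occurs exactly when the rule activates.
  Consequently, in expectation, `s(X) = antecedent_support`,
  `s(X∪Y) = antecedent_support·confidence` and `c(X→Y) = confidence` in
  closed form — directly assertable within binomial standard errors.
- **Baselines.** Default per-question answer distributions are mildly
  peaked (5-point: 0.10/0.20/0.30/0.25/0.15; 7-point analogous) rather
  than uniform, as real Likert marginals are; they are overridable per
  question and per group.
- **Shape.** The default instrument mirrors the study: 13 communication,
  10 psychological-distress, 8 susceptibility/severity, 8
  benefits/barriers (5-point) and five 7-point preventive-behaviour
  questions, plus student-status and gender demographics; default group
  sizes 41/281 (scale-up helper for statistically tighter tests). Answers
  are masked missing independently at `missing_rate` (default 0.02,
  consistent with a screened cohort); the group question is never masked.
- **Randomness.** One integer seed drives independent named streams keyed
  `(seed, group, stream-id)`, with per-question streams drawing all of a
  group's participants at once; adding questions or rules never perturbs
  existing questions' draws, and identical configs give byte-identical
  fixture files.

What passing tests on these cohorts do **not** show: robustness to
psychometrically realistic inter-item correlation (factor structure),
answer styles (acquiescence, straight-lining), or non-random missingness.
The generator's independence between non-planted questions is exactly what
makes the null case clean (lift concentrates near 1, so no spurious rules
at `lift > 1.2` for n ≥ 2000) — and exactly what real data violates.

## Degenerate inputs and edge policies

- `support(∅) = 1` by convention; support over an empty transaction list is
  an error (undefined denominator).
- Confidence/lift with a zero-support antecedent or marginal raise rather
  than return NaN.
- An all-infrequent input yields a bare FP-tree root and an empty result;
  a report with no in-scope answers yields an (logged) empty transaction
  that still counts in `|T|`.
- Thresholds of 0.99+ produce empty rule files, all-zero comparison rows
  and undefined ratios — a normal run, not an error.

## Problem sizes used in the checks

The oracle-equivalence suite uses randomized instances of up to 12 items
and 200 transactions (hundreds of instances); recovery checks use cohorts
of 2,000 per group over five seeds with tolerances of three binomial
standard errors; the recovery demonstration at `n = 5,000` asserts ±0.02 on
support and ±0.03 on confidence. These sizes make the binomial bounds
meaningful while keeping the whole suite interactive.
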