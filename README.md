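# surveyrules

Association-rule mining of Likert-scale survey responses, with
group-stratified comparison of the mined rule inventories.

## The problem

Health-behaviour surveys (here: university students' psychological,
cognitive and behavioural responses during the COVID-19 pandemic) produce
one row of ordered-categorical answers per participant. Treating each
question-answer pair as a market-basket *item* — the answer "Disagree" (2)
to question 37 becomes the item `"37-2"` — turns every survey report into a
*transaction*, and classical frequent-pattern mining applies directly:

- **support** `s(Z)` — fraction of transactions containing every item of `Z`;
- **confidence** `c(X→Y) = s(X∪Y) / s(X)` — how often the consequent holds
  when the antecedent does;
- **lift** `c(X→Y) / s(Y) = s(X,Y) / (s(X)·s(Y))` — 1 under independence,
  \>1 for positive association. Lift matters because a rule can carry high
  support and confidence purely by riding a popular consequent: with a 90%
  base rate of "creative" students, the 75%-confidence rule
  {negative feedback} → {creative} has lift 0.15/(0.20·0.90) = 0.83 and is
  in fact a *negative* association.

Frequent itemsets are mined with an **FP-growth** implementation (prefix
tree + recursive conditional pattern bases, no candidate generation, exact
integer counting), rules are filtered at `support ≥ 0.20`,
`confidence ≥ 0.70`, `lift > 1.2`, and the two participant groups (e.g.
male/female) are mined separately per questionnaire category. Each
category is then summarised by its two rule counts `M`, `F` and

```
diff = M − F        ratio = max(M, F) / min(M, F)
```

where a larger rule count is read as more consistent answering in that
category and a large ratio flags a between-group difference.

Because survey data of this kind is typically proprietary, the package
ships a synthetic cohort generator that mimics the study design (two groups
with a 1:7 imbalance, 41 + 281 = 322 participants by default, 5- and
7-point Likert questions in five categories, small missing-answer rate) and
can *plant* antecedent → consequent dependencies with known support and
confidence, so the whole pipeline is testable against ground truth.

## Worked example

```python
from surveyrules import (RuleThresholds, confidence, generate_rules,
                         lift, mine_frequent, support)

tx = ([frozenset({"NegFB", "Creative"})] * 150
      + [frozenset({"NegFB", "NotCreative"})] * 50
      + [frozenset({"PosFB", "Creative"})] * 750
      + [frozenset({"PosFB", "NotCreative"})] * 50)

support({"NegFB", "Creative"}, tx)        # 0.15
confidence({"NegFB"}, {"Creative"}, tx)   # 0.75
support({"Creative"}, tx)                 # 0.9
lift({"NegFB"}, {"Creative"}, tx)         # 0.8333333333333334

frequent = mine_frequent(tx, minsup=0.10)
rules = generate_rules(frequent, RuleThresholds(0.10, 0.70, 1.2),
                       n_transactions=len(tx))
[r.key for r in rules]                    # [] — lift 0.83 fails lift > 1.2
```

The rule is "strong" by support and confidence yet excluded by the lift
filter — the behaviour the thresholds are designed to enforce. See
`examples/` for one short script per capability (encoding, mining and
filtering, synthetic cohorts, group comparison, the file pipeline); each
prints its numbers with a note on what they mean.

## Command line

```sh
surveyrules synth --outdir fixture --seed 5          # synthetic fixture
surveyrules run --responses fixture/responses.csv \
    --codebook fixture/codebook.csv --outdir out     # full analysis
surveyrules mine --baskets baskets.tsv --out freq.csv
surveyrules compare --rules-a out/rules_male_*.csv --rules-b out/rules_female_*.csv
```

`run` writes per-(group, category) rule CSVs, the comparison table
(`comparison.csv` / full-precision `comparison.json`), the exclusion log
and a run manifest with input checksums; the analytic path is fully
deterministic.

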