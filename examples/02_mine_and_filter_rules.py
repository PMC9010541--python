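"""Why support and confidence are not enough: the lift filter.

A cohort of 1,000 students cross-classified by mentor feedback type and
creativity (150 negative-feedback creatives, 50 negative-feedback
non-creatives, 750 positive-feedback creatives, 50 positive-feedback
non-creatives).  The rule {NegFB} -> {Creative} looks strong — 15% support,
75% confidence — but 90% of the whole cohort is creative, so negative
feedback is actually *negatively* associated with creativity.  Lift
0.15 / (0.20 * 0.90) = 0.83 < 1 exposes this, and the lift > 1.2 filter
discards the rule.
"""

from surveyrules import (
    RuleThresholds,
    confidence,
    generate_rules,
    lift,
    mine_frequent,
    support,
)

transactions = (
    [frozenset({"NegFB", "Creative"})] * 150
    + [frozenset({"NegFB", "NotCreative"})] * 50
    + [frozenset({"PosFB", "Creative"})] * 750
    + [frozenset({"PosFB", "NotCreative"})] * 50
)

print(f"support({{NegFB, Creative}})     = {support({'NegFB', 'Creative'}, transactions):.2f}")
print(f"confidence(NegFB -> Creative)  = {confidence({'NegFB'}, {'Creative'}, transactions):.2f}")
print(f"support({{Creative}})            = {support({'Creative'}, transactions):.2f}")
print(f"lift(NegFB -> Creative)        = {lift({'NegFB'}, {'Creative'}, transactions):.4f}")

frequent = mine_frequent(transactions, minsup=0.10)
print(f"\nfrequent itemsets at minsup 0.10: {len(frequent)}")

for minlift, label in [(1e-9, "no lift filter"), (1.2, "lift > 1.2")]:
    rules = generate_rules(
        frequent, RuleThresholds(0.10, 0.70, minlift), n_transactions=len(transactions)
    )
    print(f"rules with {label}:")
    for rule in rules:
        print(f"  {rule}")
# With the lift > 1.2 filter no rule survives: the NegFB rule is negatively
# associated (lift 0.83) and even PosFB <-> Creative barely exceeds
# independence (lift 1.04) — high confidence alone said nothing.
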