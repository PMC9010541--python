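"""Association-rule generation and interestingness filtering.

A rule X -> Y (X, Y disjoint non-empty itemsets) is scored by

* support  s(X u Y): fraction of transactions containing both sides,
* confidence  c = s(X u Y) / s(X): conditional frequency of Y given X,
* lift  c / s(Y) = s(X,Y) / (s(X) s(Y)): 1 under independence, > 1 for a
  positive association, < 1 for a negative one.

Rules are generated from every bipartition of each frequent itemset of size
>= 2 and retained when confidence >= minconf and lift > minlift (the lift
comparison is strict; support/confidence are inclusive).  A
high-support/high-confidence rule can still ride on a popular consequent —
e.g. 75% confidence against a 90% base rate — which is exactly the
negative-association case the lift filter removes.

All metrics are evaluated from integer co-occurrence counts at the last
step, so equal counts give bitwise-equal metrics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .codebook import Codebook, decode_item
from .encoding import Transaction
from .fpgrowth import FrequentItemset, TransactionLike, support_count


@dataclass(frozen=True)
class RuleThresholds:
    """Mining thresholds: minimum support/confidence, strict lift floor."""

    minsup: float = 0.20
    minconf: float = 0.70
    minlift: float = 1.20

    def __post_init__(self) -> None:
        if not 0 < self.minsup <= 1:
            raise ValueError("minsup must be in (0, 1]")
        if not 0 < self.minconf <= 1:
            raise ValueError("minconf must be in (0, 1]")
        if self.minlift < 0:
            raise ValueError("minlift must be non-negative")


@dataclass(frozen=True)
class AssociationRule:
    """A scored rule antecedent -> consequent."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    count: int  # transactions containing antecedent u consequent
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def key(self) -> str:
        """Canonical text form, e.g. ``"2-0 37-2 -> 38-2"``."""
        return "{} -> {}".format(
            " ".join(sorted(self.antecedent)), " ".join(sorted(self.consequent))
        )

    def __str__(self) -> str:
        return (
            f"{{{', '.join(sorted(self.antecedent))}}} -> "
            f"{{{', '.join(sorted(self.consequent))}}} "
            f"(s={self.support:.2f}, c={self.confidence:.2f}, l={self.lift:.2f})"
        )


# ---------------------------------------------------------------------------
# Direct metric computation (scan-based; used for spot checks and small data)


def confidence(
    antecedent: Iterable[str],
    consequent: Iterable[str],
    transactions: Sequence[TransactionLike],
) -> float:
    """c(X -> Y) = s(X u Y) / s(X).  Undefined (raises) when s(X) = 0."""
    x = frozenset(antecedent)
    y = frozenset(consequent)
    if x & y:
        raise ValueError("antecedent and consequent must be disjoint")
    nx = support_count(x, transactions)
    if nx == 0:
        raise ZeroDivisionError("confidence undefined: antecedent never occurs")
    return support_count(x | y, transactions) / nx


def lift(
    antecedent: Iterable[str],
    consequent: Iterable[str],
    transactions: Sequence[TransactionLike],
) -> float:
    """lift(X -> Y) = s(X,Y) / (s(X) s(Y)); symmetric in X and Y."""
    x = frozenset(antecedent)
    y = frozenset(consequent)
    n = len(transactions)
    nx = support_count(x, transactions)
    ny = support_count(y, transactions)
    if nx == 0 or ny == 0:
        raise ZeroDivisionError("lift undefined: a marginal support is zero")
    nxy = support_count(x | y, transactions)
    return (nxy * n) / (nx * ny)


# ---------------------------------------------------------------------------
# Rule generation from mined frequent itemsets


def generate_rules(
    frequent: Sequence[FrequentItemset],
    thresholds: RuleThresholds = RuleThresholds(),
    single_consequent: bool = True,
    n_transactions: Optional[int] = None,
) -> list[AssociationRule]:
    """Emit the filtered rules from a complete frequent-itemset collection.

    Every frequent itemset Z with |Z| >= 2 is split into each bipartition
    X u Y; the rule X -> Y is kept iff confidence >= minconf and
    lift > minlift (support >= minsup is inherited from mining).  With
    ``single_consequent`` (default) only |Y| = 1 bipartitions are
    enumerated, matching the usual survey-rule reporting style.

    The supports of X, Y and Z are looked up in ``frequent`` — complete by
    anti-monotonicity when mining ran at ``thresholds.minsup``.  Output is
    sorted by descending lift, then descending confidence, then rule text.
    """
    counts: dict[frozenset, int] = {f.items: f.count for f in frequent}
    if n_transactions is None:
        n_transactions = _infer_n(frequent)
    rules: list[AssociationRule] = []
    seen: set[tuple[frozenset, frozenset]] = set()
    for itemset in frequent:
        z = itemset.items
        if len(z) < 2:
            continue
        for consequent_items in _consequents(z, single_consequent):
            y = frozenset(consequent_items)
            x = z - y
            if (x, y) in seen:
                continue
            seen.add((x, y))
            try:
                nx, ny = counts[x], counts[y]
            except KeyError as missing:
                raise ValueError(
                    f"frequent-itemset collection is incomplete: missing "
                    f"{set(missing.args[0])}"
                ) from None
            conf = itemset.count / nx
            if conf < thresholds.minconf:
                continue
            rule_lift = (itemset.count * n_transactions) / (nx * ny)
            if rule_lift <= thresholds.minlift:
                continue
            rules.append(
                AssociationRule(
                    antecedent=x,
                    consequent=y,
                    count=itemset.count,
                    support=itemset.support,
                    confidence=conf,
                    lift=rule_lift,
                )
            )
    rules.sort(key=lambda r: (-r.lift, -r.confidence, r.key))
    return rules


def _consequents(z: frozenset, single: bool):
    items = sorted(z)
    if single:
        yield from ((i,) for i in items)
    else:
        for size in range(1, len(items)):
            yield from itertools.combinations(items, size)


def _infer_n(frequent: Sequence[FrequentItemset]) -> int:
    for f in frequent:
        if f.support > 0:
            return round(f.count / f.support)
    raise ValueError("cannot infer transaction count; pass n_transactions")


def verify_rule(
    rule: AssociationRule,
    transactions: Sequence[TransactionLike],
    thresholds: RuleThresholds,
) -> bool:
    """Re-check a rule's metrics and thresholds by direct transaction scan."""
    n = len(transactions)
    nxy = support_count(rule.antecedent | rule.consequent, transactions)
    s = nxy / n
    c = confidence(rule.antecedent, rule.consequent, transactions)
    l = lift(rule.antecedent, rule.consequent, transactions)
    return (
        abs(s - rule.support) < 1e-12
        and abs(c - rule.confidence) < 1e-12
        and abs(l - rule.lift) < 1e-12
        and s >= thresholds.minsup - 1e-12
        and c >= thresholds.minconf - 1e-12
        and l > thresholds.minlift
    )


# ---------------------------------------------------------------------------
# Human-readable rendering


def rule_to_text(rule: AssociationRule, codebook: Codebook) -> str:
    """Expand a rule to question wording plus answer labels.

    Mirrors the reporting style ``"2-0": I am a male ...`` with the metrics
    on the first line, two decimals.
    """
    lines = [
        f"{rule.key}  "
        f"(support = {rule.support:.2f}, confidence = {rule.confidence:.2f}, "
        f"lift = {rule.lift:.2f})"
    ]
    for side, name in ((rule.antecedent, "if"), (rule.consequent, "then")):
        for item in sorted(side):
            number, answer = decode_item(item)
            question = codebook[number]  # CodebookError names the unknown question
            lines.append(
                f'  [{name}] "{item}": {question.text} '
                f"Answer: {question.label_for(answer)}"
            )
    return "\n".join(lines)
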