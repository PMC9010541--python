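"""Group-stratified mining and rule-count comparison.

The cohort is split into two groups by the answer to a group-defining
question (here gender), rules are mined independently per group and per
questionnaire category with the same thresholds, and each category's rule
counts are compared via

* diff  = M - F  (first group minus second group), and
* ratio = max(M, F) / min(M, F), undefined when either count is zero.

A larger rule count is read as more behaviourally consistent answering in
that category; a large ratio flags a category where the two groups differ.
Both groups are mined at identical absolute thresholds even when group
sizes are imbalanced — small-group supports are coarser fractions, a caveat
the report surfaces rather than adjusts away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .codebook import ANALYSIS_CATEGORIES, Category, Codebook, SurveyReport
from .encoding import build_transactions
from .fpgrowth import DEFAULT_MAX_LEN, mine_frequent
from .rules import AssociationRule, RuleThresholds, generate_rules

logger = logging.getLogger(__name__)

RuleMap = dict[tuple[str, Category], list[AssociationRule]]


class GroupingError(ValueError):
    """The group question does not induce exactly two non-empty groups."""


@dataclass(frozen=True)
class GroupComparisonRow:
    """Per-category rule counts for two groups, with diff and ratio."""

    category: Category
    count_a: int
    count_b: int

    @property
    def diff(self) -> int:
        return self.count_a - self.count_b

    @property
    def ratio(self) -> Optional[float]:
        lo = min(self.count_a, self.count_b)
        if lo == 0:
            return None  # max/min undefined on a zero cell
        return max(self.count_a, self.count_b) / lo


def group_label_of(
    report: SurveyReport, codebook: Codebook, group_question: int
) -> Optional[str]:
    """Group label from the report's answer to the group question.

    The label is the lower-cased answer label (e.g. ``"male"``).  Returns
    None when the question is unanswered.
    """
    answer = report.answers.get(group_question)
    if answer is None:
        return None
    return codebook[group_question].label_for(answer).lower()


def stratify_and_mine(
    reports: Sequence[SurveyReport],
    codebook: Codebook,
    group_question: int,
    thresholds: RuleThresholds = RuleThresholds(),
    categories: Optional[Sequence[Category]] = None,
    include_group_item: bool = False,
    max_len: Optional[int] = DEFAULT_MAX_LEN,
    single_consequent: bool = True,
) -> RuleMap:
    """Mine rules per (group, category) with one shared threshold set.

    For each of the two groups and each category, baskets are restricted to
    that category's questions and the full mine -> generate -> filter
    pipeline runs on the group's transactions.  Cross-category rules are
    deliberately out of reach here; use :func:`mine_whole_survey` to explore
    unrestricted baskets.
    """
    if categories is None:
        categories = [c for c in ANALYSIS_CATEGORIES if codebook.questions_in(c)]

    groups: dict[str, list[SurveyReport]] = {}
    for report in reports:
        label = group_label_of(report, codebook, group_question)
        if label is None:
            logger.warning(
                "participant %s: group question %d unanswered, skipped",
                report.participant_id,
                group_question,
            )
            continue
        groups.setdefault(label, []).append(report)
    if len(groups) != 2:
        raise GroupingError(
            f"group question {group_question} induces {len(groups)} group(s) "
            f"({sorted(groups)}); exactly two required"
        )
    for label, members in groups.items():
        if not members:  # pragma: no cover - unreachable via setdefault
            raise GroupingError(f"group {label!r} has zero reports; cannot mine")

    rule_map: RuleMap = {}
    for label, members in sorted(groups.items()):
        for category in categories:
            scope = [q.number for q in codebook.questions_in(category)]
            transactions = build_transactions(
                members,
                codebook,
                include_questions=scope,
                include_group_item=include_group_item,
                group_question=group_question,
            )
            answered = any(len(t) for t in transactions)
            if not answered:
                logger.warning(
                    "group %s, category %s: no answered questions in scope",
                    label,
                    category.value,
                )
                rule_map[(label, category)] = []
                continue
            frequent = mine_frequent(transactions, thresholds.minsup, max_len=max_len)
            rule_map[(label, category)] = generate_rules(
                frequent,
                thresholds,
                single_consequent=single_consequent,
                n_transactions=len(transactions),
            )
    return rule_map


def mine_whole_survey(
    reports: Sequence[SurveyReport],
    codebook: Codebook,
    group_question: int,
    thresholds: RuleThresholds = RuleThresholds(),
    include_group_item: bool = False,
    max_len: Optional[int] = DEFAULT_MAX_LEN,
    single_consequent: bool = True,
) -> dict[str, list[AssociationRule]]:
    """Exploratory variant: mine unrestricted (cross-category) baskets per group."""
    groups: dict[str, list[SurveyReport]] = {}
    for report in reports:
        label = group_label_of(report, codebook, group_question)
        if label is not None:
            groups.setdefault(label, []).append(report)
    out: dict[str, list[AssociationRule]] = {}
    for label, members in sorted(groups.items()):
        transactions = build_transactions(
            members,
            codebook,
            include_group_item=include_group_item,
            group_question=group_question,
        )
        frequent = mine_frequent(transactions, thresholds.minsup, max_len=max_len)
        out[label] = generate_rules(
            frequent,
            thresholds,
            single_consequent=single_consequent,
            n_transactions=len(transactions),
        )
    return out


def compare_counts(
    rule_map: Mapping[tuple[str, Category], Sequence],
    groups: Optional[tuple[str, str]] = None,
) -> list[GroupComparisonRow]:
    """One comparison row per category, ordered by descending ratio.

    ``groups`` fixes which group plays the first (diff-positive) role; by
    default the two labels found in the map, sorted, with the *second*
    sorted label first (so ("female", "male") maps to male-first, matching
    the usual male-minus-female convention).  Rows with an undefined ratio
    sort last.
    """
    labels = sorted({g for g, _ in rule_map})
    if groups is None:
        if len(labels) != 2:
            raise GroupingError(f"rule map covers {len(labels)} groups; need two")
        groups = (labels[1], labels[0])
    a, b = groups
    categories = []
    for _, category in rule_map:
        if category not in categories:
            categories.append(category)
    rows = []
    for category in categories:
        try:
            count_a = len(rule_map[(a, category)])
            count_b = len(rule_map[(b, category)])
        except KeyError as missing:
            raise GroupingError(f"rule map missing cell {missing.args[0]}") from None
        rows.append(GroupComparisonRow(category=category, count_a=count_a, count_b=count_b))
    rows.sort(key=lambda r: (r.ratio is None, -(r.ratio or 0.0)))
    return rows


def comparison_table(
    rows: Sequence[GroupComparisonRow], groups: tuple[str, str]
) -> pd.DataFrame:
    """Display table: counts, diff, ratio rounded to 2 decimals."""
    return pd.DataFrame(
        {
            "index": range(1, len(rows) + 1),
            "category": [r.category.value for r in rows],
            groups[0]: [r.count_a for r in rows],
            groups[1]: [r.count_b for r in rows],
            "diff": [r.diff for r in rows],
            "ratio": [None if r.ratio is None else round(r.ratio, 2) for r in rows],
        }
    )


def consistency_report(
    rows: Sequence[GroupComparisonRow], groups: tuple[str, str]
) -> str:
    """Name the more-consistent group per category (larger rule count)."""
    if not rows:
        raise ValueError("no comparison rows")
    a, b = groups
    lines = []
    for row in rows:
        if row.count_a == row.count_b:
            verdict = f"tie ({row.count_a} rules each)"
        else:
            winner = a if row.count_a > row.count_b else b
            ratio = "undefined" if row.ratio is None else f"{row.ratio:.2f}"
            verdict = (
                f"more consistent in {winner} "
                f"({a}: {row.count_a}, {b}: {row.count_b}, ratio {ratio})"
            )
        lines.append(f"{row.category.value}: {verdict}")
    return "\n".join(lines)
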