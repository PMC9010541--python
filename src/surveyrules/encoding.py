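"""Turning survey reports into market-basket transactions.

Each retained report becomes one :class:`Transaction` whose items are the
encoded question-answer pairs of its answered questions, e.g. a report with
Q2=0, Q37=2, Q41=4 yields the basket ``{"2-0", "37-2", "41-4"}``.  A missing
answer contributes no item (never a sentinel), so a transaction carries at
most one item per question.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .codebook import Codebook, SurveyReport, encode_item

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Transaction:
    """One participant's basket of question-answer items."""

    participant_id: str
    group_label: str = ""
    items: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.items)


def build_transactions(
    reports: Sequence[SurveyReport],
    codebook: Codebook,
    include_questions: Optional[Iterable[int]] = None,
    include_group_item: bool = False,
    group_question: Optional[int] = None,
) -> list[Transaction]:
    """Encode filtered reports as transactions, one per report.

    Parameters
    ----------
    reports:
        Eligibility-filtered reports.
    include_questions:
        Restrict baskets to these question numbers (default: all codebook
        questions).
    include_group_item:
        Whether the group-defining question's item is kept in the basket.
        When mining a single group this item has support 1.0 and is
        uninformative, so the default drops it; enabling it reproduces
        whole-cohort baskets in which the group item can enter rules.
    group_question:
        The group-defining question number (only consulted when
        ``include_group_item`` is false).
    """
    scope = set(codebook.question_numbers if include_questions is None else include_questions)
    if not include_group_item and group_question is not None:
        scope.discard(group_question)

    transactions: list[Transaction] = []
    for report in reports:
        items = frozenset(
            encode_item(number, answer, codebook)
            for number, answer in report.answers.items()
            if number in scope
        )
        if not items:
            logger.warning(
                "participant %s: no in-scope answers, keeping empty transaction",
                report.participant_id,
            )
        transactions.append(
            Transaction(
                participant_id=report.participant_id,
                group_label=report.group_label,
                items=items,
            )
        )
    return transactions
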