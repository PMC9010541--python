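"""Survey data model: questions, codebook, reports, and question-answer items.

A questionnaire is described by a :class:`Codebook` of :class:`Question`
objects.  Each question has an ordered list of answer labels and an
answer-index base (demographic questions here index answers from 0, Likert
questions from 1).  Every question-answer pair is encoded as a market-basket
*item* of the form ``"<question_number>-<answer_index>"`` — e.g. ``"153-4"``
for answer 4 of question 153 — so a participant's report becomes a
transaction over such items.  Answer arities are capped at 9 so the answer
index is always a single trailing digit and the encoding round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional


class Category(str, Enum):
    """Questionnaire category a question belongs to."""

    DEMOGRAPHICS = "demographics"
    COMMUNICATION = "communication"
    PSYCHOLOGICAL_DISTRESS = "psychological_distress"
    PERCEIVED_SUSCEPTIBILITY_SEVERITY = "perceived_susceptibility_severity"
    PERCEIVED_BENEFITS_BARRIERS = "perceived_benefits_barriers"
    PREVENTIVE_BEHAVIORS = "preventive_behaviors"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The five analysis categories (demographics excluded).
ANALYSIS_CATEGORIES: tuple[Category, ...] = (
    Category.COMMUNICATION,
    Category.PSYCHOLOGICAL_DISTRESS,
    Category.PERCEIVED_SUSCEPTIBILITY_SEVERITY,
    Category.PERCEIVED_BENEFITS_BARRIERS,
    Category.PREVENTIVE_BEHAVIORS,
)


class CodebookError(KeyError):
    """An item or operation references a question absent from the codebook."""


class ValidationError(ValueError):
    """A value violates the survey data model (bad index, arity > 9, ...)."""


class ItemParseError(ValueError):
    """An item code cannot be decoded back to (question, answer)."""


@dataclass(frozen=True)
class Question:
    """One survey question.

    Parameters
    ----------
    number:
        Unique positive question number.
    text:
        Question wording.
    answer_labels:
        Ordered labels of the ``k`` answer choices, ``1 <= k <= 9``.
    answer_index_base:
        Index of the first answer choice, 0 or 1.  Valid answer indices are
        ``base .. base + k - 1``.
    category:
        Questionnaire category.
    """

    number: int
    text: str
    answer_labels: tuple[str, ...]
    answer_index_base: int = 1
    category: Category = Category.DEMOGRAPHICS

    def __post_init__(self) -> None:
        if self.number <= 0:
            raise ValidationError(f"question number must be positive, got {self.number}")
        k = len(self.answer_labels)
        if not 1 <= k <= 9:
            raise ValidationError(
                f"question {self.number}: {k} answer choices; need 1..9 so the "
                "answer index stays a single digit"
            )
        if self.answer_index_base not in (0, 1):
            raise ValidationError(
                f"question {self.number}: answer_index_base must be 0 or 1"
            )
        if self.answer_index_base + k - 1 > 9:
            raise ValidationError(
                f"question {self.number}: highest answer index exceeds 9"
            )

    @property
    def n_answers(self) -> int:
        return len(self.answer_labels)

    @property
    def valid_indices(self) -> range:
        return range(self.answer_index_base, self.answer_index_base + self.n_answers)

    def label_for(self, answer_index: int) -> str:
        if answer_index not in self.valid_indices:
            raise ValidationError(
                f"answer index {answer_index} invalid for question {self.number} "
                f"(valid: {self.valid_indices.start}..{self.valid_indices.stop - 1})"
            )
        return self.answer_labels[answer_index - self.answer_index_base]


class Codebook:
    """Collection of :class:`Question` keyed by question number."""

    def __init__(self, questions: Iterable[Question]):
        self._questions: dict[int, Question] = {}
        for q in questions:
            if q.number in self._questions:
                raise ValidationError(f"duplicate question number {q.number}")
            self._questions[q.number] = q

    def __len__(self) -> int:
        return len(self._questions)

    def __iter__(self) -> Iterator[Question]:
        return iter(sorted(self._questions.values(), key=lambda q: q.number))

    def __contains__(self, number: int) -> bool:
        return number in self._questions

    def __getitem__(self, number: int) -> Question:
        try:
            return self._questions[number]
        except KeyError:
            raise CodebookError(f"unknown question number {number}") from None

    @property
    def question_numbers(self) -> list[int]:
        return sorted(self._questions)

    def questions_in(self, category: Category) -> list[Question]:
        return [q for q in self if q.category == category]

    def categories(self) -> list[Category]:
        """Categories present, in canonical order."""
        present = {q.category for q in self}
        order = [Category.DEMOGRAPHICS, *ANALYSIS_CATEGORIES]
        return [c for c in order if c in present]

    def n_possible_items(self, questions: Optional[Iterable[int]] = None) -> int:
        """Number of distinct items the encoding can produce: sum of arities."""
        numbers = self.question_numbers if questions is None else list(questions)
        return sum(self[n].n_answers for n in numbers)


# ---------------------------------------------------------------------------
# Item encoding


def encode_item(question_number: int, answer_index: int, codebook: Codebook) -> str:
    """Encode a question-answer pair as the item ``"<question>-<answer>"``.

    Raises :class:`CodebookError` for an unknown question and
    :class:`ValidationError` for an out-of-range answer index.
    """
    question = codebook[question_number]
    if answer_index not in question.valid_indices:
        raise ValidationError(
            f"answer index {answer_index} invalid for question {question_number} "
            f"(valid: {question.valid_indices.start}..{question.valid_indices.stop - 1})"
        )
    return f"{question_number}-{answer_index}"


def decode_item(item: str) -> tuple[int, int]:
    """Decode an item code back to ``(question_number, answer_index)``.

    The answer index is the single digit after the final ``"-"``.
    """
    head, sep, tail = item.rpartition("-")
    if not sep or len(tail) != 1 or not tail.isdigit() or not head.isdigit():
        raise ItemParseError(f"malformed item code {item!r}")
    return int(head), int(tail)


# ---------------------------------------------------------------------------
# Survey reports


@dataclass
class SurveyReport:
    """One participant's raw survey report.

    ``answers`` maps question number to the given answer index; unanswered
    questions are simply absent.  ``group_label`` carries the participant's
    group (e.g. ``"male"``/``"female"``); the two exclusion flags mirror the
    eligibility screen applied before analysis.
    """

    participant_id: str
    answers: dict[int, int] = field(default_factory=dict)
    group_label: str = ""
    outside_us: bool = False
    nonbinary_gender: bool = False

    def validate(self, codebook: Codebook) -> None:
        """Check every present answer index against the codebook."""
        for number, index in self.answers.items():
            question = codebook[number]
            if index not in question.valid_indices:
                raise ValidationError(
                    f"participant {self.participant_id}: answer {index} invalid "
                    f"for question {number}"
                )

    def missing_fraction(self, codebook: Codebook) -> float:
        """Fraction of codebook questions left unanswered."""
        total = len(codebook)
        if total == 0:
            return 0.0
        answered = sum(1 for n in self.answers if n in codebook)
        return 1.0 - answered / total
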