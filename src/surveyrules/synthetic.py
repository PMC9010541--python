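"""Synthetic survey cohorts with plantable association rules.

The real survey data behind this kind of analysis is typically proprietary,
so every pipeline stage here is exercised on generated cohorts that mimic
the study design: a two-group cohort (default 41 vs 281 participants, the
~1:7 gender imbalance), 5- and 7-point Likert questions across five
questionnaire categories plus two demographic questions, a small
missing-answer rate, and — the part that makes recovery testable —
*planted* antecedent -> consequent dependencies.

Generative model (mixture): for each participant, each planted rule that
applies to their group activates independently with probability
``antecedent_support``.  When active, the antecedent answers are forced;
the consequent answer is then set with probability ``confidence`` and
otherwise redrawn from the baseline distribution *excluding* that answer.
All remaining answers come from per-question baseline distributions
(optionally group-specific), with the planted antecedent answers reserved —
the baseline never emits them — so the antecedent occurs exactly when the
rule activates.  Hence, in expectation, the planted rule's support is
``antecedent_support * confidence`` in closed form and its confidence is
``confidence`` exactly.

Randomness is a hierarchy of independent streams keyed by
``(seed, group, stream-id)`` where per-question streams draw all
participants of a group at once; adding questions or rules to a config
therefore never perturbs the draws of existing questions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .codebook import (
    ANALYSIS_CATEGORIES,
    Category,
    Codebook,
    Question,
    SurveyReport,
    ValidationError,
    encode_item,
)

logger = logging.getLogger(__name__)

LIKERT5 = ("Strongly Disagree", "Disagree", "Neutral", "Agree", "Strongly Agree")
LIKERT7 = (
    "Strongly Disagree",
    "Disagree",
    "Slightly Disagree",
    "Neutral",
    "Slightly Agree",
    "Agree",
    "Strongly Agree",
)

#: Mildly peaked default answer distributions; real Likert marginals are
#: rarely uniform.
BASELINE_5PT = (0.10, 0.20, 0.30, 0.25, 0.15)
BASELINE_7PT = (0.05, 0.10, 0.15, 0.25, 0.20, 0.15, 0.10)

#: Question arities per category mirroring the study instrument:
#: 13 communication items, 10 psychological-distress items, 4+4
#: susceptibility/severity, 4+4 benefits/barriers (all 5-point), and five
#: 7-point preventive-behaviour items.
DEFAULT_QUESTION_COUNTS: dict[Category, tuple[int, ...]] = {
    Category.COMMUNICATION: (5,) * 13,
    Category.PSYCHOLOGICAL_DISTRESS: (5,) * 10,
    Category.PERCEIVED_SUSCEPTIBILITY_SEVERITY: (5,) * 8,
    Category.PERCEIVED_BENEFITS_BARRIERS: (5,) * 8,
    Category.PREVENTIVE_BEHAVIORS: (7,) * 5,
}

GROUP_QUESTION = 2  # gender question number in the generated codebook

# stream-id namespaces (kept disjoint)
_NS_QUESTION = 0
_NS_RULE = 1_000_000
_NS_MISSING = 2_000_000
_NS_REGISTRY = 3_000_000


@dataclass(frozen=True)
class PlantedRule:
    """An antecedent -> consequent dependency to embed in one group.

    ``antecedent_support`` is the activation probability of the forced
    antecedent pattern; the planted rule's expected transaction support is
    ``antecedent_support * confidence``.
    """

    group: str  # group label, or "all"
    antecedent_answers: tuple[tuple[int, int], ...]  # (question, answer) pairs
    consequent: tuple[int, int]
    antecedent_support: float
    confidence: float

    def __post_init__(self) -> None:
        questions = [q for q, _ in self.antecedent_answers]
        if len(set(questions)) != len(questions):
            raise ValidationError("antecedent repeats a question")
        if self.consequent[0] in questions:
            raise ValidationError("antecedent and consequent questions must differ")
        if not 0 < self.antecedent_support <= 1 or not 0 < self.confidence <= 1:
            raise ValidationError("antecedent_support and confidence must be in (0, 1]")

    @property
    def questions(self) -> set[int]:
        return {q for q, _ in self.antecedent_answers} | {self.consequent[0]}

    @property
    def planted_support(self) -> float:
        return self.antecedent_support * self.confidence


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort recipe: sizes, instrument shape, baselines, planted rules."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"male": 41, "female": 281}
    )
    question_counts: Mapping[Category, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_QUESTION_COUNTS)
    )
    baseline: Mapping[int, tuple[float, ...]] = field(default_factory=dict)
    group_baseline: Mapping[str, Mapping[int, tuple[float, ...]]] = field(
        default_factory=dict
    )
    planted_rules: tuple[PlantedRule, ...] = ()
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        for probs in list(self.baseline.values()) + [
            p for g in self.group_baseline.values() for p in g.values()
        ]:
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError("answer probabilities must sum to 1")


def generate_codebook(config: GeneratorConfig = GeneratorConfig()) -> Codebook:
    """Deterministic codebook for the configured instrument shape."""
    questions = [
        Question(
            number=1,
            text="During the survey semester, you were a(n)",
            answer_labels=("Not a student", "Undergraduate", "Graduate"),
            answer_index_base=0,
            category=Category.DEMOGRAPHICS,
        ),
        Question(
            number=2,
            text="Your gender",
            answer_labels=("Male", "Female", "Other"),
            answer_index_base=0,
            category=Category.DEMOGRAPHICS,
        ),
    ]
    number = 3
    for category in ANALYSIS_CATEGORIES:
        arities = config.question_counts.get(category, ())
        if not arities:
            logger.warning("category %s has zero questions", category.value)
        for arity in arities:
            if arity == 5:
                labels = LIKERT5
            elif arity == 7:
                labels = LIKERT7
            else:
                labels = tuple(f"Choice {i}" for i in range(1, arity + 1))
            questions.append(
                Question(
                    number=number,
                    text=f"Synthetic {category.value.replace('_', ' ')} question {number}.",
                    answer_labels=labels,
                    answer_index_base=1,
                    category=category,
                )
            )
            number += 1
    return Codebook(questions)


def _baseline_for(
    config: GeneratorConfig, group: str, question: Question
) -> np.ndarray:
    probs = config.group_baseline.get(group, {}).get(question.number)
    if probs is None:
        probs = config.baseline.get(question.number)
    if probs is None:
        if question.number == 1:
            probs = (0.0, 0.5, 0.5)  # all students, equal UG/G split
        elif question.n_answers == 5:
            probs = BASELINE_5PT
        elif question.n_answers == 7:
            probs = BASELINE_7PT
        else:
            probs = tuple(1.0 / question.n_answers for _ in range(question.n_answers))
    probs = np.asarray(probs, dtype=float)
    if len(probs) != question.n_answers:
        raise ValidationError(
            f"baseline for question {question.number} has {len(probs)} entries, "
            f"expected {question.n_answers}"
        )
    return probs


def _validate_planted(config: GeneratorConfig, codebook: Codebook) -> None:
    for group in config.n_per_group:
        used: set[int] = set()
        for rule in config.planted_rules:
            if rule.group not in ("all", group):
                continue
            for q, a in list(rule.antecedent_answers) + [rule.consequent]:
                question = codebook[q]
                if a not in question.valid_indices:
                    raise ValidationError(
                        f"planted rule answer {a} invalid for question {q}"
                    )
            overlap = used & rule.questions
            if overlap:
                raise ValidationError(
                    f"planted rules share question(s) {sorted(overlap)} in group "
                    f"{group!r}"
                )
            used |= rule.questions
            if rule.planted_support < 0.2:
                logger.warning(
                    "planted rule in group %s has support %.3f < 0.2; it may not "
                    "be recoverable at default thresholds",
                    group,
                    rule.planted_support,
                )


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    codebook: Optional[Codebook] = None,
) -> list[SurveyReport]:
    """Draw a full cohort; reproducible from ``config.seed``."""
    if codebook is None:
        codebook = generate_codebook(config)
    _validate_planted(config, codebook)
    gender = codebook[GROUP_QUESTION]
    gender_labels = [lbl.lower() for lbl in gender.answer_labels]

    reports: list[SurveyReport] = []
    for gi, (group, n) in enumerate(sorted(config.n_per_group.items())):
        if n <= 0:
            raise ValidationError(f"group {group!r} size must be positive")
        try:
            gender_answer = gender.answer_index_base + gender_labels.index(group)
        except ValueError:
            raise ValidationError(
                f"group label {group!r} does not match an answer of question "
                f"{GROUP_QUESTION} ({gender.answer_labels})"
            ) from None

        # Planted antecedent answers are reserved for rule activation: the
        # baseline never emits them, so s(antecedent) = antecedent_support
        # and planted confidence is exact rather than diluted by chance
        # baseline matches.
        reserved: dict[int, set[int]] = {}
        for rule in config.planted_rules:
            if rule.group in ("all", group):
                for q, a in rule.antecedent_answers:
                    reserved.setdefault(q, set()).add(a)

        # baseline draws, one vectorized stream per question
        answers: dict[int, np.ndarray] = {}
        for question in codebook:
            if question.number == GROUP_QUESTION:
                answers[question.number] = np.full(n, gender_answer)
                continue
            probs = _baseline_for(config, group, question)
            if question.number in reserved:
                probs = probs.copy()
                for a in reserved[question.number]:
                    probs[a - question.answer_index_base] = 0.0
                if probs.sum() <= 0:
                    raise ValidationError(
                        f"question {question.number}: planted antecedents leave "
                        "no baseline answer mass"
                    )
                probs = probs / probs.sum()
            rng = np.random.default_rng([config.seed, gi, _NS_QUESTION + question.number])
            answers[question.number] = (
                rng.choice(question.n_answers, size=n, p=probs)
                + question.answer_index_base
            )

        # planted dependencies override the baseline where active
        for ri, rule in enumerate(config.planted_rules):
            if rule.group not in ("all", group):
                continue
            rng = np.random.default_rng([config.seed, gi, _NS_RULE + ri])
            active = rng.random(n) < rule.antecedent_support
            keep = rng.random(n) < rule.confidence
            for q, a in rule.antecedent_answers:
                answers[q][active] = a
            cq, ca = rule.consequent
            answers[cq][active & keep] = ca
            miss = active & ~keep
            if miss.any():
                question = codebook[cq]
                probs = _baseline_for(config, group, question)
                probs = probs.copy()
                probs[ca - question.answer_index_base] = 0.0
                if probs.sum() <= 0:
                    raise ValidationError(
                        f"cannot redraw consequent for question {cq}: baseline "
                        "mass is concentrated on the planted answer"
                    )
                probs /= probs.sum()
                answers[cq][miss] = (
                    rng.choice(question.n_answers, size=int(miss.sum()), p=probs)
                    + question.answer_index_base
                )

        # independent missingness per question (the group question stays)
        missing: dict[int, np.ndarray] = {}
        for question in codebook:
            if question.number == GROUP_QUESTION or config.missing_rate == 0:
                missing[question.number] = np.zeros(n, dtype=bool)
            else:
                rng = np.random.default_rng(
                    [config.seed, gi, _NS_MISSING + question.number]
                )
                missing[question.number] = rng.random(n) < config.missing_rate

        for i in range(n):
            report_answers = {
                q: int(answers[q][i])
                for q in codebook.question_numbers
                if not missing[q][i]
            }
            reports.append(
                SurveyReport(
                    participant_id=f"{group}-{i:04d}",
                    answers=report_answers,
                    group_label=group,
                )
            )
    return reports


def generate_screening_registry(
    config: GeneratorConfig = GeneratorConfig(),
    n_outside_us: int = 37,
    n_nonbinary: int = 7,
) -> list[SurveyReport]:
    """An unscreened registry: the cohort plus flagged ineligible reports.

    Mirrors a raw recruitment pool (default 322 eligible + 37 outside-US +
    7 non-binary = 366) for exercising the eligibility filter.
    """
    codebook = generate_codebook(config)
    reports = generate_cohort(config, codebook)
    rng = np.random.default_rng([config.seed, _NS_REGISTRY])

    def flagged(prefix: str, count: int, **flags) -> list[SurveyReport]:
        out = []
        for i in range(count):
            answers = {}
            for question in codebook:
                probs = _baseline_for(config, prefix, question)
                if question.number == GROUP_QUESTION:
                    # non-binary reports answer "Other"; outside-US keep a draw
                    answers[question.number] = (
                        2 if flags.get("nonbinary_gender") else int(rng.integers(0, 2))
                    )
                else:
                    answers[question.number] = int(
                        rng.choice(question.n_answers, p=probs)
                        + question.answer_index_base
                    )
            out.append(
                SurveyReport(
                    participant_id=f"{prefix}-{i:04d}",
                    answers=answers,
                    group_label="other" if flags.get("nonbinary_gender") else "",
                    **flags,
                )
            )
        return out

    registry = (
        reports
        + flagged("outside", n_outside_us, outside_us=True)
        + flagged("nonbinary", n_nonbinary, nonbinary_gender=True)
    )
    order = rng.permutation(len(registry))
    return [registry[i] for i in order]


def end_to_end_fixture(
    config: GeneratorConfig,
    outdir: Path,
) -> dict:
    """Write pipeline-ready responses/codebook CSVs plus a planted manifest.

    Returns the manifest dict: file paths, planted rules with their target
    support (= antecedent_support * confidence) and confidence, and the
    encoded item forms used downstream.
    """
    from .io import write_codebook_csv, write_responses_csv  # local: avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    codebook = generate_codebook(config)
    reports = generate_cohort(config, codebook)

    responses_path = outdir / "responses.csv"
    codebook_path = outdir / "codebook.csv"
    manifest_path = outdir / "manifest.json"
    write_responses_csv(reports, codebook, responses_path)
    write_codebook_csv(codebook, codebook_path)

    manifest = {
        "seed": config.seed,
        "n_per_group": dict(config.n_per_group),
        "missing_rate": config.missing_rate,
        "responses": responses_path.name,
        "codebook": codebook_path.name,
        "planted_rules": [
            {
                "group": rule.group,
                "antecedent_items": sorted(
                    encode_item(q, a, codebook) for q, a in rule.antecedent_answers
                ),
                "consequent_item": encode_item(*rule.consequent, codebook),
                "target_support": rule.planted_support,
                "target_confidence": rule.confidence,
            }
            for rule in config.planted_rules
        ],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def scaled_config(config: GeneratorConfig, n_per_group: int) -> GeneratorConfig:
    """Same recipe with every group scaled to ``n_per_group`` participants."""
    return replace(
        config, n_per_group={g: n_per_group for g in config.n_per_group}
    )
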