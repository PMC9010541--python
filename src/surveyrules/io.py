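"""Reading and writing the delimited formats used by the pipeline.

* Responses CSV: header ``participant_id,group,outside_us,<q>,<q>,...`` with
  one row per participant, integer answer indices, blank cells for missing
  answers.  ``outside_us`` is optional on input (0/1); a group value of
  other/non-binary sets the non-binary exclusion flag.
* Codebook CSV: columns ``number,text,category,index_base,labels`` with
  pipe-separated answer labels.
* Basket list: one transaction per line, participant id then tab-separated
  item codes.
* Rules CSV and comparison CSV: machine-readable pipeline outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .codebook import Category, Codebook, Question, SurveyReport
from .compare import GroupComparisonRow, comparison_table
from .encoding import Transaction
from .fpgrowth import FrequentItemset
from .rules import AssociationRule, rule_to_text

PathLike = Union[str, Path]

#: Group values (lower-cased) that mark a non-binary report on input.
NONBINARY_GROUP_VALUES = frozenset({"other", "nonbinary", "non-binary"})


class InputFormatError(ValueError):
    """An input file does not match the expected delimited layout."""


# ---------------------------------------------------------------------------
# Codebook


def write_codebook_csv(codebook: Codebook, path: PathLike) -> None:
    rows = [
        {
            "number": q.number,
            "text": q.text,
            "category": q.category.value,
            "index_base": q.answer_index_base,
            "labels": "|".join(q.answer_labels),
        }
        for q in codebook
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codebook_csv(path: PathLike) -> Codebook:
    try:
        frame = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputFormatError(f"cannot parse codebook {path}: {exc}") from exc
    required = {"number", "text", "category", "index_base", "labels"}
    if not required <= set(frame.columns):
        raise InputFormatError(
            f"codebook {path} missing column(s) {sorted(required - set(frame.columns))}"
        )
    questions = []
    for record in frame.to_dict("records"):
        try:
            questions.append(
                Question(
                    number=int(record["number"]),
                    text=str(record["text"]),
                    answer_labels=tuple(str(record["labels"]).split("|")),
                    answer_index_base=int(record["index_base"]),
                    category=Category(str(record["category"])),
                )
            )
        except (KeyError, ValueError) as exc:
            raise InputFormatError(
                f"codebook {path}: bad row {record!r}: {exc}"
            ) from exc
    return Codebook(questions)


# ---------------------------------------------------------------------------
# Responses


def write_responses_csv(
    reports: Sequence[SurveyReport], codebook: Codebook, path: PathLike
) -> None:
    numbers = codebook.question_numbers
    rows = []
    for report in reports:
        row: dict[str, object] = {
            "participant_id": report.participant_id,
            "group": report.group_label,
            "outside_us": int(report.outside_us),
        }
        for number in numbers:
            answer = report.answers.get(number)
            row[str(number)] = "" if answer is None else answer
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_responses_csv(path: PathLike, codebook: Codebook) -> list[SurveyReport]:
    """Parse and validate a responses table against the codebook."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise InputFormatError(f"cannot parse responses {path}: {exc}") from exc
    if "participant_id" not in frame.columns or "group" not in frame.columns:
        raise InputFormatError(
            f"responses {path} must have 'participant_id' and 'group' columns"
        )
    question_columns = [c for c in frame.columns if c.isdigit()]
    unknown = [c for c in question_columns if int(c) not in codebook]
    if unknown:
        raise InputFormatError(
            f"responses {path}: column(s) {unknown} not in codebook"
        )
    reports = []
    for record in frame.to_dict("records"):
        group = str(record["group"]).strip().lower()
        answers = {}
        for column in question_columns:
            cell = str(record[column]).strip()
            if not cell:
                continue
            try:
                answers[int(column)] = int(cell)
            except ValueError:
                raise InputFormatError(
                    f"responses {path}: non-integer answer {cell!r} "
                    f"for question {column}"
                ) from None
        outside = str(record.get("outside_us", "0")).strip().lower()
        report = SurveyReport(
            participant_id=str(record["participant_id"]),
            answers=answers,
            group_label=group,
            outside_us=outside in {"1", "true", "yes"},
            nonbinary_gender=group in NONBINARY_GROUP_VALUES,
        )
        report.validate(codebook)
        reports.append(report)
    return reports


# ---------------------------------------------------------------------------
# Baskets


def write_baskets(transactions: Sequence[Transaction], path: PathLike) -> None:
    with open(path, "w") as handle:
        for t in transactions:
            handle.write("\t".join([t.participant_id, *sorted(t.items)]) + "\n")


def read_baskets(path: PathLike) -> list[Transaction]:
    transactions = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            participant_id, *items = line.split("\t")
            transactions.append(
                Transaction(participant_id=participant_id, items=frozenset(items))
            )
    return transactions


# ---------------------------------------------------------------------------
# Mining outputs


def write_frequent_csv(frequent: Sequence[FrequentItemset], path: PathLike) -> None:
    pd.DataFrame(
        {
            "itemset": [" ".join(sorted(f.items)) for f in frequent],
            "count": [f.count for f in frequent],
            "support": [f.support for f in frequent],
        }
    ).to_csv(path, index=False)


def write_rules_csv(
    rules: Sequence[AssociationRule],
    path: PathLike,
    category: Optional[Category] = None,
    group: Optional[str] = None,
) -> None:
    pd.DataFrame(
        {
            "antecedent": [" ".join(sorted(r.antecedent)) for r in rules],
            "consequent": [" ".join(sorted(r.consequent)) for r in rules],
            "count": [r.count for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
            "category": [category.value if category else "" for _ in rules],
            "group": [group or "" for _ in rules],
        }
    ).to_csv(path, index=False)


def read_rules_csv(path: PathLike) -> list[AssociationRule]:
    frame = pd.read_csv(path, keep_default_na=False)
    return [
        AssociationRule(
            antecedent=frozenset(str(r["antecedent"]).split()),
            consequent=frozenset(str(r["consequent"]).split()),
            count=int(r["count"]),
            support=float(r["support"]),
            confidence=float(r["confidence"]),
            lift=float(r["lift"]),
        )
        for r in frame.to_dict("records")
    ]


def write_rules_jsonl(
    rules: Sequence[AssociationRule], codebook: Codebook, path: PathLike
) -> None:
    """JSON-lines export with the decoded question/answer text per rule."""
    with open(path, "w") as handle:
        for rule in rules:
            record = {
                "antecedent": sorted(rule.antecedent),
                "consequent": sorted(rule.consequent),
                "support": rule.support,
                "confidence": rule.confidence,
                "lift": rule.lift,
                "text": rule_to_text(rule, codebook),
            }
            handle.write(json.dumps(record) + "\n")


def write_comparison_csv(
    rows: Sequence[GroupComparisonRow],
    groups: tuple[str, str],
    path: PathLike,
) -> None:
    comparison_table(rows, groups).to_csv(path, index=False)


def write_comparison_json(
    rows: Sequence[GroupComparisonRow],
    groups: tuple[str, str],
    path: PathLike,
    rule_files: Optional[dict] = None,
) -> None:
    """Full-precision comparison values (display CSV rounds to 2 decimals)."""
    payload = {
        "groups": list(groups),
        "rows": [
            {
                "category": r.category.value,
                groups[0]: r.count_a,
                groups[1]: r.count_b,
                "diff": r.diff,
                "ratio": r.ratio,
            }
            for r in rows
        ],
    }
    if rule_files:
        payload["rule_files"] = {
            f"{group}/{category.value}": str(p)
            for (group, category), p in rule_files.items()
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
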