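"""End-to-end orchestration: filter -> encode -> mine -> rules -> compare.

`run_pipeline` reads a responses table and codebook, screens participants,
mines association rules per (group, category) cell, and writes the rule
CSVs, the comparison table, the exclusion log and a run manifest (with
input checksums) to an output directory.  The analytic path contains no
randomness: re-running on the same inputs reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .codebook import Category
from .compare import compare_counts, consistency_report, stratify_and_mine
from .filtering import DEFAULT_MAX_MISSING_FRACTION, eligibility_filter
from .fpgrowth import DEFAULT_MAX_LEN
from .io import (
    read_codebook_csv,
    read_responses_csv,
    write_comparison_csv,
    write_comparison_json,
    write_rules_csv,
)
from .rules import RuleThresholds
from .synthetic import GROUP_QUESTION

logger = logging.getLogger(__name__)


class NoEligibleReportsError(RuntimeError):
    """The eligibility screen removed every report."""


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs, with the study's default thresholds."""

    responses: Path
    codebook: Path
    outdir: Path
    thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    group_question: int = GROUP_QUESTION
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION
    categories: Optional[Sequence[Category]] = None
    include_group_item: bool = False
    single_consequent: bool = True
    max_len: Optional[int] = DEFAULT_MAX_LEN


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    codebook = read_codebook_csv(config.codebook)
    reports = read_responses_csv(config.responses, codebook)
    retained, log = eligibility_filter(
        reports, codebook, max_missing_fraction=config.max_missing_fraction
    )
    logger.info(
        "eligibility: %d in, %d retained, exclusions %s",
        log.n_input,
        log.n_retained,
        log.counts,
    )
    if not retained:
        raise NoEligibleReportsError("no reports survive the eligibility screen")

    rule_map = stratify_and_mine(
        retained,
        codebook,
        group_question=config.group_question,
        thresholds=config.thresholds,
        categories=config.categories,
        include_group_item=config.include_group_item,
        max_len=config.max_len,
        single_consequent=config.single_consequent,
    )
    labels = sorted({g for g, _ in rule_map})
    groups = (labels[1], labels[0])  # second sorted label first: male-minus-female style
    for (group, category), rules in rule_map.items():
        logger.info("%s/%s: %d rule(s)", group, category.value, len(rules))

    rule_files = {}
    for (group, category), rules in sorted(rule_map.items()):
        path = outdir / f"rules_{group}_{category.value}.csv"
        write_rules_csv(rules, path, category=category, group=group)
        rule_files[(group, category)] = path.name

    rows = compare_counts(rule_map, groups=groups)
    write_comparison_csv(rows, groups, outdir / "comparison.csv")
    write_comparison_json(
        rows, groups, outdir / "comparison.json", rule_files=rule_files
    )
    (outdir / "consistency.txt").write_text(consistency_report(rows, groups) + "\n")
    (outdir / "exclusion_log.json").write_text(
        json.dumps(
            {
                "n_input": log.n_input,
                "n_retained": log.n_retained,
                "exclusions": log.counts,
            },
            indent=2,
        )
        + "\n"
    )

    manifest = {
        "version": __version__,
        "inputs": {
            "responses": {"path": str(config.responses), "sha256": _sha256(config.responses)},
            "codebook": {"path": str(config.codebook), "sha256": _sha256(config.codebook)},
        },
        "thresholds": {
            "minsup": config.thresholds.minsup,
            "minconf": config.thresholds.minconf,
            "minlift": config.thresholds.minlift,
        },
        "group_question": config.group_question,
        "max_missing_fraction": config.max_missing_fraction,
        "max_len": config.max_len,
        "single_consequent": config.single_consequent,
        "include_group_item": config.include_group_item,
        "groups": list(groups),
        "eligibility": {
            "n_input": log.n_input,
            "n_retained": log.n_retained,
            "exclusions": log.counts,
        },
        "rule_counts": {
            f"{group}/{category.value}": len(rules)
            for (group, category), rules in sorted(rule_map.items())
        },
        "outputs": {
            "comparison_csv": "comparison.csv",
            "comparison_json": "comparison.json",
            "consistency": "consistency.txt",
            "exclusion_log": "exclusion_log.json",
            "rules": sorted(rule_files.values()),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
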