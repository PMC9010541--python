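"""Participant eligibility screening.

Reports are excluded, in a fixed precedence order, when the participant was
outside the US at survey time, reported a non-binary gender (two-group
analysis only), or left more than a configurable fraction of questions
unanswered.  The fixed order makes the exclusion log deterministic for a
report carrying several flags: each report is counted under exactly one
reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .codebook import Codebook, SurveyReport

#: Default ceiling on the unanswered-question fraction.  "No excessive
#: missing answers" is a qualitative screen; 0.2 is a conservative,
#: documented default exposed in every entry point.
DEFAULT_MAX_MISSING_FRACTION = 0.2

#: Exclusion reasons in the precedence order they are checked.
EXCLUSION_REASONS = ("outside_us", "nonbinary_gender", "missingness")


@dataclass
class ExclusionLog:
    """Per-reason exclusion counts from one eligibility pass."""

    n_input: int = 0
    n_retained: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {reason: 0 for reason in EXCLUSION_REASONS}
    )

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def check(self) -> None:
        """Every input report is retained or counted under exactly one reason."""
        assert self.n_input == self.n_retained + self.n_excluded


def eligibility_filter(
    reports: Sequence[SurveyReport],
    codebook: Codebook,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> tuple[list[SurveyReport], ExclusionLog]:
    """Screen reports for eligibility.

    Parameters
    ----------
    reports:
        Raw survey reports (already validated against the codebook).
    codebook:
        Defines the question set against which missingness is measured.
    max_missing_fraction:
        A report with a strictly larger unanswered fraction is dropped.

    Returns
    -------
    (retained, log):
        The retained reports in input order and an :class:`ExclusionLog`
        with one count per reason.  Empty input yields an empty output with
        a zeroed log.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    log = ExclusionLog(n_input=len(reports))
    retained: list[SurveyReport] = []
    for report in reports:
        if report.outside_us:
            log.counts["outside_us"] += 1
        elif report.nonbinary_gender:
            log.counts["nonbinary_gender"] += 1
        elif report.missing_fraction(codebook) > max_missing_fraction:
            log.counts["missingness"] += 1
        else:
            retained.append(report)
    log.n_retained = len(retained)
    log.check()
    return retained, log
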